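"""Independent brute-force reference implementations for the test suite.

Everything here is written from the definitions in pure Python loops and
sets -- no code from the package under test, no shared helpers -- so the
pipeline can be checked against an implementation that cannot share its
bugs. p-values use scipy.special/integrate directly (erfc for the normal
tail, numerical integration of the Bessel K0 density for the volcano
tail), not the package's interpolant.
"""

from __future__ import annotations

import math

from scipy import integrate, special


def pearson(xs, ys):
    """Pearson correlation from the definitional sum formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)


def pcc_matrix(rows):
    """rows: list of per-molecule value lists -> nested dict of PCCs."""
    m = len(rows)
    return {
        i: {j: pearson(rows[i], rows[j]) for j in range(m)} for i in range(m)
    }


def normal_two_sided(z):
    return math.erfc(abs(z) / math.sqrt(2))


def volcano_two_sided(z):
    """P(|XY| > |z|) by numerical integration of the product-normal
    density K0(|x|)/pi."""
    t = abs(z)
    if t == 0:
        return 1.0
    val, _ = integrate.quad(special.k0, t, math.inf)
    return 2.0 * val / math.pi


def z_statistic(spcc, pcc_n, n):
    return spcc * (n - 1) / (1.0 - pcc_n**2)


def ssn_edges(rows_ref, new_values, alpha=0.05, tail="volcano"):
    """Significant differential-correlation edges as a set of index pairs,
    plus the full sPCC lookup. All pairwise, straight from definitions."""
    m = len(rows_ref)
    n = len(rows_ref[0])
    tail_fn = volcano_two_sided if tail == "volcano" else normal_two_sided
    edges = set()
    spcc = {}
    for i in range(m):
        for j in range(i + 1, m):
            p_n = pearson(rows_ref[i], rows_ref[j])
            p_n1 = pearson(
                list(rows_ref[i]) + [new_values[i]],
                list(rows_ref[j]) + [new_values[j]],
            )
            d = p_n1 - p_n
            spcc[(i, j)] = spcc[(j, i)] = d
            if abs(p_n) >= 1 - 1e-12:
                continue
            if tail_fn(z_statistic(d, p_n, n)) < alpha:
                edges.add((i, j))
                edges.add((j, i))
    return edges, spcc


def neighbor_sets(edges, center, m):
    """First- and second-order neighbor sets of `center` from an edge set."""
    first = {j for j in range(m) if (center, j) in edges}
    second = set()
    for y in first:
        for z in range(m):
            if (y, z) in edges and z != center and z not in first:
                second.add(z)
    return first, second


def brute_landscape(
    rows_ref,
    new_values,
    ref_means,
    ref_sds,
    alpha=0.05,
    tail="volcano",
    standardize=True,
    score_form="ratio",
    epsilon=1e-6,
):
    """Local DNB scores of every eligible molecule, plus the global score.

    Pure-Python evaluation of the module deviation, intra-module and
    module-to-outside differential-correlation averages, and their
    combination, over the edge set from `ssn_edges`.
    """
    m = len(rows_ref)
    edges, spcc = ssn_edges(rows_ref, new_values, alpha=alpha, tail=tail)
    scores = {}
    for c in range(m):
        first, second = neighbor_sets(edges, c, m)
        if len(first) < 3 or len(second) < 1:
            continue
        members = [c] + sorted(first)
        devs = []
        for i in members:
            d = abs(new_values[i] - ref_means[i])
            if standardize:
                d /= ref_sds[i]
            devs.append(d)
        sad_in = sum(devs) / len(members)
        spcc_in = sum(abs(spcc[(c, y)]) for y in first) / len(first)
        spcc_out = sum(
            abs(spcc[(y, z)]) for y in first for z in second
        ) / (len(first) * len(second))
        if score_form == "ratio":
            s = sad_in * spcc_in / max(spcc_out, epsilon)
        else:
            s = sad_in * spcc_in * spcc_out
        scores[c] = (s, sad_in, spcc_in, spcc_out)
    if scores:
        global_score = sum(v[0] for v in scores.values()) / len(scores)
    else:
        global_score = 0.0
    return scores, global_score
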