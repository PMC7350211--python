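"""Local and global DNB scores over single-sample networks.

For each molecule x with enough network context in a sample's SSN, the
local module is x plus its first-order neighbors N_x; the second-order
neighbors M_x are neighbors-of-neighbors excluding x and N_x. The local
DNB score combines the three DNB conditions:

    sAD_in   -- mean absolute abundance deviation of the module's
                1 + |N_x| molecules from their reference means,
    sPCC_in  -- mean |sPCC| between x and its first-order neighbors,
    sPCC_out -- mean |sPCC| between first- and second-order neighbors
                (all N_x x M_x pairs, significant or not),

    Is(x) = sAD_in * sPCC_in / max(sPCC_out, eps)      ("ratio", default)
    Is(x) = sAD_in * sPCC_in * sPCC_out                ("product")

Only molecules with at least three first-order and one second-order
neighbor are scored. The sample's global DNB score is the arithmetic mean
of its local scores over exactly the eligible molecules.

Abundances are z-scored per molecule against the reference mean and SD by
default, so deviations are on a common scale and the fixed high-risk
threshold on the global score is meaningful across platforms; raw-scale
deviations are available with ``standardize=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ssn import ReferenceStatistics, SSNetwork, build_ssn, compute_reference_stats

logger = logging.getLogger(__name__)

__all__ = [
    "LocalModule",
    "LocalScore",
    "DNBLandscape",
    "sad",
    "sad_in",
    "spcc_in",
    "spcc_out",
    "local_dnb_score",
    "enumerate_modules",
    "landscape",
    "cohort_landscapes",
    "EPSILON",
]

#: floor on sPCC_out in the ratio score, guarding near-zero denominators
EPSILON = 1e-6

MIN_FIRST_ORDER = 3
MIN_SECOND_ORDER = 1


@dataclass(frozen=True)
class LocalModule:
    """A center molecule with its first- and second-order neighbor sets."""

    center: str
    first_order: frozenset[str]
    second_order: frozenset[str]

    def __post_init__(self) -> None:
        if self.center in self.first_order or self.center in self.second_order:
            raise ValueError(f"center {self.center!r} appears in its neighbor sets")
        if self.first_order & self.second_order:
            raise ValueError(
                "first- and second-order neighbor sets must be disjoint: "
                f"{sorted(self.first_order & self.second_order)}"
            )

    @property
    def eligible(self) -> bool:
        return (
            len(self.first_order) >= MIN_FIRST_ORDER
            and len(self.second_order) >= MIN_SECOND_ORDER
        )


@dataclass(frozen=True)
class LocalScore:
    """One molecule's local DNB score and its components."""

    score: float
    sad_in: float
    spcc_in: float
    spcc_out: float
    n_first: int
    n_second: int
    floored: bool = False  # sPCC_out hit the EPSILON floor


@dataclass(frozen=True)
class DNBLandscape:
    """All local DNB scores of one sample plus the global score."""

    sample_id: str
    scores: dict[str, LocalScore]
    global_score: float

    @property
    def eligible_count(self) -> int:
        return len(self.scores)

    def score_series(self) -> pd.Series:
        return pd.Series(
            {m: s.score for m, s in self.scores.items()}, name=self.sample_id
        )

    def table(self) -> pd.DataFrame:
        rows = [
            (m, s.score, s.sad_in, s.spcc_in, s.spcc_out, s.n_first, s.n_second)
            for m, s in sorted(self.scores.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "molecule_id", "Is", "sADin", "sPCCin", "sPCCout",
                "n_first", "n_second",
            ],
        )


def sad(
    x_value: float,
    ref_mean: float,
    ref_sd: float | None = None,
    standardized: bool = True,
) -> float:
    """Single-sample abundance deviation |x_d - x_bar|.

    With ``standardized=True`` (default) the deviation is taken on the
    z-scale, i.e. |x_d - x_bar| / sd.
    """
    dev = abs(float(x_value) - float(ref_mean))
    if standardized:
        if ref_sd is None or ref_sd <= 0:
            raise ValueError("standardized deviation requires ref_sd > 0")
        dev /= float(ref_sd)
    return dev


def _deviations(
    sample: Mapping[str, float] | pd.Series,
    ref_stats: ReferenceStatistics,
    standardized: bool,
) -> dict[str, float]:
    out = {}
    for i, m in enumerate(ref_stats.molecule_ids):
        out[m] = sad(
            sample[m], ref_stats.mean[i], ref_stats.sd[i], standardized=standardized
        )
    return out


def sad_in(
    module: LocalModule,
    sample: Mapping[str, float] | pd.Series,
    ref_stats: ReferenceStatistics,
    standardized: bool = True,
) -> float:
    """Mean deviation over the 1 + n_x molecules of the local module."""
    devs = _deviations(sample, ref_stats, standardized)
    members = [module.center, *sorted(module.first_order)]
    return sum(devs[m] for m in members) / len(members)


def spcc_in(module: LocalModule, ssn: SSNetwork, absolute: bool = True) -> float:
    """Mean (absolute) sPCC between the center and its first-order
    neighbors."""
    vals = [ssn.spcc_of(module.center, y) for y in sorted(module.first_order)]
    if absolute:
        vals = [abs(v) for v in vals]
    return float(np.mean(vals))


def spcc_out(module: LocalModule, ssn: SSNetwork, absolute: bool = True) -> float:
    """Mean (absolute) sPCC over all first-order x second-order pairs.

    Every pair is counted whether or not it is a significant SSN edge.
    """
    vals = [
        ssn.spcc_of(y, z_)
        for y in sorted(module.first_order)
        for z_ in sorted(module.second_order)
    ]
    if absolute:
        vals = [abs(v) for v in vals]
    return float(np.mean(vals))


def local_dnb_score(
    module: LocalModule,
    sample: Mapping[str, float] | pd.Series,
    ref_stats: ReferenceStatistics,
    ssn: SSNetwork,
    standardize: bool = True,
    absolute_spcc: bool = True,
    score_form: str = "ratio",
    epsilon: float = EPSILON,
) -> LocalScore:
    """Score one eligible local module."""
    if not module.eligible:
        raise ValueError(
            f"module of {module.center!r} is ineligible "
            f"({len(module.first_order)} first-order, "
            f"{len(module.second_order)} second-order neighbors)"
        )
    a = sad_in(module, sample, ref_stats, standardized=standardize)
    b = spcc_in(module, ssn, absolute=absolute_spcc)
    c = spcc_out(module, ssn, absolute=absolute_spcc)
    if score_form == "ratio":
        floored = c < epsilon
        score = a * b / max(c, epsilon)
    elif score_form == "product":
        floored = False
        score = a * b * c
    else:
        raise ValueError(f"unknown score_form {score_form!r}")
    return LocalScore(
        score=float(score),
        sad_in=float(a),
        spcc_in=float(b),
        spcc_out=float(c),
        n_first=len(module.first_order),
        n_second=len(module.second_order),
        floored=floored,
    )


def enumerate_modules(ssn: SSNetwork, eligible_only: bool = True) -> list[LocalModule]:
    """All local modules of the SSN, in molecule order.

    The second-order set of a center is the union of its first-order
    neighbors' neighborhoods, minus the center and the first-order set.
    """
    adj = ssn.adjacency
    ids = ssn.molecule_ids
    out = []
    for i in range(len(ids)):
        first = np.flatnonzero(adj[i])
        if eligible_only and len(first) < MIN_FIRST_ORDER:
            continue
        second_mask = adj[first].any(axis=0)
        second_mask[i] = False
        second_mask[first] = False
        second = np.flatnonzero(second_mask)
        mod = LocalModule(
            center=ids[i],
            first_order=frozenset(ids[j] for j in first),
            second_order=frozenset(ids[j] for j in second),
        )
        if not eligible_only or mod.eligible:
            out.append(mod)
    return out


def _landscape_from_ssn(
    ssn: SSNetwork,
    sample: Mapping[str, float] | pd.Series,
    ref_stats: ReferenceStatistics,
    standardize: bool,
    absolute_spcc: bool,
    score_form: str,
    epsilon: float,
) -> DNBLandscape:
    # vectorized equivalent of scoring each eligible module in turn
    adj = ssn.adjacency
    ids = ssn.molecule_ids
    x = np.asarray([sample[m] for m in ids], dtype=float)
    dev = np.abs(x - ref_stats.mean)
    if standardize:
        dev = dev / ref_stats.sd
    spcc = np.abs(ssn.spcc) if absolute_spcc else ssn.spcc

    scores: dict[str, LocalScore] = {}
    n_floored = 0
    for i in range(len(ids)):
        first = np.flatnonzero(adj[i])
        if len(first) < MIN_FIRST_ORDER:
            continue
        second_mask = adj[first].any(axis=0)
        second_mask[i] = False
        second_mask[first] = False
        second = np.flatnonzero(second_mask)
        if len(second) < MIN_SECOND_ORDER:
            continue
        a = (dev[i] + dev[first].sum()) / (1 + len(first))
        b = spcc[i, first].mean()
        c = spcc[np.ix_(first, second)].mean()
        if score_form == "ratio":
            floored = c < epsilon
            n_floored += floored
            s = a * b / max(c, epsilon)
        else:
            floored = False
            s = a * b * c
        scores[ids[i]] = LocalScore(
            score=float(s),
            sad_in=float(a),
            spcc_in=float(b),
            spcc_out=float(c),
            n_first=len(first),
            n_second=len(second),
            floored=floored,
        )
    if n_floored:
        logger.info(
            "sample %s: %d module(s) hit the sPCC_out floor of %g",
            ssn.sample_id, n_floored, epsilon,
        )
    if scores:
        global_score = float(np.mean([s.score for s in scores.values()]))
    else:
        global_score = 0.0
        warnings.warn(
            f"sample {ssn.sample_id!r} has no eligible local module; "
            "its global DNB score is reported as 0",
            stacklevel=3,
        )
    return DNBLandscape(
        sample_id=ssn.sample_id, scores=scores, global_score=global_score
    )


def landscape(
    sample_id: str,
    abundance: pd.DataFrame,
    reference_ids: Sequence[str],
    alpha: float = 0.05,
    tail: str = "volcano",
    standardize: bool = True,
    absolute_spcc: bool = True,
    score_form: str = "ratio",
    epsilon: float = EPSILON,
    leave_one_out: bool = False,
    reference_edge_filter: str = "none",
    ref_stats: ReferenceStatistics | None = None,
) -> DNBLandscape:
    """Build the sample's SSN and score every eligible local module.

    Deterministic given its inputs; samples whose SSN yields no eligible
    module get a global score of 0 with a warning.
    """
    if score_form not in ("ratio", "product"):
        raise ValueError(f"unknown score_form {score_form!r}")
    refs = list(reference_ids)
    if leave_one_out and sample_id in refs:
        refs = [s for s in refs if s != sample_id]
        ref_stats = None
    if ref_stats is None:
        ref_stats = compute_reference_stats(abundance, refs)
    ssn = build_ssn(
        abundance,
        refs,
        sample_id,
        alpha=alpha,
        tail=tail,
        reference_edge_filter=reference_edge_filter,
        ref_stats=ref_stats,
    )
    sample = abundance[sample_id]
    return _landscape_from_ssn(
        ssn, sample, ref_stats, standardize, absolute_spcc, score_form, epsilon
    )


def cohort_landscapes(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_group: str = "control",
    sample_ids: Sequence[str] | None = None,
    **kwargs,
) -> tuple[dict[str, DNBLandscape], pd.DataFrame]:
    """Landscapes for every sample against the reference group.

    All samples -- including the reference group's own members, scored
    against the unchanged reference per the same-reference-network rule --
    share one reference set. Returns the landscapes plus a tidy global
    score table (``sample_id``, ``group``, ``global_dnb_score``).
    """
    reference_ids = list(metadata.index[metadata["group"] == reference_group])
    if not reference_ids:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    if sample_ids is None:
        sample_ids = list(metadata.index)
    ref_stats = compute_reference_stats(abundance, reference_ids)
    landscapes = {}
    for sid in sample_ids:
        landscapes[sid] = landscape(
            sid, abundance, reference_ids, ref_stats=ref_stats, **kwargs
        )
    table = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "group": [metadata.loc[s, "group"] for s in sample_ids],
            "global_dnb_score": [landscapes[s].global_score for s in sample_ids],
        }
    )
    return landscapes, table
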