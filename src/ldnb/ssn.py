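"""Single-sample network (SSN) construction.

A single-sample network captures how adding one new sample *d* to a
reference cohort of *n* samples perturbs pairwise Pearson correlations.
For every molecule pair (x, y) the differential correlation

    sPCC_n(x, y) = PCC_{n+1}(x, y) - PCC_n(x, y)

is tested against its null sampling law; pairs whose correlation changes
significantly (p < alpha) become the edges of that sample's network.

Under the null hypothesis that *d* is drawn from the reference
distribution, the standardized statistic

    z = sPCC * (n - 1) / (1 - PCC_n**2)

is asymptotically distributed (in the reference size n) as the product of
two independent standard normals -- the heavy-tailed "volcano"
distribution -- not as a standard normal: the new sample's contribution
z_x * z_y does not average out with n. Tail probabilities therefore
default to the exact product-normal law (``tail="volcano"``); the common
normal approximation and a resampling fallback for small n are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceStatistics",
    "SSNEdge",
    "SSNetwork",
    "compute_reference_stats",
    "perturbed_pcc",
    "delta_pcc",
    "volcano_sf",
    "edge_significance",
    "build_ssn",
]

#: |PCC| at or above this is treated as numerically degenerate.
_DEGENERATE = 1.0 - 1e-12


@dataclass(frozen=True)
class ReferenceStatistics:
    """Per-molecule moments and the PCC matrix of the reference cohort.

    Attributes
    ----------
    molecule_ids
        Ordered molecule identifiers of the retained (non-constant) rows.
    n
        Number of reference samples.
    mean, sd
        Per-molecule reference mean and sample standard deviation
        (``ddof=1``), aligned with ``molecule_ids``.
    pcc
        Symmetric reference correlation matrix, unit diagonal.
    dropped
        Molecules removed because they are constant across the reference.
    """

    molecule_ids: tuple[str, ...]
    n: int
    mean: np.ndarray
    sd: np.ndarray
    pcc: np.ndarray
    dropped: tuple[str, ...] = ()

    def index_of(self, molecule: str) -> int:
        return self.molecule_ids.index(molecule)


@dataclass(frozen=True)
class SSNEdge:
    """One significant differential-correlation edge."""

    molecule_a: str
    molecule_b: str
    pcc_n: float
    pcc_n1: float
    spcc: float
    z: float
    p: float


class SSNetwork:
    """A sample's differential-correlation network.

    Stores the full pairwise matrices (``pcc_n``, ``pcc_n1``, ``spcc``,
    ``z``, ``p``) plus the boolean adjacency of significant edges, so that
    downstream scoring can read sPCC for *any* pair, edge or not.
    """

    def __init__(
        self,
        sample_id: str,
        molecule_ids: Sequence[str],
        alpha: float,
        pcc_n: np.ndarray,
        pcc_n1: np.ndarray,
        z: np.ndarray,
        p: np.ndarray,
    ) -> None:
        m = len(molecule_ids)
        self.sample_id = str(sample_id)
        self.molecule_ids = tuple(str(x) for x in molecule_ids)
        self.alpha = float(alpha)
        self.pcc_n = pcc_n
        self.pcc_n1 = pcc_n1
        self.spcc = pcc_n1 - pcc_n
        self.z = z
        self.p = p
        adjacency = np.asarray(p < alpha, dtype=bool)
        np.fill_diagonal(adjacency, False)
        adjacency &= adjacency.T  # symmetry guard; p is symmetric anyway
        self.adjacency = adjacency
        self._index = {mol: i for i, mol in enumerate(self.molecule_ids)}
        assert adjacency.shape == (m, m)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbors(self, molecule: str) -> set[str]:
        """First-order neighbor IDs of ``molecule``."""
        i = self._index[molecule]
        return {self.molecule_ids[j] for j in np.flatnonzero(self.adjacency[i])}

    def spcc_of(self, a: str, b: str) -> float:
        return float(self.spcc[self._index[a], self._index[b]])

    def edges(self) -> Iterator[SSNEdge]:
        iu, ju = np.where(np.triu(self.adjacency, k=1))
        for i, j in zip(iu, ju):
            yield SSNEdge(
                self.molecule_ids[i],
                self.molecule_ids[j],
                float(self.pcc_n[i, j]),
                float(self.pcc_n1[i, j]),
                float(self.spcc[i, j]),
                float(self.z[i, j]),
                float(self.p[i, j]),
            )

    def edge_table(self) -> pd.DataFrame:
        """Edge list as a DataFrame with fixed column order."""
        rows = [
            (e.molecule_a, e.molecule_b, e.pcc_n, e.pcc_n1, e.spcc, e.z, e.p)
            for e in self.edges()
        ]
        return pd.DataFrame(
            rows,
            columns=["molecule_a", "molecule_b", "pcc_n", "pcc_n1", "spcc", "z", "p"],
        )


def _as_matrix(abundance: pd.DataFrame, sample_ids: Sequence[str]) -> np.ndarray:
    missing = [s for s in sample_ids if s not in abundance.columns]
    if missing:
        raise KeyError(f"sample IDs not present in abundance matrix: {missing}")
    return abundance.loc[:, list(sample_ids)].to_numpy(dtype=float)


def compute_reference_stats(
    abundance: pd.DataFrame, reference_ids: Sequence[str]
) -> ReferenceStatistics:
    """Per-molecule reference moments and the n-sample PCC matrix.

    Molecules that are constant across the reference samples are dropped
    (Pearson correlation is undefined for them) and recorded both in the
    log and in ``ReferenceStatistics.dropped``.
    """
    reference_ids = list(reference_ids)
    if len(reference_ids) < 3:
        raise ValueError(
            f"need at least 3 reference samples, got {len(reference_ids)}"
        )
    X = _as_matrix(abundance, reference_ids)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = tuple(abundance.index[~keep].astype(str))
    if dropped:
        logger.info(
            "dropping %d molecule(s) constant in the reference: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    X = X[keep]
    ids = tuple(abundance.index[keep].astype(str))
    pcc = np.corrcoef(X)
    np.fill_diagonal(pcc, 1.0)
    return ReferenceStatistics(
        molecule_ids=ids,
        n=len(reference_ids),
        mean=X.mean(axis=1),
        sd=X.std(axis=1, ddof=1),
        pcc=pcc,
        dropped=dropped,
    )


def perturbed_pcc(
    abundance: pd.DataFrame,
    reference_ids: Sequence[str],
    new_sample: str | pd.Series,
    ref_stats: ReferenceStatistics | None = None,
) -> np.ndarray:
    """PCC matrix over the reference samples plus one new sample.

    ``new_sample`` may be a column name of ``abundance`` or a Series
    indexed by molecule ID. The correlation is recomputed directly on the
    concatenated (n+1)-sample matrix, which is its defining form.
    """
    if ref_stats is None:
        ref_stats = compute_reference_stats(abundance, reference_ids)
    X = _as_matrix(abundance, list(reference_ids))[
        [abundance.index.get_loc(m) for m in ref_stats.molecule_ids]
    ]
    if isinstance(new_sample, pd.Series):
        missing = [m for m in ref_stats.molecule_ids if m not in new_sample.index]
        if missing:
            raise KeyError(f"new sample is missing molecules: {missing}")
        d = new_sample.loc[list(ref_stats.molecule_ids)].to_numpy(dtype=float)
    else:
        if new_sample not in abundance.columns:
            raise KeyError(f"sample {new_sample!r} not in abundance matrix")
        d = abundance.loc[list(ref_stats.molecule_ids), new_sample].to_numpy(
            dtype=float
        )
    full = np.hstack([X, d[:, None]])
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.corrcoef(full)
    return pcc


def delta_pcc(pcc_n: np.ndarray, pcc_n1: np.ndarray) -> np.ndarray:
    """Differential correlation sPCC = PCC_{n+1} - PCC_n, elementwise."""
    pcc_n = np.asarray(pcc_n, dtype=float)
    pcc_n1 = np.asarray(pcc_n1, dtype=float)
    if pcc_n.shape != pcc_n1.shape:
        raise ValueError("shape mismatch between PCC_n and PCC_{n+1}")
    return pcc_n1 - pcc_n


def _volcano_sf_exact(t: np.ndarray) -> np.ndarray:
    """Closed-form tail: 1 - t*(K0(t)*L_{-1}(t) + K1(t)*L_0(t)), with L
    the modified Struve functions; valid up to t ~ 30 where the
    Bessel/Struve product over- and underflows."""
    out = np.ones_like(t)
    mid = (t > 0) & (t < 30.0)
    tm = t[mid]
    out[mid] = 1.0 - tm * (
        special.k0(tm) * special.modstruve(-1, tm)
        + special.k1(tm) * special.modstruve(0, tm)
    )
    far = t >= 30.0
    tf = t[far]
    with np.errstate(under="ignore"):
        out[far] = (2.0 / np.pi) * np.sqrt(np.pi / (2.0 * tf)) * np.exp(-tf)
    return np.clip(out, 0.0, 1.0)


_VOLCANO_GRID: tuple[np.ndarray, np.ndarray] | None = None


def volcano_sf(t):
    """Two-sided tail P(|XY| > t) for X, Y independent standard normals.

    The product-normal density is K0(|x|)/pi. The modified Struve
    functions in the closed-form tail are expensive, so the exact curve
    is tabulated once on a dense grid and interpolated on the log scale
    (relative error < 1e-7); the asymptotic tail takes over beyond t=30.
    """
    global _VOLCANO_GRID
    if _VOLCANO_GRID is None:
        # dense near 0 where the log-tail slope diverges; the closed form
        # loses to cancellation past t ~ 26 where sf < 1e-12 anyway
        grid = np.concatenate([[0.0], np.geomspace(1e-6, 1.0, 4000),
                               np.linspace(1.0, 26.0, 12501)[1:]])
        _VOLCANO_GRID = (grid, np.log(_volcano_sf_exact(grid)))
    t = np.abs(np.asarray(t, dtype=float))
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    grid, log_sf = _VOLCANO_GRID
    out = np.exp(np.interp(t, grid, log_sf))
    far = t >= 26.0
    if far.any():
        tf = t[far]
        with np.errstate(under="ignore"):
            out[far] = (2.0 / np.pi) * np.sqrt(np.pi / (2.0 * tf)) * np.exp(-tf)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def edge_significance(spcc, pcc_n, n: int, tail: str = "volcano"):
    """Test statistic and two-sided p-value for a differential correlation.

    z = sPCC * (n - 1) / (1 - PCC_n**2); the p-value is the two-sided tail
    of the product-normal ("volcano") null by default, or of the standard
    normal with ``tail="normal"``.

    Scalar inputs with |PCC_n| = 1 raise; in array inputs such entries are
    returned as NaN so the caller can exclude and log them.
    """
    if n < 3:
        raise ValueError("need n >= 3 reference samples")
    if tail not in ("volcano", "normal"):
        raise ValueError(f"unknown tail {tail!r}")
    spcc_a = np.asarray(spcc, dtype=float)
    pcc_a = np.asarray(pcc_n, dtype=float)
    scalar = spcc_a.ndim == 0 and pcc_a.ndim == 0
    degenerate = np.abs(pcc_a) >= _DEGENERATE
    if scalar and degenerate:
        raise ValueError(
            f"degenerate edge: |PCC_n| = {abs(float(pcc_a)):.12f} >= 1; "
            "the differential-correlation test is undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = spcc_a * (n - 1) / (1.0 - pcc_a**2)
    if tail == "volcano":
        p = volcano_sf(np.abs(z))
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    z = np.where(degenerate, np.nan, z)
    p = np.where(degenerate, np.nan, p)
    if scalar:
        return float(z), float(p)
    return z, p


def _permutation_pvalues(
    X: np.ndarray, pcc_n: np.ndarray, spcc_obs: np.ndarray, n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resampling p-values for sPCC: pseudo-new-samples are built by
    bootstrap-resampling each molecule's reference values independently,
    which preserves marginals while breaking any sample-specific
    co-deviation. p = (1 + #{|sPCC_null| >= |sPCC_obs|}) / (B + 1)."""
    m, n = X.shape
    exceed = np.zeros_like(spcc_obs)
    for _ in range(n_permutations):
        picks = rng.integers(0, n, size=m)
        pseudo = X[np.arange(m), picks]
        pcc_b = np.corrcoef(np.hstack([X, pseudo[:, None]]))
        exceed += np.abs(pcc_b - pcc_n) >= np.abs(spcc_obs)
    return (1.0 + exceed) / (n_permutations + 1.0)


def build_ssn(
    abundance: pd.DataFrame,
    reference_ids: Sequence[str],
    sample_id: str | pd.Series,
    alpha: float = 0.05,
    tail: str = "volcano",
    leave_one_out: bool = False,
    reference_edge_filter: str = "none",
    n_permutations: int = 199,
    rng: np.random.Generator | None = None,
    ref_stats: ReferenceStatistics | None = None,
) -> SSNetwork:
    """Construct one sample's SSN.

    Edges are exactly the molecule pairs whose differential correlation is
    significant at ``alpha``. Samples that belong to the reference group
    are, by default, scored against the unchanged reference set (they are
    appended as an extra observation just like any other sample);
    ``leave_one_out=True`` removes the sample from its own reference
    first.

    ``reference_edge_filter="pcc_pvalue"`` restricts the candidate pair
    universe to pairs already significantly correlated in the reference
    (two-sided t-test on PCC_n at the same ``alpha``).

    ``tail`` may also be ``"permutation"``: a resampling null for small
    reference cohorts, provided as an extension beyond the analytic test.
    """
    reference_ids = list(reference_ids)
    name = sample_id.name if isinstance(sample_id, pd.Series) else sample_id
    if leave_one_out and not isinstance(sample_id, pd.Series) and name in reference_ids:
        reference_ids = [s for s in reference_ids if s != name]
        ref_stats = None  # stats must be recomputed on the reduced reference
    if ref_stats is None:
        ref_stats = compute_reference_stats(abundance, reference_ids)
    n = ref_stats.n
    pcc_n = ref_stats.pcc
    pcc_n1 = perturbed_pcc(abundance, reference_ids, sample_id, ref_stats=ref_stats)
    spcc = delta_pcc(pcc_n, pcc_n1)

    if tail == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        X = _as_matrix(abundance, reference_ids)[
            [abundance.index.get_loc(m) for m in ref_stats.molecule_ids]
        ]
        p = _permutation_pvalues(X, pcc_n, spcc, n_permutations, rng)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = spcc * (n - 1) / (1.0 - pcc_n**2)
        degenerate = np.abs(pcc_n) >= _DEGENERATE
        z = np.where(degenerate, np.nan, z)
        p = np.where(degenerate, np.nan, p)
    else:
        z, p = edge_significance(spcc, pcc_n, n, tail=tail)

    n_degenerate = (np.isnan(p).sum() - len(ref_stats.molecule_ids)) // 2
    if n_degenerate > 0:
        logger.info(
            "sample %s: %d molecule pair(s) with |PCC_n| = 1 excluded as degenerate",
            name,
            n_degenerate,
        )
    p = np.where(np.isnan(p), 1.1, p)  # degenerate pairs can never be edges

    if reference_edge_filter == "pcc_pvalue":
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ref = pcc_n * np.sqrt((n - 2) / np.clip(1 - pcc_n**2, 1e-300, None))
        p_ref = 2.0 * stats.t.sf(np.abs(t_ref), df=n - 2)
        p = np.where(p_ref < alpha, p, 1.1)
    elif reference_edge_filter != "none":
        raise ValueError(f"unknown reference_edge_filter {reference_edge_filter!r}")

    net = SSNetwork(
        sample_id=str(name),
        molecule_ids=ref_stats.molecule_ids,
        alpha=alpha,
        pcc_n=pcc_n,
        pcc_n1=pcc_n1,
        z=z,
        p=p,
    )
    logger.debug("sample %s: SSN with %d edges at alpha=%g", name, net.n_edges, alpha)
    return net
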