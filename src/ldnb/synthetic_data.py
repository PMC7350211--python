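"""Synthetic metabolomics cohorts with a planted DNB module.

The generator emulates the second-order structure that dynamic network
biomarker (DNB) theory posits near a tipping point: in the predisease
group a small module of molecules shows (1) strongly inflated standard
deviation, (2) raised intra-module correlation and (3) depressed
correlation with the rest of the network, while the disease group relaxes
back to baseline second-order structure but acquires first-order (mean)
shifts.

Cohorts are drawn from block-structured multivariate Gaussians -- one
correlation target per block (module / background / cross) per group --
and exponentiated to log-normal intensities by default, since
metabolomics intensities are positive and right-skewed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "fixture_small"]

GROUPS = ("control", "stageA", "stageB")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults are desk-scale study conditions: three groups of 19/15/14
    samples (control / predisease / disease), 200 molecules with a planted
    10-molecule module whose predisease SD triples while intra-module
    correlation rises 0.2 -> 0.8 and module-to-background correlation
    falls 0.2 -> 0.02.
    """

    n_molecules: int = 200
    group_sizes: tuple[int, int, int] = (19, 15, 14)
    module_size: int = 10
    sd_inflation: float = 3.0
    rho_in_normal: float = 0.2
    rho_in_predisease: float = 0.8
    rho_out_normal: float = 0.2
    rho_out_predisease: float = 0.02
    background_rho: float = 0.2
    mean_shift_disease: float = 0.2
    seed: int = 0
    log_normal: bool = True
    log_mean: float = 7.0
    log_sd: float = 0.25
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.module_size < 4:
            raise ValueError(
                "module_size must be >= 4 so planted molecules can have "
                ">= 3 first-order neighbors"
            )
        if self.module_size >= self.n_molecules:
            raise ValueError("module_size must be smaller than n_molecules")
        if any(g < 1 for g in self.group_sizes) or len(self.group_sizes) != 3:
            raise ValueError("group_sizes must be three positive counts")
        for name in (
            "rho_in_normal",
            "rho_in_predisease",
            "rho_out_normal",
            "rho_out_predisease",
            "background_rho",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1)")
        if self.sd_inflation < 1.0:
            raise ValueError("sd_inflation must be >= 1")
        if self.rho_in_predisease < self.rho_in_normal:
            raise ValueError(
                "rho_in_predisease must not be below rho_in_normal "
                "(the predisease module gains internal correlation)"
            )
        if self.rho_out_predisease > self.rho_out_normal:
            raise ValueError(
                "rho_out_predisease must not exceed rho_out_normal "
                "(the predisease module decouples from the background)"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        # fail fast on correlation targets with no PSD realization
        for label, C in (
            ("baseline", self.baseline_correlation()),
            ("predisease", self.predisease_correlation()),
        ):
            _repair_psd(C, label, self)

    def null(self) -> "CohortSpec":
        """The matched no-effect spec: stage A distributionally identical
        to control, no disease mean shift."""
        return replace(
            self,
            sd_inflation=1.0,
            rho_in_predisease=self.rho_in_normal,
            rho_out_predisease=self.rho_out_normal,
            mean_shift_disease=0.0,
        )

    # --- correlation targets -------------------------------------------------

    def _block_correlation(self, rho_in: float, rho_out: float) -> np.ndarray:
        m, k = self.n_molecules, self.module_size
        C = np.full((m, m), self.background_rho)
        C[:k, :k] = rho_in
        C[:k, k:] = rho_out
        C[k:, :k] = rho_out
        np.fill_diagonal(C, 1.0)
        return C

    def baseline_correlation(self) -> np.ndarray:
        return self._block_correlation(self.rho_in_normal, self.rho_out_normal)

    def predisease_correlation(self) -> np.ndarray:
        return self._block_correlation(
            self.rho_in_predisease, self.rho_out_predisease
        )

    def predisease_sd(self) -> np.ndarray:
        sd = np.ones(self.n_molecules)
        sd[: self.module_size] = self.sd_inflation
        return sd


@dataclass(frozen=True)
class SyntheticCohort:
    """One generated cohort: abundance table, metadata, planted truth."""

    abundance: pd.DataFrame  # molecules x samples
    metadata: pd.DataFrame  # index sample_id, column "group"
    truth_module: frozenset[str]
    truth_tipping_group: str
    spec: CohortSpec

    @property
    def group_samples(self) -> dict[str, list[str]]:
        return {
            g: list(self.metadata.index[self.metadata["group"] == g])
            for g in GROUPS
        }


def _repair_psd(C: np.ndarray, label: str, spec: CohortSpec) -> np.ndarray:
    """Return a PSD correlation matrix near C.

    Slightly indefinite targets (cross-block combinations can push the
    smallest eigenvalue just below zero) are repaired by eigenvalue
    clipping and diagonal rescaling, with a warning; if the repair moves
    any entry by more than 0.05 the targets are rejected outright.
    """
    w = np.linalg.eigvalsh(C)
    if w[0] >= -1e-10:
        return C
    eigval, eigvec = np.linalg.eigh(C)
    eigval = np.clip(eigval, 1e-10, None)
    C2 = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    dist = float(np.abs(C2 - C).max())
    if dist > 0.05:
        raise ValueError(
            f"{label} correlation targets are not positive semidefinite and "
            f"cannot be repaired (max entry distortion {dist:.3f} > 0.05): "
            f"rho_in={spec.rho_in_normal}/{spec.rho_in_predisease}, "
            f"rho_out={spec.rho_out_normal}/{spec.rho_out_predisease}, "
            f"background_rho={spec.background_rho}"
        )
    warnings.warn(
        f"{label} correlation target repaired to nearest PSD "
        f"(max entry change {dist:.4f})",
        stacklevel=3,
    )
    return C2


def _draw(
    rng: np.random.Generator,
    n: int,
    C: np.ndarray,
    sd: np.ndarray | None,
    mean_shift: float,
) -> np.ndarray:
    """n samples (columns) from N(mean_shift, diag(sd) C diag(sd))."""
    L = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))
    Z = L @ rng.standard_normal((C.shape[0], n))
    if sd is not None:
        Z = Z * sd[:, None]
    return Z + mean_shift


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort under ``spec``. Same spec + seed is bit-identical.

    Control samples come from the baseline covariance; stage A from the
    predisease covariance (inflated module SD, shifted block
    correlations); stage B from the baseline covariance plus a uniform
    mean shift on every molecule (first-order change, second-order
    structure relaxed).
    """
    rng = np.random.default_rng(spec.seed)
    C0 = _repair_psd(spec.baseline_correlation(), "baseline", spec)
    C1 = _repair_psd(spec.predisease_correlation(), "predisease", spec)
    n_ctrl, n_a, n_b = spec.group_sizes

    # per-molecule disease shift: common magnitude, molecule-specific
    # direction (some metabolites rise, others fall), fixed per cohort
    shift = spec.mean_shift_disease * rng.choice([-1.0, 1.0], size=spec.n_molecules)
    blocks = [
        _draw(rng, n_ctrl, C0, None, 0.0),
        _draw(rng, n_a, C1, spec.predisease_sd(), 0.0),
        _draw(rng, n_b, C0, None, 0.0) + shift[:, None],
    ]
    latent = np.hstack(blocks)

    if spec.log_normal:
        values = np.exp(spec.log_mean + spec.log_sd * latent)
    else:
        values = latent

    width = len(str(spec.n_molecules))
    molecules = [f"m{i + 1:0{width}d}" for i in range(spec.n_molecules)]
    samples = (
        [f"ctrl{i + 1:02d}" for i in range(n_ctrl)]
        + [f"A{i + 1:02d}" for i in range(n_a)]
        + [f"B{i + 1:02d}" for i in range(n_b)]
    )
    groups = ["control"] * n_ctrl + ["stageA"] * n_a + ["stageB"] * n_b

    if spec.dropout_rate > 0:
        # uniform dropout: censor at the detection floor of each molecule
        mask = rng.random(values.shape) < spec.dropout_rate
        floor = values.min(axis=1, keepdims=True)
        values = np.where(mask, floor, values)

    abundance = pd.DataFrame(values, index=molecules, columns=samples)
    abundance.index.name = "molecule_id"
    metadata = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    return SyntheticCohort(
        abundance=abundance,
        metadata=metadata,
        truth_module=frozenset(molecules[: spec.module_size]),
        truth_tipping_group="stageA",
        spec=spec,
    )


# committed worked-example cohort: 10 molecules x 8 samples, integer
# intensities, planted module {m1..m4}; control samples s1..s4 are the
# reference. PCC(m1, m2) over the reference is 4/5 = 0.8 by hand.
_FIXTURE_VALUES = {
    "m1": (1, 2, 3, 4, 9, 8, 3, 2),
    "m2": (1, 3, 2, 4, 8, 9, 2, 3),
    "m3": (2, 1, 4, 3, 9, 7, 3, 1),
    "m4": (5, 3, 4, 2, 10, 9, 4, 3),
    "m5": (2, 4, 3, 3, 3, 2, 6, 7),
    "m6": (1, 1, 2, 4, 2, 3, 5, 6),
    "m7": (3, 2, 2, 1, 2, 2, 5, 5),
    "m8": (4, 4, 3, 1, 3, 4, 7, 8),
    "m9": (2, 3, 1, 2, 2, 1, 5, 4),
    "m10": (1, 2, 2, 3, 3, 2, 4, 6),
}
_FIXTURE_SAMPLES = ("s1", "s2", "s3", "s4", "s5", "s6", "s7", "s8")
_FIXTURE_GROUPS = (
    "control", "control", "control", "control",
    "stageA", "stageA", "stageB", "stageB",
)


def fixture_small() -> SyntheticCohort:
    """A fixed 10-molecule, 8-sample cohort with integer-friendly values.

    Used in unit tests and documentation examples; every call returns an
    identical object. The planted module is {m1, m2, m3, m4} and the
    stage-A samples deviate strongly on it.
    """
    abundance = pd.DataFrame(
        {s: [_FIXTURE_VALUES[m][i] for m in _FIXTURE_VALUES]
         for i, s in enumerate(_FIXTURE_SAMPLES)},
        index=pd.Index(list(_FIXTURE_VALUES), name="molecule_id"),
        dtype=float,
    )
    metadata = pd.DataFrame(
        {"group": list(_FIXTURE_GROUPS)},
        index=pd.Index(list(_FIXTURE_SAMPLES), name="sample_id"),
    )
    spec = CohortSpec(
        n_molecules=10,
        group_sizes=(4, 2, 2),
        module_size=4,
        sd_inflation=3.0,
        seed=0,
        log_normal=False,
    )
    return SyntheticCohort(
        abundance=abundance,
        metadata=metadata,
        truth_module=frozenset({"m1", "m2", "m3", "m4"}),
        truth_tipping_group="stageA",
        spec=spec,
    )
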