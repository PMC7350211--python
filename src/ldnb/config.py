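"""Run configuration: every tunable knob of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, serializable to/from YAML or a dict.

    Attributes
    ----------
    alpha
        Edge significance level of the SSN test.
    tail
        Null reference for edge p-values: "volcano" (exact product-normal),
        "normal", or "permutation".
    score_form
        "ratio" (sADin * sPCCin / sPCCout) or "product".
    standardize
        z-score abundances against reference mean/SD before deviations.
    absolute_spcc
        Average |sPCC| rather than signed sPCC in the score components.
    epsilon
        Floor on sPCCout in the ratio score.
    threshold
        Global-score cutoff for the high-risk call.
    top_n, min_samples, freq_cut
        Candidate-molecule selection parameters.
    k_min, k_max, k_step
        The top-k grid of the ranking-robustness analysis.
    leave_one_out
        Score reference-group samples against a reference excluding
        themselves instead of the shared full reference.
    reference_edge_filter
        "none" or "pcc_pvalue" (pre-filter pairs by significant
        reference correlation).
    seed
        RNG seed recorded with every run (used by permutation tests and
        simulation).
    """

    alpha: float = 0.05
    tail: str = "volcano"
    score_form: str = "ratio"
    standardize: bool = True
    absolute_spcc: bool = True
    epsilon: float = 1e-6
    threshold: float = 1.0
    top_n: int = 50
    min_samples: int = 3
    freq_cut: float = 0.5
    k_min: int = 5
    k_max: int = 500
    k_step: int = 5
    leave_one_out: bool = False
    reference_edge_filter: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.tail not in ("volcano", "normal", "permutation"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.score_form not in ("ratio", "product"):
            raise ValueError(f"unknown score_form {self.score_form!r}")
        if self.reference_edge_filter not in ("none", "pcc_pvalue"):
            raise ValueError(
                f"unknown reference_edge_filter {self.reference_edge_filter!r}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 < self.freq_cut <= 1.0):
            raise ValueError("freq_cut must lie in (0, 1]")
        if min(self.top_n, self.min_samples, self.k_min, self.k_step) < 1:
            raise ValueError("top_n, min_samples, k_min, k_step must be >= 1")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    def k_grid(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1, self.k_step))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
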