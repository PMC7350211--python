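"""Cohort-level inference over global DNB scores.

Four procedures: identification of the tipping-point group (the group
whose mean global DNB score is highest), high-risk classification at a
fixed global-score threshold with TPR/FPR, a top-k ranking-robustness
analysis for a single sample of interest, and selection of candidate DNB
molecules from the predisease group's per-sample score rankings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DNBLandscape

logger = logging.getLogger(__name__)

__all__ = [
    "TippingPointResult",
    "ClassificationResult",
    "RankingRobustness",
    "CandidateSelection",
    "tipping_point",
    "classify_and_rate",
    "ranking_robustness",
    "select_candidates",
    "default_k_grid",
]


def _scores_frame(
    global_scores: pd.Series | pd.DataFrame, metadata: pd.DataFrame | None
) -> pd.DataFrame:
    """Normalize score input to columns sample_id/group/global_dnb_score."""
    if isinstance(global_scores, pd.DataFrame):
        df = global_scores[["sample_id", "group", "global_dnb_score"]].copy()
    else:
        if metadata is None:
            raise ValueError("metadata required when scores are given as a Series")
        df = pd.DataFrame(
            {
                "sample_id": global_scores.index,
                "group": metadata.loc[global_scores.index, "group"].to_numpy(),
                "global_dnb_score": global_scores.to_numpy(dtype=float),
            }
        )
    return df


@dataclass(frozen=True)
class TippingPointResult:
    """Group identified as the tipping point, with the mean/SEM table."""

    group: str
    tied_groups: tuple[str, ...]
    table: pd.DataFrame  # columns: group, n, mean, sem


def tipping_point(
    global_scores: pd.Series | pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> TippingPointResult:
    """The group with maximal mean global DNB score.

    SEM is reported as NaN for single-sample groups; exact ties are all
    reported, with a warning.
    """
    df = _scores_frame(global_scores, metadata)
    if df["group"].nunique() < 2:
        raise ValueError("tipping-point identification needs at least 2 groups")
    rows = []
    for g, sub in df.groupby("group", sort=False):
        vals = sub["global_dnb_score"].to_numpy()
        sem = float(stats.sem(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append((g, len(vals), float(vals.mean()), sem))
    table = pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])
    best = table["mean"].max()
    tied = tuple(table.loc[table["mean"] == best, "group"])
    if len(tied) > 1:
        warnings.warn(f"tied maximal group means among {tied}", stacklevel=2)
    return TippingPointResult(group=tied[0], tied_groups=tied, table=table)


@dataclass(frozen=True)
class ClassificationResult:
    """High-risk calls at a global-score threshold, with TPR/FPR."""

    threshold: float
    positive_group: str
    predictions: pd.Series  # sample_id -> bool (high-risk)
    per_group: pd.DataFrame  # columns: group, n, high_risk
    tpr: float
    fpr: float


def classify_and_rate(
    global_scores: pd.Series | pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    positive_group: str = "stageA",
    threshold: float = 1.0,
) -> ClassificationResult:
    """Call samples high-risk when global score > threshold (strictly).

    TPR is the high-risk fraction of the positive group; FPR the
    high-risk fraction of all other groups pooled.
    """
    df = _scores_frame(global_scores, metadata)
    if positive_group not in set(df["group"]):
        raise ValueError(f"positive group {positive_group!r} has no samples")
    if (df["group"] != positive_group).sum() == 0:
        raise ValueError("no negative samples: all samples are in the positive group")
    high = df["global_dnb_score"] > threshold
    per_group = (
        df.assign(high_risk=high)
        .groupby("group", sort=False)
        .agg(n=("sample_id", "size"), high_risk=("high_risk", "sum"))
        .reset_index()
    )
    pos = df["group"] == positive_group
    tpr = float(high[pos].sum() / pos.sum())
    fpr = float(high[~pos].sum() / (~pos).sum())
    return ClassificationResult(
        threshold=float(threshold),
        positive_group=positive_group,
        predictions=pd.Series(high.to_numpy(), index=df["sample_id"], name="high_risk"),
        per_group=per_group,
        tpr=tpr,
        fpr=fpr,
    )


def default_k_grid() -> list[int]:
    """k = 5, 10, ..., 500: one hundred module sizes."""
    return list(range(5, 501, 5))


@dataclass(frozen=True)
class RankingRobustness:
    """Rank of a target sample across top-k global-score recomputations."""

    target_sample: str
    k_grid: tuple[int, ...]
    ranks: tuple[int, ...]  # rank per k; 1 = highest score
    n_samples: int

    def prob_top(self, m: int) -> float:
        """Fraction of k values at which the target ranks in the top m."""
        return float(np.mean([r <= m for r in self.ranks]))

    def rank_counts(self) -> pd.Series:
        return pd.Series(self.ranks).value_counts().sort_index()


def _local_score_arrays(
    landscapes: Mapping[str, DNBLandscape | Sequence[float]],
) -> dict[str, np.ndarray]:
    out = {}
    for sid, ls in landscapes.items():
        if isinstance(ls, DNBLandscape):
            vals = np.array([s.score for s in ls.scores.values()], dtype=float)
        else:
            vals = np.asarray(ls, dtype=float)
        out[sid] = np.sort(vals)[::-1]
    return out


def ranking_robustness(
    landscapes: Mapping[str, DNBLandscape | Sequence[float]],
    target_sample: str,
    k_grid: Sequence[int] | None = None,
) -> RankingRobustness:
    """Rank the target sample as the global score is recomputed from each
    sample's top-k local scores, over a grid of k.

    For each k every sample's score is the mean of its k largest local
    scores (truncated, with a warning, to what the sample has when its
    landscape is smaller than k). Ranks are 1-based, ties broken by
    sample ID so the result is deterministic.
    """
    if target_sample not in landscapes:
        raise KeyError(f"target sample {target_sample!r} not among landscapes")
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = [int(k) for k in k_grid]
    if any(k < 1 for k in k_grid):
        raise ValueError("k values must be positive")
    sorted_scores = _local_score_arrays(landscapes)
    smallest = min(len(v) for v in sorted_scores.values())
    if max(k_grid) > smallest:
        warnings.warn(
            f"k up to {max(k_grid)} requested but the smallest landscape has "
            f"{smallest} scores; k is truncated per sample",
            stacklevel=2,
        )
    ranks = []
    for k in k_grid:
        scored = sorted(
            (
                (-(v[: min(k, len(v))].mean() if len(v) else 0.0), sid)
                for sid, v in sorted_scores.items()
            ),
        )
        rank = 1 + [sid for _, sid in scored].index(target_sample)
        ranks.append(rank)
    return RankingRobustness(
        target_sample=target_sample,
        k_grid=tuple(k_grid),
        ranks=tuple(ranks),
        n_samples=len(landscapes),
    )


@dataclass(frozen=True)
class CandidateSelection:
    """Candidate and core DNB molecules from predisease-group rankings."""

    top_lists: dict[str, tuple[str, ...]]  # sample -> its top-N molecules
    candidates: frozenset[str]  # in >= min_samples top lists
    core: frozenset[str]  # in >= freq_cut of the samples' top lists
    frequency: dict[str, float]  # molecule -> fraction of samples listing it
    top_n: int
    min_samples: int
    freq_cut: float

    def frequency_table(self) -> pd.DataFrame:
        rows = sorted(
            ((m, f) for m, f in self.frequency.items()),
            key=lambda t: (-t[1], t[0]),
        )
        df = pd.DataFrame(rows, columns=["molecule_id", "frequency"])
        df["candidate"] = df["molecule_id"].isin(self.candidates)
        df["core"] = df["molecule_id"].isin(self.core)
        return df


def _top_n(ls: DNBLandscape | Mapping[str, float], n: int) -> tuple[str, ...]:
    if isinstance(ls, DNBLandscape):
        items = [(m, s.score) for m, s in ls.scores.items()]
    else:
        items = list(ls.items())
    items.sort(key=lambda t: (-t[1], t[0]))  # score desc, ID asc for ties
    return tuple(m for m, _ in items[:n])


def select_candidates(
    stage_landscapes: Mapping[str, DNBLandscape | Mapping[str, float]],
    top_n: int = 50,
    min_samples: int = 3,
    freq_cut: float = 0.5,
) -> CandidateSelection:
    """Select candidate DNB molecules from per-sample top-N score lists.

    A molecule is a *candidate* if it appears in the top-``top_n`` list of
    at least ``min_samples`` samples, and *core* if it additionally
    appears in at least ``freq_cut`` of all samples' lists.
    """
    if len(stage_landscapes) < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} landscapes, "
            f"got {len(stage_landscapes)}"
        )
    top_lists = {
        sid: _top_n(ls, top_n) for sid, ls in sorted(stage_landscapes.items())
    }
    n_samples = len(top_lists)
    counts: dict[str, int] = {}
    for lst in top_lists.values():
        for m in lst:
            counts[m] = counts.get(m, 0) + 1
    frequency = {m: c / n_samples for m, c in counts.items()}
    candidates = frozenset(m for m, c in counts.items() if c >= min_samples)
    core = frozenset(
        m for m in candidates if frequency[m] >= freq_cut
    )
    return CandidateSelection(
        top_lists=top_lists,
        candidates=candidates,
        core=core,
        frequency=frequency,
        top_n=top_n,
        min_samples=min_samples,
        freq_cut=freq_cut,
    )
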