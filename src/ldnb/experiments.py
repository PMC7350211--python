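"""Repeatable simulation experiments at the package's study conditions.

These routines define the standing benchmarks of the method on synthetic
cohorts: null calibration of the SSN edge test, recovery of the planted
tipping point and DNB module across replicate cohorts, and specificity
under a no-effect generator. They are used by the test suite, the
acceptance script and the analysis drivers alike so every report computes
the same quantities the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import select_candidates, tipping_point
from .scoring import cohort_landscapes
from .ssn import edge_significance
from .synthetic_data import CohortSpec, generate_cohort

__all__ = [
    "null_rejection_rate",
    "RecoveryResult",
    "recovery_experiment",
    "null_specificity",
]


def null_rejection_rate(
    n_reference: int = 50,
    n_trials: int = 10000,
    alpha: float = 0.05,
    tail: str = "volcano",
    trials_per_reference: int = 100,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the SSN edge test under the null.

    For an independent Gaussian molecule pair, draws a fresh
    ``n_reference``-sample reference for every batch of
    ``trials_per_reference`` new samples, computes the differential
    correlation of each new sample and tests it at ``alpha``. Averaging
    over reference draws estimates the test's calibration rather than its
    behavior conditional on one arbitrary reference.
    """
    rng = np.random.default_rng(seed)
    n_batches = int(np.ceil(n_trials / trials_per_reference))
    rejected = 0
    total = 0
    for _ in range(n_batches):
        X = rng.standard_normal((2, n_reference))
        x, y = X
        pcc_n = float(np.corrcoef(X)[0, 1])
        k = min(trials_per_reference, n_trials - total)
        D = rng.standard_normal((2, k))
        # perturbed PCC for each new sample, by definition on n+1 points
        sx, sy = x.sum(), y.sum()
        sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
        N = n_reference + 1
        mx = (sx + D[0]) / N
        my = (sy + D[1]) / N
        cxy = (sxy + D[0] * D[1]) - N * mx * my
        cxx = (sxx + D[0] ** 2) - N * mx**2
        cyy = (syy + D[1] ** 2) - N * my**2
        pcc_n1 = cxy / np.sqrt(cxx * cyy)
        _, p = edge_significance(pcc_n1 - pcc_n, pcc_n, n_reference, tail=tail)
        rejected += int((p < alpha).sum())
        total += k
    return rejected / total


@dataclass(frozen=True)
class RecoveryResult:
    """Per-replicate outcomes of the planted-module recovery experiment."""

    table: pd.DataFrame  # replicate, tipping_group, candidate_recovery
    tipping_rate: float  # fraction of replicates with stage A on top
    mean_candidate_recovery: float  # planted molecules in the candidate set


def recovery_experiment(
    n_replicates: int = 20,
    spec: CohortSpec | None = None,
    seed: int = 0,
    **landscape_kwargs,
) -> RecoveryResult:
    """Strong-effect parameter recovery across replicate cohorts.

    Each replicate draws a fresh cohort from ``spec`` (reseeded), scores
    every sample, and records whether stage A has the highest group-mean
    global DNB score and what fraction of the planted module enters the
    candidate molecule set.
    """
    if spec is None:
        spec = CohortSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r, s in enumerate(seeds):
        cohort = generate_cohort(
            CohortSpec(**{**_spec_dict(spec), "seed": int(s)})
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            landscapes, scores = cohort_landscapes(
                cohort.abundance, cohort.metadata, **landscape_kwargs
            )
        tp = tipping_point(scores)
        stage_ids = cohort.group_samples["stageA"]
        sel = select_candidates({sid: landscapes[sid] for sid in stage_ids})
        recovery = len(cohort.truth_module & sel.candidates) / len(
            cohort.truth_module
        )
        rows.append((r, tp.group, recovery))
    table = pd.DataFrame(
        rows, columns=["replicate", "tipping_group", "candidate_recovery"]
    )
    return RecoveryResult(
        table=table,
        tipping_rate=float((table["tipping_group"] == "stageA").mean()),
        mean_candidate_recovery=float(table["candidate_recovery"].mean()),
    )


def null_specificity(
    n_replicates: int = 20,
    spec: CohortSpec | None = None,
    seed: int = 0,
    **landscape_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Group effect on global DNB scores under the no-effect generator.

    Draws ``n_replicates`` null cohorts (stage A distributionally
    identical to control, no disease shift), records each group's mean
    global score per replicate, and Kruskal-Wallis-tests the three
    groups' replicate-level means for a location difference. Returns the
    p-value (large = no spurious group effect) and the per-replicate
    table.

    Samples are scored with leave-one-out references by default: under
    the shared-reference rule, reference-group samples are part of their
    own reference and score systematically lower even under the null, so
    only leave-one-out scoring makes the three groups exchangeable and
    the specificity test meaningful.
    """
    landscape_kwargs.setdefault("leave_one_out", True)
    base = (spec or CohortSpec()).null()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r, s in enumerate(seeds):
        cohort = generate_cohort(
            CohortSpec(**{**_spec_dict(base), "seed": int(s)})
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, scores = cohort_landscapes(
                cohort.abundance, cohort.metadata, **landscape_kwargs
            )
        means = scores.groupby("group")["global_dnb_score"].mean()
        rows.append((r, means["control"], means["stageA"], means["stageB"]))
    table = pd.DataFrame(
        rows, columns=["replicate", "control", "stageA", "stageB"]
    )
    stat, p = stats.kruskal(table["control"], table["stageA"], table["stageB"])
    return float(p), table


def _spec_dict(spec: CohortSpec) -> dict:
    import dataclasses

    return dataclasses.asdict(spec)
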