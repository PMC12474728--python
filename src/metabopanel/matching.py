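"""Case-control matching by a weighted standardized dissimilarity score.

For a case-control pair the score is a zero-covariance special case of the
Mahalanobis distance over four covariates, in pooled-SD (Z) units:

    score = ( 3·[(ΔGA1/SD_GA1 + ΔGA2/SD_GA2)/2] + 2·ΔAge/SD_age
              + 1·ΔBMI/SD_BMI ) / 6

with Δ the absolute case-control difference, gestational age at the two urine
collections averaged and weighted 3, maternal age weighted 2, and
pre-pregnancy BMI weighted 1. Controls are selected one-to-one from a larger
pool, by default minimizing the total score over all assignments (min-cost
bipartite matching); a greedy policy that repeatedly takes the smallest
remaining pair is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import GROUP_CASE, GROUP_CONTROL
from .errors import ConfigurationError, DataError

COVARIATES = ("ga1", "ga2", "age", "bmi")


@dataclass(frozen=True)
class CovariateVector:
    """Matching covariates of one gravida: gestational ages at the early and
    late urine collections (weeks), maternal age (years), pre-pregnancy BMI
    (kg/m²)."""

    ga1: float
    ga2: float
    age: float
    bmi: float

    def __post_init__(self):
        for f in COVARIATES:
            if not np.isfinite(getattr(self, f)):
                raise DataError(f"covariate {f} must be finite")


@dataclass(frozen=True)
class PooledSDs:
    """Pooled standard deviations of the four matching covariates."""

    ga1: float
    ga2: float
    age: float
    bmi: float

    def __post_init__(self):
        for f in COVARIATES:
            if not getattr(self, f) > 0:
                raise DataError(f"pooled SD for {f} must be > 0")


@dataclass(frozen=True)
class MatchSet:
    """One-to-one matched pairs with their dissimilarity scores."""

    pairs: tuple[tuple[str, str, float], ...]  # (case_id, control_id, score)
    policy: str

    @property
    def mean(self) -> float:
        return float(np.mean([s for _, _, s in self.pairs]))

    @property
    def sd(self) -> float:
        scores = [s for _, _, s in self.pairs]
        return float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [k for _, k, _ in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id", "score"])


def pooled_sd(values_a, values_b) -> float:
    """Pooled SD: square root of the (n_g − 1)-weighted mean of group variances."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("pooled SD needs at least two values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        raise DataError("zero variance in both groups; standardized score undefined")
    return float(np.sqrt(pooled))


def dissimilarity_score(case: CovariateVector, control: CovariateVector,
                        sds: PooledSDs) -> float:
    """Weighted standardized dissimilarity of one case-control pair (SD units)."""
    d_ga1 = abs(case.ga1 - control.ga1) / sds.ga1
    d_ga2 = abs(case.ga2 - control.ga2) / sds.ga2
    d_age = abs(case.age - control.age) / sds.age
    d_bmi = abs(case.bmi - control.bmi) / sds.bmi
    return (3.0 * (d_ga1 + d_ga2) / 2.0 + 2.0 * d_age + 1.0 * d_bmi) / 6.0


def compute_pooled_sds(cases: pd.DataFrame, pool: pd.DataFrame) -> PooledSDs:
    """Pooled SDs of the matching covariates from the cases and the entire
    candidate pool (SDs must exist before any selection)."""
    return PooledSDs(**{c: pooled_sd(cases[c], pool[c]) for c in COVARIATES})


def score_matrix(cases: pd.DataFrame, pool: pd.DataFrame, sds: PooledSDs) -> pd.DataFrame:
    """Dense cases × pool matrix of dissimilarity scores.

    Rows are indexed by case id and columns by control id; entry (i, j) equals
    ``dissimilarity_score`` of that pair.
    """
    if len(pool) < len(cases):
        raise DataError(
            f"control pool ({len(pool)}) smaller than case count ({len(cases)})"
        )
    weights = {"ga1": 3.0 / 2.0, "ga2": 3.0 / 2.0, "age": 2.0, "bmi": 1.0}
    total = np.zeros((len(cases), len(pool)))
    for cov, w in weights.items():
        diff = np.abs(
            cases[cov].to_numpy(dtype=float)[:, None]
            - pool[cov].to_numpy(dtype=float)[None, :]
        )
        total += w * diff / getattr(sds, cov)
    return pd.DataFrame(total / 6.0, index=cases.index, columns=pool.index)


def select_matches(scores: pd.DataFrame, policy: str = "optimal") -> MatchSet:
    """One-to-one assignment of every case to a distinct control.

    ``optimal`` minimizes the total score over all assignments (min-cost
    bipartite matching); ``greedy`` repeatedly takes the globally smallest
    remaining (case, control) entry, ties broken by (case id, control id).
    """
    n_cases, n_pool = scores.shape
    if n_pool < n_cases:
        raise DataError(f"control pool ({n_pool}) smaller than case count ({n_cases})")
    cost = scores.to_numpy(dtype=float)
    if policy == "optimal":
        rows, cols = linear_sum_assignment(cost)
        order = np.argsort(rows)
        pairs = tuple(
            (str(scores.index[r]), str(scores.columns[c]), float(cost[r, c]))
            for r, c in zip(rows[order], cols[order])
        )
    elif policy == "greedy":
        entries = sorted(
            ((float(cost[i, j]), str(scores.index[i]), str(scores.columns[j]), i, j)
             for i in range(n_cases) for j in range(n_pool)),
            key=lambda e: (e[0], e[1], e[2]),
        )
        used_cases: set[int] = set()
        used_controls: set[int] = set()
        chosen = {}
        for s, case_id, control_id, i, j in entries:
            if i in used_cases or j in used_controls:
                continue
            used_cases.add(i)
            used_controls.add(j)
            chosen[i] = (case_id, control_id, s)
            if len(chosen) == n_cases:
                break
        pairs = tuple(chosen[i] for i in sorted(chosen))
    else:
        raise ConfigurationError(f"unknown matching policy {policy!r}")
    return MatchSet(pairs=pairs, policy=policy)


def match_cohort(subjects: pd.DataFrame, policy: str = "optimal") -> MatchSet:
    """Match every case to a control drawn from the full pool of controls."""
    cases = subjects[subjects["group"] == GROUP_CASE]
    pool = subjects[subjects["group"] == GROUP_CONTROL]
    if cases.empty or pool.empty:
        raise DataError("both GDM cases and CON controls are required for matching")
    sds = compute_pooled_sds(cases, pool)
    return select_matches(score_matrix(cases, pool, sds), policy=policy)
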