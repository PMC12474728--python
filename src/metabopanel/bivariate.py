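"""One-metabolite-at-a-time screening.

Per-metabolite standardized effect sizes on the normalized log scale
(d = (mean GDM − mean CON) / pooled SD, t-test P, nominal), group comparisons
for demographics (t-test / Wilcoxon rank-sum / Fisher exact), and a
single-marker optimal-cutpoint ranking by unweighted accuracy. P values are
reported nominal; no multiple-testing correction is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DataError
from .matching import pooled_sd


@dataclass(frozen=True)
class EffectSize:
    """Standardized group difference of one metabolite, GDM minus CON, in
    pooled-SD units on the log scale, with its nominal two-sided t-test P."""

    metabolite: str
    d: float
    p_value: float


@dataclass(frozen=True)
class CutpointResult:
    """Best single-marker cutpoint: threshold, orientation, and the
    resulting sensitivity/specificity/unweighted accuracy (all %)."""

    threshold: float
    orientation: str  # "high" = values >= threshold called case, "low" = values < threshold
    sensitivity: float
    specificity: float
    accuracy: float
    constant: bool = False  # flag: marker had a single unique value


def effect_size(values_gdm, values_con, metabolite: str = "") -> EffectSize:
    """d = (mean GDM − mean CON)/pooled SD with a two-sample (pooled-variance)
    t-test P; metabolites are treated as normal on the log scale."""
    a = np.asarray(values_gdm, dtype=float)
    b = np.asarray(values_con, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("effect size needs at least two values per group")
    sd = pooled_sd(a, b)  # raises on zero pooled SD
    d = (a.mean() - b.mean()) / sd
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return EffectSize(metabolite=metabolite, d=float(d), p_value=p)


def group_compare(values_a, values_b, kind: str) -> float:
    """Two-sided P for a two-group comparison.

    kind = "normal" → pooled t-test; "nonnormal" → Wilcoxon rank-sum
    (Mann-Whitney); "categorical" → Fisher exact on the category × group
    contingency table.
    """
    if kind == "categorical":
        a = pd.Series(values_a)
        b = pd.Series(values_b)
        if len(a) < 2 or len(b) < 2:
            raise DataError("need at least two observations per group")
        cats = sorted(set(a) | set(b))
        table = np.array(
            [[int((a == c).sum()) for c in cats], [int((b == c).sum()) for c in cats]]
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            return 1.0
        return float(stats.fisher_exact(table).pvalue)

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need at least two observations per group")
    if kind == "normal":
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
        return 1.0 if np.isnan(p) else float(p)
    if kind == "nonnormal":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ConfigurationError(f"unknown comparison kind {kind!r}")


def single_marker_accuracy(values, is_case) -> CutpointResult:
    """Exhaustive optimal-cutpoint search for one marker.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values; both orientations are tried (high values called case, or low
    values called case, i.e. ``x < t`` positive). Returns the cutpoint
    maximizing unweighted accuracy = (sensitivity + specificity)/2, ties
    broken toward the larger sensitivity, then the smaller threshold, then the
    "high" orientation. A constant marker is flagged and scored 50%.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("need at least one sample per class")

    uniq = np.unique(x)
    if len(uniq) == 1:
        return CutpointResult(
            threshold=float(uniq[0]), orientation="high",
            sensitivity=100.0, specificity=0.0, accuracy=50.0, constant=True,
        )
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0

    # sens/spec at every threshold, vectorized over thresholds
    ge = x[None, :] >= thresholds[:, None]  # predicted case under "high"
    tp_high = (ge & y[None, :]).sum(axis=1)
    fp_high = (ge & ~y[None, :]).sum(axis=1)
    sens_high = 100.0 * tp_high / n_pos
    spec_high = 100.0 * (n_neg - fp_high) / n_neg
    sens_low = 100.0 * (n_pos - tp_high) / n_pos
    spec_low = 100.0 * fp_high / n_neg

    sens_all = np.concatenate([sens_high, sens_low])
    spec_all = np.concatenate([spec_high, spec_low])
    acc_all = (sens_all + spec_all) / 2.0
    thr_all = np.concatenate([thresholds, thresholds])
    is_high = np.concatenate(
        [np.ones_like(thresholds), np.zeros_like(thresholds)]
    )
    # lexsort: accuracy desc, then sensitivity desc, then threshold asc,
    # then "high" orientation first
    i = int(np.lexsort((-is_high, thr_all, -sens_all, -acc_all))[0])
    return CutpointResult(
        threshold=float(thr_all[i]),
        orientation="high" if is_high[i] else "low",
        sensitivity=float(sens_all[i]),
        specificity=float(spec_all[i]),
        accuracy=float(acc_all[i]),
    )


def rank_markers(matrix: pd.DataFrame, is_case) -> pd.DataFrame:
    """Per-metabolite optimal-cutpoint metrics, sorted by descending
    unweighted accuracy; ties ordered by metabolite id."""
    rows = []
    for met in matrix.columns:
        r = single_marker_accuracy(matrix[met].to_numpy(), is_case)
        rows.append(
            {
                "metabolite": met,
                "threshold": r.threshold,
                "orientation": r.orientation,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
                "constant": r.constant,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["accuracy", "metabolite"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out


def effect_table(matrix: pd.DataFrame, is_case, annotations: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """Candidate-marker style table: metabolite, pathway, effect size d on the
    log scale (GDM − CON), and nominal P, ordered by |d| descending."""
    y = np.asarray(is_case, dtype=bool)
    rows = []
    for met in matrix.columns:
        es = effect_size(matrix[met].to_numpy()[y], matrix[met].to_numpy()[~y], met)
        pathway = ""
        if annotations is not None and met in annotations.index:
            pathway = str(annotations.loc[met].get("pathway", ""))
        rows.append(
            {"metabolite": met, "pathway": pathway, "d": es.d, "nominal_p": es.p_value}
        )
    out = pd.DataFrame(rows)
    return out.reindex(
        out["d"].abs().sort_values(ascending=False, kind="mergesort").index
    ).reset_index(drop=True)


class SingleMarkerRanker(BaseEstimator):
    """Estimator wrapper over :func:`rank_markers`.

    ``fit(X, y)`` computes the per-marker optimal-cutpoint ranking into
    ``ranking_`` (X as a DataFrame keeps metabolite names; y is a boolean or
    {GDM, CON}-like case indicator).
    """

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = _as_case_indicator(y)
        if len(y) != len(X):
            raise DataError("X and y lengths differ")
        self.ranking_ = rank_markers(X, y)
        self.n_features_in_ = X.shape[1]
        return self


def _as_case_indicator(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return y
    if y.dtype.kind in "iuf":
        return y.astype(bool)
    return y == "GDM"
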