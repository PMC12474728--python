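"""Consensus multivariate marker selection.

Every metabolite is ranked under three ensemble importance criteria:

1. random-forest permutation importance — the mean over trees of the drop in
   out-of-bag accuracy when the feature's out-of-bag values are permuted;
2. random-forest Gini worsening — the sample-weighted total Gini impurity
   decrease attributable to splits on the feature, averaged over trees;
3. gradient-boosting relative influence — the per-feature share of split
   improvement in a stagewise boosted ensemble of shallow trees on the
   binomial deviance, normalized so all influences sum to 100.

The consensus candidate set is the intersection of the top-k sets (k = 30 by
default) under all three criteria; the ≥2-criterion overlap and the union are
reported alongside as diagnostics.

The forest is assembled from scikit-learn decision trees over explicit
bootstrap draws so that per-tree out-of-bag indices are available for the
permutation criterion; the boosted ensemble is scikit-learn's gradient
boosting machine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataError

#: Conventional ensemble defaults, fixed for reproducibility.
FOREST_DEFAULTS = {"n_trees": 500, "max_features": "sqrt", "min_samples_leaf": 2}
BOOSTING_DEFAULTS = {
    "n_stages": 200,
    "max_depth": 2,
    "learning_rate": 0.1,
    "subsample": 0.5,
}

DEFAULT_TOP_K = 30


@dataclass(frozen=True)
class ConsensusResult:
    """Top-k sets per criterion and their overlap structure. The final
    candidate list is the three-way intersection."""

    k: int
    sets: dict[str, tuple[str, ...]]
    union: tuple[str, ...]
    at_least_two: tuple[str, ...]
    intersection: tuple[str, ...]

    @property
    def candidates(self) -> tuple[str, ...]:
        return self.intersection

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "sets": {c: list(s) for c, s in self.sets.items()},
            "union": list(self.union),
            "at_least_two": list(self.at_least_two),
            "intersection": list(self.intersection),
            "candidates": list(self.candidates),
        }


def _check_input(X: pd.DataFrame, y: np.ndarray) -> None:
    if len(X) < 10:
        raise DataError("ensemble importances need at least 10 samples")
    if len(np.unique(y)) != 2:
        raise DataError("binary labels required")


def forest_importances(
    matrix: pd.DataFrame,
    is_case,
    n_trees: int = FOREST_DEFAULTS["n_trees"],
    max_features=FOREST_DEFAULTS["max_features"],
    min_samples_leaf: int = FOREST_DEFAULTS["min_samples_leaf"],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-metabolite permutation importance and Gini worsening from a
    bootstrap forest of randomized trees.

    For each tree grown on a bootstrap draw, the out-of-bag (OOB) accuracy is
    compared with the OOB accuracy after permuting one feature's OOB values;
    the mean decrease over trees is that feature's permutation importance.
    Gini worsening is the sample-weighted total impurity decrease of the
    feature's splits, averaged over trees. Deterministic given ``seed``.
    """
    X = pd.DataFrame(matrix)
    y = np.asarray(pd.Series(is_case).to_numpy())
    _check_input(X, y)
    n, p = X.shape
    # float32: the dtype sklearn trees use internally, allowing
    # validation-free predict on the stacked permutation batches
    values = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    y_codes = pd.factorize(pd.Series(y), sort=True)[0]

    rng = np.random.default_rng(seed)
    perm_sum = np.zeros(p)
    gini_sum = np.zeros(p)
    n_oob_trees = 0
    chunk = 64  # features per stacked-predict batch

    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(values[boot], y_codes[boot])
        gini_sum += tree.tree_.compute_feature_importances(normalize=False)
        if len(oob) == 0:
            continue
        n_oob_trees += 1
        x_oob = values[oob]
        y_oob = y_codes[oob]
        base_acc = float(np.mean(tree.predict(x_oob, check_input=False) == y_oob))
        m = len(oob)
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            stacked = np.tile(x_oob, (len(feats), 1))
            for b, f in enumerate(feats):
                block = slice(b * m, (b + 1) * m)
                stacked[block, f] = x_oob[rng.permutation(m), f]
            pred = tree.predict(stacked, check_input=False)
            for b, f in enumerate(feats):
                acc = float(np.mean(pred[b * m : (b + 1) * m] == y_oob))
                perm_sum[f] += base_acc - acc

    if n_oob_trees == 0:
        raise DataError("no tree had out-of-bag samples; cannot compute permutation importance")
    out = pd.DataFrame(
        {
            "perm_importance": perm_sum / n_oob_trees,
            "gini_worsening": gini_sum / n_trees,
        },
        index=X.columns,
    )
    out.index.name = "metabolite"
    return out


def boosting_influence(
    matrix: pd.DataFrame,
    is_case,
    n_stages: int = BOOSTING_DEFAULTS["n_stages"],
    max_depth: int = BOOSTING_DEFAULTS["max_depth"],
    learning_rate: float = BOOSTING_DEFAULTS["learning_rate"],
    subsample: float = BOOSTING_DEFAULTS["subsample"],
    seed: int = 0,
) -> pd.Series:
    """Gradient-boosting relative influence per metabolite (sums to 100).

    Stagewise boosting of shallow trees on the binomial deviance; a feature's
    influence is its accumulated split improvement across the ensemble,
    normalized to a percent of the total.
    """
    X = pd.DataFrame(matrix)
    y = np.asarray(pd.Series(is_case).to_numpy())
    _check_input(X, y)
    gbm = GradientBoostingClassifier(
        n_estimators=n_stages,
        max_depth=max_depth,
        learning_rate=learning_rate,
        subsample=subsample,
        random_state=seed,
    ).fit(X.to_numpy(dtype=float), pd.factorize(pd.Series(y), sort=True)[0])
    influence = pd.Series(
        100.0 * gbm.feature_importances_, index=X.columns, name="relative_influence"
    )
    influence.index.name = "metabolite"
    return influence


def importance_table(
    matrix: pd.DataFrame, is_case, seed: int = 0,
    forest_params: dict | None = None, boosting_params: dict | None = None,
) -> pd.DataFrame:
    """All three criteria with integer ranks (1 = most important; ties broken
    by metabolite id)."""
    forest = forest_importances(matrix, is_case, seed=seed, **(forest_params or {}))
    influence = boosting_influence(matrix, is_case, seed=seed, **(boosting_params or {}))
    table = forest.join(influence)
    for col in ("perm_importance", "gini_worsening", "relative_influence"):
        # descending value with metabolite-id tie-break
        order = table.reset_index().sort_values(
            [col, "metabolite"], ascending=[False, True], kind="mergesort"
        )["metabolite"]
        rank = pd.Series(np.arange(1, len(order) + 1), index=order)
        table[f"rank_{col}"] = rank.reindex(table.index).astype(int)
    return table


def scree_topk(values: pd.Series, k: int = DEFAULT_TOP_K, elbow: bool = False
               ) -> tuple[str, ...]:
    """Top-k set under one criterion, ordered by descending value with
    metabolite-id tie-break (deterministic at the boundary).

    With ``elbow=True``, k is chosen at the maximum second difference of the
    sorted importance curve (the sharpest kink), ignoring the requested k.
    """
    values = pd.Series(values)
    p = len(values)
    ordered = values.reset_index()
    ordered.columns = ["metabolite", "value"]
    ordered = ordered.sort_values(
        ["value", "metabolite"], ascending=[False, True], kind="mergesort"
    )
    v = ordered["value"].to_numpy(dtype=float)
    if elbow:
        if p < 3:
            raise DataError("elbow detection needs at least three values")
        first_diff = v[:-1] - v[1:]
        second_diff = first_diff[1:] - first_diff[:-1]
        k = int(np.argmax(second_diff)) + 2  # kink after position k
    if not (1 <= k <= p):
        raise ConfigurationError(f"k={k} out of range for {p} metabolites")
    if np.all(v == v[0]):
        warnings.warn("all importance values equal; top-k is id-ordered")
    return tuple(str(m) for m in ordered["metabolite"].head(k))


def consensus_select(set_a, set_b, set_c, k: int | None = None,
                     names=("perm_importance", "gini_worsening", "relative_influence")
                     ) -> ConsensusResult:
    """Union, ≥2-criterion overlap, and three-way intersection of the top sets.

    The final candidates are the three-way intersection; all outputs are
    sorted by metabolite id for determinism.
    """
    sets = {n: tuple(sorted(map(str, s))) for n, s in zip(names, (set_a, set_b, set_c))}
    a, b, c = (set(s) for s in sets.values())
    union = a | b | c
    at_least_two = (a & b) | (a & c) | (b & c)
    intersection = a & b & c
    return ConsensusResult(
        k=k if k is not None else max(map(len, sets.values()), default=0),
        sets=sets,
        union=tuple(sorted(union)),
        at_least_two=tuple(sorted(at_least_two)),
        intersection=tuple(sorted(intersection)),
    )


class ConsensusImportanceSelector(TransformerMixin, BaseEstimator):
    """Feature selector: fit the three importance criteria, keep the
    consensus (three-way top-k intersection) metabolites.

    Parameters mirror the module-level defaults; ``random_state`` seeds both
    ensembles. After ``fit``, ``importance_table_`` holds values and ranks per
    criterion and ``consensus_`` the set structure; ``transform`` restricts a
    matrix to the candidate metabolites.
    """

    def __init__(self, k: int = DEFAULT_TOP_K, elbow: bool = False,
                 n_trees: int = FOREST_DEFAULTS["n_trees"],
                 min_samples_leaf: int = FOREST_DEFAULTS["min_samples_leaf"],
                 n_stages: int = BOOSTING_DEFAULTS["n_stages"],
                 boost_depth: int = BOOSTING_DEFAULTS["max_depth"],
                 learning_rate: float = BOOSTING_DEFAULTS["learning_rate"],
                 subsample: float = BOOSTING_DEFAULTS["subsample"],
                 random_state: int = 0):
        self.k = k
        self.elbow = elbow
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.n_stages = n_stages
        self.boost_depth = boost_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        table = importance_table(
            X, y, seed=self.random_state,
            forest_params={
                "n_trees": self.n_trees, "min_samples_leaf": self.min_samples_leaf,
            },
            boosting_params={
                "n_stages": self.n_stages, "max_depth": self.boost_depth,
                "learning_rate": self.learning_rate, "subsample": self.subsample,
            },
        )
        tops = [
            scree_topk(table[c], k=self.k, elbow=self.elbow)
            for c in ("perm_importance", "gini_worsening", "relative_influence")
        ]
        consensus = consensus_select(*tops, k=self.k)
        assert set(consensus.intersection) <= set(consensus.at_least_two) \
            <= set(consensus.union), "consensus set nesting violated"
        self.importance_table_ = table
        self.consensus_ = consensus
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        selected = set(self.consensus_.candidates)
        return np.array([m in selected for m in self.feature_names_in_])

    def transform(self, X):
        X = pd.DataFrame(X)
        keep = [m for m in X.columns if m in set(self.consensus_.candidates)]
        return X[keep]
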