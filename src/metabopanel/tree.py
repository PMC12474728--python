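"""Depth-limited classification tree over a candidate metabolite panel.

The final predictive model is a CART-style tree grown by greedy recursive
partitioning: at every node the split minimizing the child-size-weighted Gini
impurity is chosen by exhaustive search over the panel metabolites and the
midpoints between consecutive sorted unique values. The condition at a node
is strict (``x < t``); samples satisfying it traverse to the left (true)
branch. Growth stops at a configurable number of levels (root = level 1, so a
five-level tree performs at most four nested splits on any path), at the
minimum leaf size, or at a pure node. No pruning is applied, and evaluation
is by resubstitution unless a cross-validation split is supplied externally.

The conventions above (strict threshold, midpoint candidates, deterministic
(feature id, smaller threshold) tie-break, leaf case-proportion scores) are
part of the model contract, which is why the learner is implemented here
rather than delegated to a generic CART library.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import EARLY_PANEL, GROUP_CASE, GROUP_CONTROL, LATE_PANEL
from .errors import DataError
from .metrics import MetricsReport, report_from_predictions


@dataclass
class TreeNode:
    """Internal node (metabolite + threshold, ``x < threshold`` → left) or,
    when ``metabolite`` is None, a leaf carrying the training class
    composition."""

    metabolite: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    n: int = 0
    n_case: int = 0
    level: int = 1

    @property
    def is_leaf(self) -> bool:
        return self.metabolite is None

    @property
    def p_case(self) -> float:
        return self.n_case / self.n if self.n else 0.0

    @property
    def label(self) -> str:
        return GROUP_CASE if self.n_case * 2 >= self.n else GROUP_CONTROL

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "class": self.label,
                "p_case": self.p_case,
                "n": self.n,
            }
        return {
            "leaf": False,
            "metabolite": self.metabolite,
            "threshold": self.threshold,
            "n": self.n,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _gini(n_case: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = n_case / n
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                min_leaf: int) -> tuple[int, float] | None:
    """Exhaustive (feature, midpoint-threshold) search minimizing the weighted
    Gini impurity of the children; ties broken by (feature name, smaller
    threshold). Features are scanned in name order."""
    n = len(y)
    best: tuple[float, str, float, int] | None = None
    for j in sorted(range(X.shape[1]), key=lambda j: feature_names[j]):
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        distinct = np.nonzero(np.diff(xs))[0]  # split after position i
        for i in distinct:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            c_left = int(ys[: n_left].sum())
            c_right = int(ys.sum()) - c_left
            impurity = (n_left * _gini(c_left, n_left)
                        + n_right * _gini(c_right, n_right)) / n
            threshold = (xs[i] + xs[i + 1]) / 2.0
            key = (impurity, feature_names[j], threshold)
            if best is None or key < (best[0], best[1], best[2]):
                best = (impurity, feature_names[j], float(threshold), j)
    if best is None:
        return None
    return best[3], best[2]


class PanelTreeClassifier(ClassifierMixin, BaseEstimator):
    """Depth-limited classification tree on a metabolite panel.

    Parameters
    ----------
    max_depth : int, default 5
        Maximum number of tree levels; the root is level 1, so the default
        allows at most four nested splits on any root-to-leaf path.
    min_samples_leaf : int, default 5
        Minimum samples in each child of a split.
    panel : sequence of str, optional
        Restrict fitting to these columns of X (X must be a DataFrame).

    Attributes
    ----------
    tree_ : TreeNode
        Fitted root node.
    classes_ : ndarray
        Class labels (case label last).
    feature_names_in_ : ndarray of str
        Panel metabolites used for fitting.
    """

    def __init__(self, max_depth: int = 5, min_samples_leaf: int = 5,
                 panel=None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.panel = panel

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if self.panel is not None:
            missing = [m for m in self.panel if m not in X.columns]
            if missing:
                raise DataError(f"panel metabolite(s) not in matrix: {missing}")
            X = X[list(self.panel)]
        if X.shape[1] == 0:
            raise DataError("empty metabolite panel")
        if self.max_depth < 1:
            raise DataError("max_depth must be >= 1")
        y = np.asarray(y)
        if len(y) != len(X):
            raise DataError("X and y lengths differ")
        is_case = _case_indicator(y)
        self.classes_ = np.array([GROUP_CONTROL, GROUP_CASE])
        if is_case.all() or not is_case.any():
            warnings.warn("single-class training data; fitting a single-leaf tree")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        values = X.to_numpy(dtype=float)
        names = [str(c) for c in X.columns]
        self.tree_ = self._grow(values, is_case, names, level=1)
        self.depth_ = _depth(self.tree_)
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, names: list[str],
              level: int) -> TreeNode:
        node = TreeNode(n=len(y), n_case=int(y.sum()), level=level)
        pure = node.n_case in (0, node.n)
        if pure or level >= self.max_depth or node.n < 2 * self.min_samples_leaf:
            return node
        split = _best_split(X, y, names, self.min_samples_leaf)
        if split is None:
            return node
        j, threshold = split
        mask = X[:, j] < threshold
        node.metabolite = names[j]
        node.threshold = threshold
        node.left = self._grow(X[mask], y[mask], names, level + 1)
        node.right = self._grow(X[~mask], y[~mask], names, level + 1)
        return node

    # -- prediction ------------------------------------------------------

    def _leaf_for(self, row: pd.Series) -> TreeNode:
        node = self.tree_
        while not node.is_leaf:
            if node.metabolite not in row.index:
                raise DataError(f"sample missing panel metabolite {node.metabolite!r}")
            value = row[node.metabolite]
            # strict condition: x < t goes left; x == t is false, goes right
            node = node.left if value < node.threshold else node.right
        return node

    def _leaves(self, X) -> list[TreeNode]:
        X = pd.DataFrame(X)
        if not hasattr(self, "tree_"):
            raise DataError("classifier is not fitted")
        missing = [m for m in self.feature_names_in_ if m not in X.columns]
        if missing:
            raise DataError(f"sample(s) missing panel metabolite(s): {missing}")
        return [self._leaf_for(X.iloc[i]) for i in range(len(X))]

    def predict(self, X) -> np.ndarray:
        return np.array([leaf.label for leaf in self._leaves(X)], dtype=object)

    def predict_proba(self, X) -> np.ndarray:
        p_case = np.array([leaf.p_case for leaf in self._leaves(X)])
        return np.column_stack([1.0 - p_case, p_case])

    def decision_scores(self, X) -> np.ndarray:
        """Leaf training case-proportion for each sample (the ROC score)."""
        return np.array([leaf.p_case for leaf in self._leaves(X)])

    # -- reporting -------------------------------------------------------

    def to_dict(self, value_scale: str = "log median-scaled, osmolality-corrected"
                ) -> dict:
        return {
            "model": "classification_tree",
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "depth": self.depth_,
            "value_scale": value_scale,
            "panel": [str(m) for m in self.feature_names_in_],
            "root": self.tree_.to_dict(),
        }

    def to_json(self, path, **kwargs) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(**kwargs), fh, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}{prefix}leaf: {node.label} "
                    f"(p_case={node.p_case:.3f}, n={node.n})"
                )
            else:
                lines.append(
                    f"{pad}{prefix}{node.metabolite} < {node.threshold:.4g} "
                    f"(n={node.n})"
                )
                walk(node.left, indent + 1, "[+] ")
                walk(node.right, indent + 1, "[-] ")

        walk(self.tree_, 0, "")
        return "\n".join(lines)


def _depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return 1 + max(_depth(node.left), _depth(node.right))


def _case_indicator(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return y
    if y.dtype.kind in "iuf":
        return y.astype(bool)
    return y == GROUP_CASE


def fit_tree(matrix: pd.DataFrame, is_case, panel=None, max_depth: int = 5,
             min_samples_leaf: int = 5) -> PanelTreeClassifier:
    """Fit a depth-limited tree on the given panel (all columns by default)."""
    clf = PanelTreeClassifier(
        max_depth=max_depth, min_samples_leaf=min_samples_leaf, panel=panel
    )
    return clf.fit(matrix, is_case)


def evaluate(clf: PanelTreeClassifier, matrix: pd.DataFrame, is_case) -> MetricsReport:
    """Sensitivity/specificity/unweighted-accuracy/ROC-AUC of a fitted tree.

    The AUC scores each sample by its leaf's training case proportion, with
    ties counted 1/2.
    """
    y = _case_indicator(np.asarray(is_case))
    if y.all() or not y.any():
        raise DataError("evaluation requires both classes present")
    pred = clf.predict(matrix) == GROUP_CASE
    scores = clf.decision_scores(matrix)
    return report_from_predictions(y, pred, scores)


def compare_panels(
    matrix: pd.DataFrame,
    is_case,
    panel_late=None,
    panel_early=None,
    max_depth: int = 5,
    min_samples_leaf: int = 5,
) -> dict[str, dict]:
    """Fit and evaluate one tree per candidate panel under identical settings.

    Defaults: the eight-consensus-metabolite late-pregnancy panel and the
    seven-metabolite first-trimester model panel (used as a fixed feature
    list). Returns ``{"late": {"tree": ..., "report": ...}, "early": ...}``.
    """
    panel_late = list(panel_late) if panel_late is not None else list(LATE_PANEL)
    panel_early = list(panel_early) if panel_early is not None else list(EARLY_PANEL)
    out = {}
    for name, panel in (("late", panel_late), ("early", panel_early)):
        unknown = [m for m in panel if m not in matrix.columns]
        if unknown:
            raise DataError(f"{name} panel metabolite(s) not in matrix: {unknown}")
        clf = fit_tree(matrix, is_case, panel=panel, max_depth=max_depth,
                       min_samples_leaf=min_samples_leaf)
        out[name] = {"tree": clf, "report": evaluate(clf, matrix, is_case)}
    return out
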