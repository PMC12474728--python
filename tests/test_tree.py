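import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

import metabopanel as mp
from metabopanel.config import SyntheticConfig
from metabopanel.errors import DataError
from metabopanel.tree import PanelTreeClassifier, _best_split


def _random_instance(seed, n=16, p=4):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"m{j}" for j in range(p)])
    y = rng.integers(0, 2, n).astype(bool)
    return X, y


def test_perfect_feature_gives_depth_one_tree():
    X = pd.DataFrame({"good": [1, 2, 3, 10, 11, 12], "noise": [5, 1, 4, 2, 6, 3]})
    y = np.array([False, False, False, True, True, True])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    assert clf.depth_ == 2  # root split + leaves
    assert clf.tree_.metabolite == "good"
    assert (clf.predict(X) == np.where(y, "GDM", "CON")).all()


def _brute_force_root(X, y, min_leaf):
    """Exhaustive oracle over all feature × midpoint splits."""
    best = None
    n = len(y)
    for name in X.columns:
        x = X[name].to_numpy()
        for t in (np.sort(np.unique(x))[:-1] + np.sort(np.unique(x))[1:]) / 2:
            mask = x < t
            nl, nr = mask.sum(), n - mask.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            gini = 0.0
            for m, nn in ((mask, nl), (~mask, nr)):
                pk = y[m].mean()
                gini += nn / n * 2 * pk * (1 - pk)
            key = (gini, name, t)
            if best is None or key < best:
                best = key
    return best


@pytest.mark.parametrize("seed", range(25))
def test_root_split_matches_bruteforce_oracle(seed):
    X, y = _random_instance(seed, n=int(np.random.default_rng(seed).integers(8, 21)), p=6)
    if y.all() or not y.any():
        return
    oracle = _brute_force_root(X, y, min_leaf=2)
    split = _best_split(X.to_numpy(), y, list(X.columns), min_leaf=2)
    if oracle is None:
        assert split is None
        return
    j, t = split
    assert X.columns[j] == oracle[1]
    assert t == pytest.approx(oracle[2])


@pytest.mark.parametrize("seed", range(5))
def test_root_split_agrees_with_sklearn(seed):
    # independent CART implementation must find the same root cut on
    # continuous data (ties almost surely absent)
    X, y = _random_instance(seed, n=20, p=5)
    if y.all() or not y.any():
        return
    mine = PanelTreeClassifier(max_depth=2, min_samples_leaf=2).fit(X, y)
    sk = DecisionTreeClassifier(max_depth=1, min_samples_leaf=2, random_state=0).fit(X, y)
    assert mine.tree_.metabolite == X.columns[sk.tree_.feature[0]]
    assert mine.tree_.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)


def test_max_depth_honored_on_nonseparable_data():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(80, 6)), columns=[f"m{j}" for j in range(6)])
    y = rng.integers(0, 2, 80).astype(bool)
    clf = PanelTreeClassifier(max_depth=5, min_samples_leaf=2).fit(X, y)
    assert clf.depth_ <= 5

    def max_level(node):
        if node.is_leaf:
            return node.level
        return max(max_level(node.left), max_level(node.right))

    assert max_level(clf.tree_) <= 5


def test_predict_pure_leaf_probability_one():
    X = pd.DataFrame({"m": [1.0, 2.0, 10.0, 11.0]})
    y = np.array([False, False, True, True])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    proba = clf.predict_proba(pd.DataFrame({"m": [11.0]}))
    assert proba[0, 1] == 1.0


def test_boundary_value_goes_right():
    X = pd.DataFrame({"m": [1.0, 2.0, 10.0, 11.0]})
    y = np.array([False, False, True, True])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    t = clf.tree_.threshold
    # x == threshold: "x < t" is false, traverse right (the high/case side)
    assert clf.predict(pd.DataFrame({"m": [t]}))[0] == "GDM"


def test_single_class_input_gives_single_leaf():
    X = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0]})
    y = np.zeros(5, bool)
    with pytest.warns(UserWarning, match="single-class"):
        clf = PanelTreeClassifier().fit(X, y)
    assert clf.tree_.is_leaf
    assert (clf.predict(X) == "CON").all()


def test_predict_missing_feature_named():
    X = pd.DataFrame({"m": [1.0, 2.0, 10.0, 11.0], "z": [0, 1, 0, 1]})
    y = np.array([False, False, True, True])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    with pytest.raises(DataError, match="m"):
        clf.predict(pd.DataFrame({"z": [1.0]}))


def test_evaluate_perfect_classifier():
    X = pd.DataFrame({"m": [1.0, 2.0, 10.0, 11.0, 12.0, 0.5]})
    y = np.array([False, False, True, True, True, False])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    r = mp.evaluate(clf, X, y)
    assert (r.sensitivity, r.specificity, r.unweighted_accuracy) == (100.0, 100.0, 100.0)
    assert r.auc == 1.0


def test_evaluate_single_leaf_tree_auc_half():
    X = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
    y = np.array([True, True, False, False])
    clf = PanelTreeClassifier(max_depth=1).fit(X, y)  # forced single leaf
    r = mp.evaluate(clf, X, y)
    assert r.auc == pytest.approx(0.5)


def test_evaluate_requires_both_classes():
    X = pd.DataFrame({"m": [1.0, 2.0, 10.0, 11.0]})
    y = np.array([False, False, True, True])
    clf = PanelTreeClassifier(min_samples_leaf=1).fit(X, y)
    with pytest.raises(DataError):
        mp.evaluate(clf, X, np.ones(4, bool))


def test_metrics_identity_on_fitted_tree(matched_normalized):
    norm, is_case, _ = matched_normalized
    clf = mp.fit_tree(norm.values, is_case, panel=list(mp.LATE_PANEL))
    r = mp.evaluate(clf, norm.values, is_case)
    assert r.unweighted_accuracy == pytest.approx((r.sensitivity + r.specificity) / 2)
    assert r.n == 92
    assert clf.depth_ <= 5


def test_compare_panels_identical_panels_identical_reports(matched_normalized):
    norm, is_case, _ = matched_normalized
    panel = list(mp.LATE_PANEL)
    res = mp.compare_panels(norm.values, is_case, panel_late=panel, panel_early=panel)
    assert res["late"]["report"] == res["early"]["report"]


def test_compare_panels_unknown_metabolite_named(matched_normalized):
    norm, is_case, _ = matched_normalized
    with pytest.raises(DataError, match="nonexistent"):
        mp.compare_panels(norm.values, is_case, panel_late=["nonexistent"])


@pytest.mark.parametrize("seed", range(20))
def test_noise_feature_does_not_break_full_depth_purification(seed):
    # with continuous features and no depth bound a greedy tree purifies the
    # training set, with or without an extra pure-noise metabolite
    rng = np.random.default_rng(200 + seed)
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    y = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
    X.loc[y, "a"] += 1.0
    base = mp.evaluate(
        mp.fit_tree(X, y, panel=["a", "b", "c"], max_depth=30, min_samples_leaf=1),
        X, y,
    ).unweighted_accuracy
    X["noise"] = rng.normal(size=30)
    extended = mp.evaluate(
        mp.fit_tree(X, y, panel=["a", "b", "c", "noise"], max_depth=30,
                    min_samples_leaf=1),
        X, y,
    ).unweighted_accuracy
    assert base == 100.0 and extended == 100.0


def test_tree_serialization_roundtrip(tmp_path, matched_normalized):
    norm, is_case, _ = matched_normalized
    clf = mp.fit_tree(norm.values, is_case, panel=list(mp.LATE_PANEL))
    d = clf.to_dict()
    assert d["value_scale"]
    assert d["root"]["leaf"] is False
    text = clf.to_text()
    assert "leaf" in text and "<" in text
    clf.to_json(tmp_path / "tree.json")
    assert (tmp_path / "tree.json").stat().st_size > 0
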