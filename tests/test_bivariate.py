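import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metabopanel as mp
from metabopanel.config import SyntheticConfig
from metabopanel.errors import DataError


def test_effect_size_zero_for_equal_means():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert mp.effect_size(a, a + 0.0).d == pytest.approx(0.0)


def test_effect_size_one_for_one_pooled_sd_shift():
    rng = np.random.default_rng(0)
    con = rng.normal(size=200)
    sd = mp.pooled_sd(con, con)
    gdm = con + sd
    assert mp.effect_size(gdm, con).d == pytest.approx(1.0)


def test_effect_size_zero_pooled_sd_rejected():
    with pytest.raises(DataError):
        mp.effect_size([2.0, 2.0], [2.0, 2.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_effect_size_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=8), rng.normal(1.0, 2.0, size=9)
    forward = mp.effect_size(a, b)
    backward = mp.effect_size(b, a)
    assert forward.d == pytest.approx(-backward.d)
    assert forward.p_value == pytest.approx(backward.p_value)


def test_homocarnosine_effect_recovered_in_large_cohort():
    # planted d = -0.663 recovered within sampling error at n = 1000/group
    cfg = SyntheticConfig(
        n_cases=1000, n_control_pool=1000, n_metabolites=10,
        planted_markers={"homocarnosine": -0.663}, seed=21, dilution_sd=0.0,
    )
    subjects, matrix, _ = mp.generate_cohort(cfg)
    is_case = (subjects["group"] == "GDM").to_numpy()
    x = np.log(matrix.values["homocarnosine"]).to_numpy()
    assert mp.effect_size(x[is_case], x[~is_case]).d == pytest.approx(-0.663, abs=0.1)


def test_group_compare_identical_samples():
    a = [1.0, 2.0, 3.0]
    assert mp.group_compare(a, a, kind="normal") == pytest.approx(1.0)


def test_group_compare_fisher_two_by_two():
    # table [[2,0],[0,2]]: hypergeometric enumeration gives P = 1/3
    a = ["x", "x"]
    b = ["y", "y"]
    assert mp.group_compare(a, b, kind="categorical") == pytest.approx(1 / 3)


def test_group_compare_wilcoxon_complete_separation():
    # two separated groups of 5: minimal attainable two-sided P = 2/C(10,5)
    p = mp.group_compare([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], kind="nonnormal")
    assert p == pytest.approx(2 / 252)


def test_group_compare_too_few_observations():
    with pytest.raises(DataError):
        mp.group_compare([1.0], [2.0, 3.0], kind="normal")


def test_cutpoint_perfect_separation():
    r = mp.single_marker_accuracy([5, 6, 7, 1, 2, 3], [True] * 3 + [False] * 3)
    assert r.accuracy == 100.0
    assert r.orientation == "high"
    assert 3 < r.threshold < 5


def test_cutpoint_low_is_case_orientation():
    r = mp.single_marker_accuracy([1, 2, 3, 4, 5, 6], [True] * 3 + [False] * 3)
    assert r.accuracy == 100.0
    assert r.orientation == "low"
    assert 3 < r.threshold < 4


def test_cutpoint_constant_marker_flagged():
    r = mp.single_marker_accuracy([2.0] * 6, [True] * 3 + [False] * 3)
    assert r.constant
    assert r.accuracy == 50.0


def _brute_force_cutpoint(x, y):
    """Independent exhaustive scan over every midpoint and orientation."""
    best = 0.0
    uniq = np.unique(x)
    n_pos, n_neg = y.sum(), (~y).sum()
    for t in (uniq[:-1] + uniq[1:]) / 2:
        for pred in (x >= t, x < t):
            sens = (pred & y).sum() / n_pos
            spec = (~pred & ~y).sum() / n_neg
            best = max(best, 100 * (sens + spec) / 2)
    return best


@pytest.mark.parametrize("seed", range(20))
def test_cutpoint_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.integers(0, 2, 12).astype(bool)
    if y.all() or not y.any():
        return
    assert mp.single_marker_accuracy(x, y).accuracy == pytest.approx(
        _brute_force_cutpoint(x, y)
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_cutpoint_accuracy_at_least_fifty(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=14)
    y = np.concatenate([np.ones(7, bool), np.zeros(7, bool)])
    assert mp.single_marker_accuracy(x, y).accuracy >= 50.0


def test_rank_markers_duplicate_column_tiebreak():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    matrix = pd.DataFrame({"b_copy": x, "a_copy": x})
    y = np.concatenate([np.ones(10, bool), np.zeros(10, bool)])
    ranking = mp.rank_markers(matrix, y)
    assert list(ranking["metabolite"]) == ["a_copy", "b_copy"]
    assert ranking["accuracy"].iloc[0] == ranking["accuracy"].iloc[1]


def test_single_strong_marker_ranks_first():
    # d = 3 planted among nulls: ranked first in a clear majority of seeds
    wins = 0
    for seed in range(20):
        cfg = SyntheticConfig(
            n_cases=46, n_control_pool=46, n_metabolites=100,
            planted_markers={"3-hydroxybutyrate": 3.0}, seed=seed,
            dilution_sd=0.0,
        )
        subjects, matrix, _ = mp.generate_cohort(cfg)
        is_case = (subjects["group"] == "GDM").to_numpy()
        ranking = mp.rank_markers(np.log(matrix.values), is_case)
        wins += ranking["metabolite"].iloc[0] == "3-hydroxybutyrate"
    assert wins >= 11


def test_planted_markers_outrank_null_markers(matched_normalized):
    norm, is_case, _ = matched_normalized
    ranking = mp.rank_markers(norm.values, is_case)
    position = {m: i + 1 for i, m in enumerate(ranking["metabolite"])}
    planted_ranks = [position[m] for m in mp.CONSENSUS_MARKER_EFFECTS]
    null_ranks = [
        r for m, r in position.items() if m not in mp.CONSENSUS_MARKER_EFFECTS
    ]
    assert np.mean(planted_ranks) < np.median(null_ranks)


def test_effect_table_shape_and_order(matched_normalized):
    norm, is_case, _ = matched_normalized
    table = mp.effect_table(norm.values, is_case, norm.annotations)
    assert set(table.columns) == {"metabolite", "pathway", "d", "nominal_p"}
    assert table["d"].abs().is_monotonic_decreasing
    # the eight planted markers dominate the top of the table
    top20 = set(table["metabolite"].head(20))
    assert len(top20 & set(mp.CONSENSUS_MARKER_EFFECTS)) >= 5


def test_single_marker_ranker_estimator(matched_normalized):
    norm, is_case, _ = matched_normalized
    est = mp.SingleMarkerRanker().fit(norm.values, is_case)
    assert est.n_features_in_ == 626
    assert len(est.ranking_) == 626
    assert (est.ranking_["accuracy"] >= 50.0).all()
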