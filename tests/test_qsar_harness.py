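"""Discretization, splitting, learners, metrics, hybridization, significance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hyqsar as h
from hyqsar.qsar_harness import (
    BBB_RULE,
    EE_RULE,
    HIA_RULE,
    REFERENCE_SUBSETS,
    _fit_regression_stump,
)


def _table(frame, y, name="y"):
    return h.DescriptorTable(frame, pd.Series(y, index=frame.index, name=name), name)


# -- discretization ----------------------------------------------------------

@pytest.mark.parametrize("value, label", [(0.65, "Not Absorb"), (0.70, "Absorb"),
                                          (0.6999, "Not Absorb"), (1.0, "Absorb")])
def test_hia_thresholds(value, label):
    assert h.discretize([value], HIA_RULE)[0] == label


@pytest.mark.parametrize("value, label", [(-1.0, "BBB+"), (-0.7, "BBB+"),
                                          (-0.5, "Gray area"), (-0.3, "Gray area"),
                                          (0.0, "BBB-")])
def test_bbb_thresholds(value, label):
    assert h.discretize([value], BBB_RULE)[0] == label


@pytest.mark.parametrize("value, label", [(95, "High-enantiopurity"),
                                          (90, "High-enantiopurity"),
                                          (50, "Low-enantiopurity"),
                                          (10, "High-enantiopurity"),
                                          (5, "High-enantiopurity")])
def test_ee_thresholds(value, label):
    assert h.discretize([value], EE_RULE)[0] == label


def test_out_of_range_values_listed():
    with pytest.raises(ValueError, match="1.5"):
        h.discretize([0.5, 1.5], HIA_RULE)


# -- splits ------------------------------------------------------------------

def test_unstratified_split_sizes():
    frame = pd.DataFrame({"a": np.arange(100.0)},
                         index=[f"c{i}" for i in range(100)])
    table = _table(frame, np.arange(100.0))
    train, test = h.split_dataset(table, h.SplitSpec(0.66, seed=1))
    assert train.n_compounds == 66 and test.n_compounds == 34
    assert set(train.ids) | set(test.ids) == set(table.ids)
    assert not set(train.ids) & set(test.ids)


def test_stratified_split_preserves_class_proportions():
    labels = ["A"] * 40 + ["B"] * 20
    frame = pd.DataFrame({"a": np.arange(60.0)}, index=[f"c{i}" for i in range(60)])
    table = h.DescriptorTable(frame, pd.Series(labels, index=frame.index,
                                               name="cls"), "cls")
    train, test = h.split_dataset(table, h.SplitSpec(0.5, stratified=True, seed=2))
    tr = pd.Series(train.target)
    assert (tr == "A").sum() == 20 and (tr == "B").sum() == 10


def test_split_is_seed_deterministic():
    frame = pd.DataFrame({"a": np.arange(30.0)}, index=[f"c{i}" for i in range(30)])
    table = _table(frame, np.arange(30.0))
    t1 = h.split_dataset(table, h.SplitSpec(0.75, seed=7))
    t2 = h.split_dataset(table, h.SplitSpec(0.75, seed=7))
    assert t1[0].ids == t2[0].ids and t1[1].ids == t2[1].ids


def test_singleton_class_rejected_under_stratification():
    frame = pd.DataFrame({"a": np.arange(5.0)}, index=[f"c{i}" for i in range(5)])
    table = h.DescriptorTable(frame, pd.Series(["A", "A", "A", "A", "B"],
                                               index=frame.index, name="cls"), "cls")
    with pytest.raises(ValueError, match="B"):
        h.split_dataset(table, h.SplitSpec(0.5, stratified=True, seed=0))


# -- learners ----------------------------------------------------------------

def test_stump_finds_exact_split_point():
    x = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    feat, thr, left, right = _fit_regression_stump(x, y)
    assert feat == 0 and 2.0 < thr < 3.0
    pred = np.where(x[:, 0] <= thr, left, right)
    np.testing.assert_array_equal(pred, y)


def test_random_committee_of_identical_members_equals_single_member():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"),
                         index=[f"c{i}" for i in range(40)])
    y = frame["a"] * 2 + rng.normal(scale=0.1, size=40)
    table = _table(frame, y)
    train, test = h.split_dataset(table, h.SplitSpec(0.75, seed=1))
    single = h.train_predict(train, test, h.LearnerSpec("random_committee",
                                                        committee_size=1, seed=5))
    from sklearn.tree import ExtraTreeRegressor
    t = ExtraTreeRegressor(random_state=5, max_features=1.0)
    t.fit(train.values.to_numpy(), train.target.to_numpy())
    np.testing.assert_array_equal(single, t.predict(test.values.to_numpy()))


def test_random_forest_single_tree_equals_that_tree():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"),
                         index=[f"c{i}" for i in range(30)])
    y = frame["a"] + rng.normal(scale=0.05, size=30)
    table = _table(frame, y)
    train, test = h.split_dataset(table, h.SplitSpec(0.66, seed=2))
    spec = h.LearnerSpec("random_forest", trees=1, k_attributes=2, seed=9)
    pred = h.train_predict(train, test, spec)
    from sklearn.ensemble import RandomForestRegressor
    rf = RandomForestRegressor(n_estimators=1, max_features=2, random_state=9)
    rf.fit(train.values.to_numpy(), train.target.to_numpy())
    np.testing.assert_array_equal(pred, rf.estimators_[0].predict(test.values.to_numpy()))


def test_column_mismatch_rejected():
    frame = pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"])
    t1 = _table(frame, [0.0, 1.0])
    t2 = _table(frame.rename(columns={"a": "b"}), [0.0, 1.0])
    with pytest.raises(ValueError, match="differ"):
        h.train_predict(t1, t2, h.LearnerSpec("linear_regression"))


def test_single_class_training_rejected():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=["x", "y", "z"])
    table = h.DescriptorTable(frame, pd.Series(["p", "p", "p"], index=frame.index,
                                               name="cls"), "cls")
    with pytest.raises(ValueError, match="single-class"):
        h.train_predict(table, table, h.LearnerSpec("decision_stump"),
                        "classification", ["p", "q"])


@pytest.mark.parametrize("family", ["linear_regression", "decision_stump", "mlp",
                                    "random_forest", "random_committee"])
def test_every_family_runs_both_tasks(family):
    rng = np.random.default_rng(8)
    frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"),
                         index=[f"c{i}" for i in range(50)])
    y = frame["a"] - frame["b"] + rng.normal(scale=0.2, size=50)
    reg = _table(frame, y)
    train, test = h.split_dataset(reg, h.SplitSpec(0.66, seed=3))
    spec = h.LearnerSpec(family, epochs=100, seed=2)
    pred = h.train_predict(train, test, spec)
    assert pred.shape == (test.n_compounds,)

    labels = pd.Series(np.where(y > np.median(y), "hi", "lo"), index=frame.index)
    cls = h.DescriptorTable(frame, labels, "cls")
    train, test = h.split_dataset(cls, h.SplitSpec(0.66, stratified=True, seed=3))
    probs, order = h.train_predict(train, test, spec, "classification", ["lo", "hi"])
    assert list(probs.columns) == ["lo", "hi"]
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


# -- regression metrics ------------------------------------------------------

def test_perfect_prediction_metrics():
    m = h.evaluate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 2.0)
    assert m["CC"] == pytest.approx(1.0)
    assert m["RAE"] == 0.0 and m["RRSE"] == 0.0


def test_naive_baseline_scores_exactly_100_percent():
    y = np.array([1.0, 2.0, 4.0])
    m = h.evaluate_regression(np.full(3, 2.0), y, 2.0)
    assert m["RAE"] == pytest.approx(100.0)
    assert m["RRSE"] == pytest.approx(100.0)


def test_regression_metrics_match_hand_computation():
    y = np.array([1.0, 2.0, 3.0])
    pred = np.array([1.0, 2.0, 4.0])
    m = h.evaluate_regression(pred, y, 2.0)
    assert m["RAE"] == pytest.approx(100.0 * 1.0 / 2.0, abs=1e-12)
    assert m["RRSE"] == pytest.approx(100.0 * math.sqrt(1.0 / 2.0), abs=1e-12)
    assert m["CC"] == pytest.approx(float(np.corrcoef(pred, y)[0, 1]), abs=1e-12)


def test_uninformative_test_set_rejected():
    with pytest.raises(ValueError, match="uninformative"):
        h.evaluate_regression([1.0, 1.0], [2.0, 2.0], 2.0)


# -- classification metrics --------------------------------------------------

def test_perfect_separation_scores_100_and_auc_1():
    p = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
    m = h.evaluate_classification(p, ["a", "a", "b", "b"], [0.5, 0.5], ["a", "b"])
    assert m["%CC"] == 100.0
    assert m["ROC"] == pytest.approx(1.0)
    assert m["confusion_matrix"].to_numpy().tolist() == [[2, 0], [0, 2]]


def test_uniform_probabilities_give_midrank_half_auc():
    p = np.full((6, 2), 0.5)
    m = h.evaluate_classification(p, ["a", "b", "a", "b", "a", "b"],
                                  [0.5, 0.5], ["a", "b"])
    assert m["ROC"] == pytest.approx(0.5)


def test_roc_matches_pairwise_comparison_oracle():
    rng = np.random.default_rng(11)
    p1 = rng.uniform(size=6)
    p = np.column_stack([p1, 1 - p1])
    actual = ["a", "b", "a", "b", "b", "a"]
    m = h.evaluate_classification(p, actual, [0.5, 0.5], ["a", "b"])
    # O(n^2) pairwise oracle for class "a"
    pos = [p1[i] for i, c in enumerate(actual) if c == "a"]
    neg = [p1[i] for i, c in enumerate(actual) if c == "b"]
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0
               for sp in pos for sn in neg)
    auc_a = wins / (len(pos) * len(neg))
    pos_b = [1 - p1[i] for i, c in enumerate(actual) if c == "b"]
    neg_b = [1 - p1[i] for i, c in enumerate(actual) if c == "a"]
    wins_b = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0
                 for sp in pos_b for sn in neg_b)
    auc_b = wins_b / (len(pos_b) * len(neg_b))
    expected = 0.5 * auc_a + 0.5 * auc_b
    assert m["ROC"] == pytest.approx(expected, abs=1e-10)


def test_class_frequency_baseline_probabilities_score_100_rae():
    q = np.array([2 / 3, 1 / 3])
    p = np.tile(q, (6, 1))
    m = h.evaluate_classification(p, ["a", "a", "b", "a", "a", "b"], q, ["a", "b"])
    assert m["RAE"] == pytest.approx(100.0)
    assert m["RRSE"] == pytest.approx(100.0)


def test_confusion_matrix_rows_sum_to_class_counts():
    p = np.array([[0.6, 0.4], [0.4, 0.6], [0.7, 0.3], [0.2, 0.8], [0.9, 0.1]])
    actual = ["a", "a", "b", "b", "a"]
    m = h.evaluate_classification(p, actual, [0.6, 0.4], ["a", "b"])
    cm = m["confusion_matrix"]
    assert cm.sum(axis=1).tolist() == [3, 2]
    assert cm.to_numpy().sum() == 5
    assert m["%CC"] == pytest.approx(100.0 * np.trace(cm.to_numpy()) / 5)


def test_unknown_test_label_rejected():
    p = np.array([[1.0, 0.0]])
    with pytest.raises(ValueError, match="unknown"):
        h.evaluate_classification(p, ["z"], [0.5, 0.5], ["a", "b"])


# -- hybridization -----------------------------------------------------------

def test_reference_combined_cardinalities():
    """The six published combined-subset sizes: 6, 10, 7, 8, 14, 27."""
    expected = {("BBB", "M2_BBB", "CT_BBB"): 6, ("BBB", "M13_BBB", "CT_BBB"): 10,
                ("HIA", "M5_HIA", "CT_HIA"): 7, ("HIA", "M9_HIA", "CT_HIA"): 8,
                ("EE", "M9_EE", "CT_EE"): 14, ("EE", "M14_EE", "CT_EE"): 27}
    for (ds, a, b), size in expected.items():
        union = h.combine_subsets(REFERENCE_SUBSETS[ds][a], REFERENCE_SUBSETS[ds][b])
        assert len(union) == size
        assert union.provenance == "combined"
        assert union.parents == (a, b)


def test_union_order_and_idempotence():
    a = h.DescriptorSubset("A", ["x", "y"], "selected")
    b = h.DescriptorSubset("B", ["y", "z"], "learned")
    u = h.combine_subsets(a, b)
    assert u.descriptors == ["x", "y", "z"]
    self_union = h.combine_subsets(a, a)
    assert self_union.descriptors == a.descriptors


# -- reaction tables ---------------------------------------------------------

def _codes(prefix, n_rows, n_cols):
    rng = np.random.default_rng(len(prefix))
    frame = pd.DataFrame(rng.normal(size=(n_rows, n_cols)),
                         index=[f"{prefix}{i}" for i in range(n_rows)],
                         columns=[f"{prefix}c{j}" for j in range(n_cols)])
    return h.DescriptorTable(frame)


def test_reaction_table_shape_and_column_order():
    subs = _codes("S", 2, 4)
    ligs = _codes("L", 3, 6)
    pairs = [("S0", "L0", 90.0), ("S0", "L1", 45.0), ("S1", "L2", 5.0),
             ("S1", "L0", 99.0), ("S0", "L2", 60.0)]
    table = h.assemble_reaction_table(subs, ligs, pairs)
    assert table.values.shape == (5, 10)
    assert table.descriptor_names[:4] == subs.descriptor_names
    assert table.descriptor_names[4:] == ligs.descriptor_names
    np.testing.assert_array_equal(table.target.to_numpy(),
                                  [90.0, 45.0, 5.0, 99.0, 60.0])


def test_duplicate_pairs_preserved():
    subs, ligs = _codes("S", 1, 2), _codes("L", 1, 2)
    table = h.assemble_reaction_table(subs, ligs,
                                      [("S0", "L0", 10.0), ("S0", "L0", 20.0)])
    assert table.n_compounds == 2


def test_unknown_ligand_id_named_in_error():
    subs, ligs = _codes("S", 1, 2), _codes("L", 1, 2)
    with pytest.raises(KeyError, match="L9"):
        h.assemble_reaction_table(subs, ligs, [("S0", "L9", 1.0)])


# -- replacement test --------------------------------------------------------

@pytest.fixture(scope="module")
def replacement_setup():
    spec = h.SyntheticSpec(n_molecules=200, seed=31, n_informative=4,
                           coefficients=(1.0, 2.0, -2.0, 2.0), noise_sigma=1.0)
    table, _, truth = h.generate_dataset(spec)
    learner = h.LearnerSpec("linear_regression")
    split = h.SplitSpec(0.75, seed=5)
    ref_sub = table.subset(truth["informative"])
    tr, te = h.split_dataset(ref_sub, split)
    pred = h.train_predict(tr, te, learner)
    ref = h.evaluate_regression(pred, te.target.to_numpy(),
                                float(tr.target.mean()))
    return table, truth, learner, split, ref["CC"]


def test_replicate_count_and_determinism(replacement_setup):
    table, truth, learner, split, ref_cc = replacement_setup
    kwargs = dict(fixed_subset=[truth["informative"][0]], replaced_size=3,
                  excluded=truth["informative"][1:], learner=learner,
                  split=split, replicates=20, reference_cc=ref_cc, seed=42)
    r1 = h.run_replacement_test(table, **kwargs)
    r2 = h.run_replacement_test(table, **kwargs)
    assert len(r1.replicate_cc) == 20
    np.testing.assert_array_equal(r1.replicate_cc, r2.replicate_cc)


def test_noise_replacements_underperform_reference(replacement_setup):
    table, truth, learner, split, ref_cc = replacement_setup
    result = h.run_replacement_test(
        table, [truth["informative"][0]], 3, truth["informative"][1:],
        learner, split, replicates=50, reference_cc=ref_cc, seed=7)
    assert result.mean_cc < result.reference_cc
    assert result.p_value <= 0.05


def test_insufficient_pool_rejected(replacement_setup):
    table, truth, learner, split, ref_cc = replacement_setup
    with pytest.raises(ValueError, match="pool"):
        h.run_replacement_test(table, table.descriptor_names[:-2], 3, [],
                               learner, split, replicates=5, reference_cc=0.5)


# -- confidence intervals ----------------------------------------------------

def test_equal_series_not_significant():
    a = np.linspace(0, 1, 10)
    res = h.compare_with_ci(a, a)
    assert res["mean_difference"] == 0.0
    assert not res["significant"]
    assert res["degenerate"]


def test_constant_shift_degenerate_but_significant():
    a = np.linspace(0, 1, 10)
    res = h.compare_with_ci(a + 1.0, a)
    assert res["degenerate"] and res["significant"]
    assert res["ci"] == (1.0, 1.0)


def test_t_interval_matches_closed_form():
    rng = np.random.default_rng(13)
    d = rng.normal(0.1, 0.1, size=30)
    res = h.compare_with_ci(d, np.zeros(30), level=0.95, method="t")
    s = d.std(ddof=1)
    half = stats.t.ppf(0.975, 29) * s / math.sqrt(30)
    assert res["ci"][0] == pytest.approx(d.mean() - half, abs=1e-10)
    assert res["ci"][1] == pytest.approx(d.mean() + half, abs=1e-10)


def test_bootstrap_interval_is_seeded_and_sane():
    rng = np.random.default_rng(17)
    d = rng.normal(0.2, 0.1, size=30)
    r1 = h.compare_with_ci(d, np.zeros(30), method="bootstrap", seed=3)
    r2 = h.compare_with_ci(d, np.zeros(30), method="bootstrap", seed=3)
    assert r1["ci"] == r2["ci"]
    assert r1["significant"]
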