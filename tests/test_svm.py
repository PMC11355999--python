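"""Greedy forward SVM selection: oracle equivalence, signal dominance,
confusion-matrix aggregation."""

import numpy as np
import pytest

import metabopanel as mp
from conftest import brute_force_greedy, prepare_log
from metabopanel.errors import AggregationError, ContrastError
from metabopanel.peaktable import Metabolite, PeakTable, SampleMeta
from metabopanel.svm import make_fold_plan, score_subset, \
    _standardized_folds


def log_table(groups, values):
    values = np.asarray(values, dtype=float)
    samples = [SampleMeta(f"s{i}", g, injection_order=i + 1)
               for i, g in enumerate(groups)]
    mets = [Metabolite(f"M{j}") for j in range(values.shape[1])]
    return PeakTable(samples, mets, values, stage="log")


def test_train_svm_separable_1d():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([-1, -1, 1, 1])
    model, mean, std = mp.train_svm_lk(X, y)
    assert (model.predict((X - mean) / std) == y).all()
    # decision boundary between the classes
    b = -model.intercept_[0] / model.coef_[0][0] * std[0] + mean[0]
    assert -1.0 < b < 1.0


def test_train_svm_label_flip_negates_decision():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 3))
    y = np.array([1] * 5 + [-1] * 5)
    m1, mu, sd = mp.train_svm_lk(X, y)
    m2, _, _ = mp.train_svm_lk(X, -y)
    Z = (X - mu) / sd
    # the separating hyperplane is the same up to solver tolerance, so
    # predictions flip exactly and decision values negate approximately
    np.testing.assert_array_equal(m1.predict(Z), -m2.predict(Z))
    np.testing.assert_allclose(m1.decision_function(Z),
                               -m2.decision_function(Z), atol=5e-2)


def test_train_svm_single_class_errors():
    with pytest.raises(ContrastError):
        mp.train_svm_lk(np.zeros((4, 2)), np.ones(4))


def test_xor_not_linearly_separable():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 2, dtype=float)
    y = np.array([1, -1, -1, 1] * 2)
    model, mu, sd = mp.train_svm_lk(X, y)
    acc = (model.predict((X - mu) / sd) == y).mean()
    assert acc <= 0.75


def test_greedy_matches_brute_force_oracle(config):
    """Exact path equality with an independent plain-loop scorer sharing
    folds and seeds, m = 6."""
    rng = np.random.default_rng(42)
    n = 8
    X = rng.normal(size=(2 * n, 6))
    y_groups = ["CSIS"] * n + ["Control"] * n
    X[:n, 2] += 2.0
    X[:n, 4] += 1.0
    t = log_table(y_groups, X)
    cfg = config.replace(cv_repeats=3)
    path, _ = mp.greedy_forward_select(t, ("CSIS", "Control"), cfg)

    Xc, y = t.contrast_values(("CSIS", "Control"))
    plans = make_fold_plan(y, cfg.cv_folds, cfg.cv_repeats, cfg.rng_seed)
    oracle = brute_force_greedy(Xc, y, plans, max_steps=3)
    names = t.metabolite_names
    assert [s[0] for s in path.steps] == [names[j] for j, _ in oracle]
    assert [s[1] for s in path.steps] == pytest.approx(
        [a for _, a in oracle])


def test_informative_feature_selected_first(config):
    """One planted feature (4 sigma) among 4 noise features wins step 1."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(16, 5))
    X[:8, 3] += 4.0
    t = log_table(["CSIS"] * 8 + ["Control"] * 8, X)
    path, report = mp.greedy_forward_select(t, ("CSIS", "Control"), config)
    assert path.steps[0][0] == "M3"
    assert report.accuracy >= 90.0


def test_panel_is_prefix_and_steps_unique(config, strong_design):
    table, _ = mp.simulate_peak_table(strong_design, 5)
    _, log_t = prepare_log(table, config)
    path, _ = mp.greedy_forward_select(log_t, ("CSISFlx", "CSIS"), config)
    names = [s[0] for s in path.steps]
    assert len(set(names)) == len(names)          # no re-selection
    assert path.panel == names[:len(path.panel)]  # panel is a path prefix
    assert len(path.steps) <= path.max_steps
    best = max(a for _, a in path.steps)
    assert path.steps[len(path.panel) - 1][1] == pytest.approx(best)


def test_all_noise_accuracy_near_chance(config):
    rng = np.random.default_rng(9)
    X = rng.normal(size=(16, 6))
    t = log_table(["CSIS"] * 8 + ["Control"] * 8, X)
    cfg = config.replace(cv_repeats=5)
    _, report = mp.greedy_forward_select(t, ("CSIS", "Control"), cfg,
                                         max_steps=2)
    assert 35.0 <= report.accuracy <= 65.0


@pytest.mark.parametrize("sens,spec,expected", [
    (83.30, 87.50, 85.40),
    (83.30, 66.70, 75.00),
    (100.0, 100.0, 100.0),
])
def test_balanced_accuracy_is_arithmetic_mean(sens, spec, expected):
    assert mp.balanced_accuracy(sens, spec) == expected


def test_aggregate_report_counts_and_metrics():
    y = np.array([1, 1, 1, -1, -1, -1])
    # repeat 1: one false negative; repeat 2: one false positive
    p1 = np.array([1, 1, -1, -1, -1, -1], dtype=object)
    p2 = np.array([1, 1, 1, 1, -1, -1], dtype=object)
    rep = mp.aggregate_report([y, y], [p1, p2], "CSIS", repeats=2, folds=3)
    assert (rep.tp, rep.fn, rep.fp, rep.tn) == (5, 1, 1, 5)
    assert rep.accuracy == pytest.approx(83.33)
    assert rep.sensitivity == pytest.approx(83.33)
    assert rep.specificity == pytest.approx(83.33)
    assert rep.balanced_accuracy == pytest.approx(83.33)


def test_aggregate_report_perfect_predictions():
    y = np.array([1, -1, 1, -1])
    rep = mp.aggregate_report([y], [y.astype(object)], "CSIS", 1, 2)
    assert rep.accuracy == rep.sensitivity == rep.specificity == 100.0


def test_aggregate_report_coverage_gap_errors():
    y = np.array([1, -1])
    pred = np.array([1, None], dtype=object)
    with pytest.raises(AggregationError):
        mp.aggregate_report([y], [pred], "CSIS", 1, 2)


def test_fold_plan_deterministic():
    y = np.array([1, 1, 1, 1, -1, -1, -1, -1] * 2)
    p1 = make_fold_plan(y, 3, 4, 7)
    p2 = make_fold_plan(y, 3, 4, 7)
    for a, b in zip(p1, p2):
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)
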