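"""Random forest: OOB tuning, evaluation, Gini importances."""

import numpy as np
import pytest

import metabopanel as mp
from conftest import prepare_log
from metabopanel.peaktable import Metabolite, PeakTable, SampleMeta

SMALL_GRID = tuple((n, d) for n in (50, 100) for d in (2, None))


def log_table(groups, values):
    values = np.asarray(values, dtype=float)
    samples = [SampleMeta(f"s{i}", g, injection_order=i + 1)
               for i, g in enumerate(groups)]
    mets = [Metabolite(f"M{j}") for j in range(values.shape[1])]
    return PeakTable(samples, mets, values, stage="log")


def separable_table(seed=0, n=10, m=8, delta=5.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, m))
    X[:n, 0] += delta
    return log_table(["CSIS"] * n + ["Control"] * n, X)


def test_tune_separable_ties_resolve_to_smallest_forest():
    t = separable_table(n=16, delta=8.0)
    settings = mp.tune_rf_oob(t, ("CSIS", "Control"), grid=SMALL_GRID,
                              seed=0)
    assert len(settings.grid_trace) == len(SMALL_GRID)
    best = max(s for _, _, s in settings.grid_trace)
    assert settings.oob_score == best
    # among equally scoring grid points the smallest forest wins, with
    # ties on tree count broken by shallower depth
    tied = [(n, d) for n, d, s in settings.grid_trace if s == best]
    expected = min(tied, key=lambda nd: (nd[0], float("inf")
                                         if nd[1] is None else nd[1]))
    assert (settings.n_trees, settings.max_depth) == expected


def test_tune_pure_noise_oob_near_half():
    rng = np.random.default_rng(4)
    t = log_table(["CSIS"] * 12 + ["Control"] * 12,
                  rng.normal(size=(24, 10)))
    settings = mp.tune_rf_oob(t, ("CSIS", "Control"), grid=SMALL_GRID,
                              seed=1)
    assert 0.2 <= settings.oob_score <= 0.8


def test_tune_deterministic():
    t = separable_table(seed=2)
    a = mp.tune_rf_oob(t, ("CSIS", "Control"), grid=SMALL_GRID, seed=5)
    b = mp.tune_rf_oob(t, ("CSIS", "Control"), grid=SMALL_GRID, seed=5)
    assert (a.n_trees, a.max_depth, a.oob_score) == \
           (b.n_trees, b.max_depth, b.oob_score)


def test_evaluate_separable_high_accuracy(config):
    t = separable_table(seed=6, delta=8.0)
    settings = mp.RfSettings(n_trees=200, max_depth=None, oob_score=1.0)
    rep = mp.evaluate_rf(t, ("CSIS", "Control"), settings, config)
    assert rep.accuracy >= 95.0
    assert rep.total == 20 * config.cv_repeats   # each sample once per repeat


def test_evaluate_label_permuted_near_chance(config):
    rng = np.random.default_rng(8)
    t = log_table(["CSIS"] * 10 + ["Control"] * 10,
                  rng.normal(size=(20, 12)))
    settings = mp.RfSettings(n_trees=100, max_depth=None, oob_score=0.5)
    rep = mp.evaluate_rf(t, ("CSIS", "Control"), settings,
                         config.replace(cv_repeats=5))
    assert 35.0 <= rep.accuracy <= 65.0


def test_importances_sum_to_one_and_rank_informative_first():
    t = separable_table(seed=1, delta=4.0)
    settings = mp.RfSettings(n_trees=200, max_depth=None, oob_score=1.0)
    imps = mp.rf_importance(t, ("CSIS", "Control"), settings, seed=0,
                            n_average=3)
    total = sum(i.importance for i in imps)
    assert total == pytest.approx(1.0, abs=1e-9)
    assert imps[0].metabolite == "M0"
    assert imps[0].rank == 1
    ranks = [i.rank for i in imps]
    assert ranks == list(range(1, len(imps) + 1))


def test_importance_permutation_equivariance():
    """Permuting feature columns permutes the importances up to the
    randomness of per-split feature subsampling: the informative feature
    keeps rank 1 and every averaged importance moves only a little."""
    t = separable_table(seed=3, m=6)
    settings = mp.RfSettings(n_trees=500, max_depth=None, oob_score=1.0)
    base = {i.metabolite: i.importance
            for i in mp.rf_importance(t, ("CSIS", "Control"), settings,
                                      seed=2, n_average=10)}
    perm = [3, 0, 5, 1, 4, 2]
    t2 = PeakTable(t.samples,
                   [t.metabolites[j] for j in perm],
                   t.areas[:, perm], stage="log")
    permuted_list = mp.rf_importance(t2, ("CSIS", "Control"), settings,
                                     seed=2, n_average=10)
    permuted = {i.metabolite: i.importance for i in permuted_list}
    assert permuted_list[0].metabolite == "M0"
    for name in base:
        assert permuted[name] == pytest.approx(base[name], abs=0.05)


def test_oob_tracks_cv_accuracy(config, strong_design):
    """OOB score of the tuned forest agrees with repeated-CV accuracy
    within 10 percentage points on planted-signal data."""
    table, _ = mp.simulate_peak_table(strong_design, 13)
    _, log_t = prepare_log(table, config)
    settings = mp.tune_rf_oob(log_t, ("CSISFlx", "CSIS"),
                              grid=((500, None),), seed=3)
    rep = mp.evaluate_rf(log_t, ("CSISFlx", "CSIS"), settings,
                         config.replace(cv_repeats=5))
    assert abs(settings.oob_score * 100 - rep.accuracy) <= 10.0
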