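"""t-tests, Benjamini-Hochberg adjustment and DEM gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metabopanel as mp
from conftest import brute_force_bh
from metabopanel.errors import SchemaError
from metabopanel.peaktable import Metabolite, PeakTable, SampleMeta


def log_table(groups, values):
    """Build a log-stage table directly (values: n x m)."""
    values = np.asarray(values, dtype=float)
    samples = [SampleMeta(f"s{i}", g, injection_order=i + 1)
               for i, g in enumerate(groups)]
    mets = [Metabolite(f"M{j}") for j in range(values.shape[1])]
    return PeakTable(samples, mets, values, stage="log")


def test_ttest_identical_groups_p_one():
    t = log_table(["Control"] * 3 + ["CSIS"] * 3,
                  [[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
    (res,) = mp.ttest_per_metabolite(t, ("CSIS", "Control"))
    # same values in both groups: t = 0, p = 1
    assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_ttest_strong_separation():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1e-4, size=(4, 1))
    b = 1.0 + rng.normal(0.0, 1e-4, size=(4, 1))
    t = log_table(["Control"] * 4 + ["CSIS"] * 4, np.vstack([a, b]))
    (res,) = mp.ttest_per_metabolite(t, ("CSIS", "Control"))
    assert res.p_value < 1e-6


def test_ttest_two_vs_two_hand_computed():
    """Groups {1,2} vs {3,5}: pooled-variance t = -2.23607, p = 0.154845
    (df = 2, closed-form Student CDF)."""
    t = log_table(["CSIS", "CSIS", "Control", "Control"],
                  [[1.0], [2.0], [3.0], [5.0]])
    (res,) = mp.ttest_per_metabolite(t, ("CSIS", "Control"))
    assert res.t_statistic == pytest.approx(-2.2360679, abs=1e-6)
    assert res.p_value == pytest.approx(0.1548457, abs=1e-6)


def test_ttest_degenerate_zero_variance_equal_means():
    t = log_table(["CSIS", "CSIS", "Control", "Control"],
                  [[2.0], [2.0], [2.0], [2.0]])
    (res,) = mp.ttest_per_metabolite(t, ("CSIS", "Control"))
    assert (res.t_statistic, res.p_value) == (0.0, 1.0)


def test_bh_hand_computed_step_up():
    assert mp.bh_adjust([0.01, 0.02, 0.03, 0.04]) == \
        pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert mp.bh_adjust([0.123]) == pytest.approx([0.123])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                max_size=50))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_bh_matches_brute_force_and_bounds(ps):
    q = np.array(mp.bh_adjust(ps))
    assert np.all(q >= np.asarray(ps) - 1e-15)
    assert np.all(q <= 1.0)
    np.testing.assert_allclose(q, brute_force_bh(ps), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(Exception):
        mp.bh_adjust([0.5, 1.2])


def tss_table(groups, values):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    samples = [SampleMeta(f"s{i}", g, injection_order=i + 1)
               for i, g in enumerate(groups)]
    mets = [Metabolite(f"M{j}") for j in range(values.shape[1])]
    return PeakTable(samples, mets, values, stage="tss")


def test_fold_change_identity_and_doubling():
    t = tss_table(["CSIS", "CSIS", "Control", "Control"],
                  [[2.0, 1.0], [2.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    fcs = {f.metabolite: f.fc for f in mp.fold_change(t, ("CSIS", "Control"))}
    # after TSS: CSIS rows (2/3, 1/3), Control rows (1/2, 1/2)
    assert fcs["M0"] == pytest.approx((2 / 3) / 0.5)
    assert fcs["M1"] == pytest.approx((1 / 3) / 0.5)


def test_fold_change_orientation_first_over_second():
    t = tss_table(["CSISFlx"] * 2 + ["CSIS"] * 2,
                  [[4.0, 1.0]] * 2 + [[2.0, 1.0]] * 2)
    fcs = mp.fold_change(t, ("CSISFlx", "CSIS"))
    assert fcs[0].fc > 1.0   # treated over untreated


def test_planted_fc_recovered_through_dem(config):
    """A planted FC like the published succinate ratio (2.42) is estimated
    within 10 % at large n."""
    design = mp.SimDesign(
        n_per_group={"Control": 60, "ControlFlx": 60, "CSIS": 2,
                     "CSISFlx": 2},
        n_planted={"ControlFlx:Control": 1},
        fc_up_range=(2.42, 2.42), frac_down=0.0, drift_amplitude=0.0)
    table, truth = mp.simulate_peak_table(design, 6)
    (j, fc), = truth.planted["ControlFlx:Control"].items()
    study = table.subset_samples(np.nonzero(table.study_mask)[0])
    t = mp.tss(study)
    est = {f.metabolite: f.fc
           for f in mp.fold_change(t, ("ControlFlx", "Control"))}
    name = table.metabolite_names[j]
    assert est[name] == pytest.approx(2.42, rel=0.10)


@pytest.mark.parametrize("p_adj,fc,expected", [
    (0.03, 1.5, True),
    (0.03, 1.1, False),    # dead-band
    (0.06, 3.0, False),    # FDR gate
    (0.03, 0.5, True),
    (0.05, 1.5, False),    # strict: p_adj must be < alpha
])
def test_dem_gating(config, p_adj, fc, expected):
    from metabopanel.dem import FoldChange, TtestResult
    records = mp.call_dems(
        [TtestResult("M0", min(p_adj, 1.0), 1.0)], [p_adj],
        [FoldChange("M0", fc)], config, "CSIS:Control")
    assert records[0].is_dem is expected


def test_call_dems_misaligned_inputs_error(config):
    from metabopanel.dem import FoldChange, TtestResult
    with pytest.raises(SchemaError):
        mp.call_dems([TtestResult("A", 0.1, 1.0)], [0.1],
                     [FoldChange("B", 2.0)], config)


def test_dem_records_sorted_ascending_fc(config):
    from metabopanel.dem import FoldChange, TtestResult
    tests = [TtestResult(f"M{i}", 0.001, 1.0) for i in range(4)]
    fcs = [FoldChange("M0", 3.0), FoldChange("M1", 0.4),
           FoldChange("M2", 2.0), FoldChange("M3", 0.6)]
    recs = mp.call_dems(tests, [0.01] * 4, fcs, config)
    assert [r.fc for r in recs] == [0.4, 0.6, 2.0, 3.0]
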