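"""Drift correction, QC gates, total-sum scaling and log transform."""

import numpy as np
import pytest

import metabopanel as mp
from metabopanel.errors import InsufficientQcError, SchemaError, StageError
from metabopanel.peaktable import Metabolite, PeakTable, SampleMeta


def make_table(areas, roles=None, orders=None, dilutions=None,
               dil_stage=None, groups=None, stage="raw"):
    areas = np.asarray(areas, dtype=float)
    n, m = areas.shape
    roles = roles or ["study"] * n
    orders = orders or list(range(1, n + 1))
    dilutions = dilutions or [1.0] * n
    dil_stage = dil_stage or ["none"] * n
    groups = groups or ["Control"] * n
    samples = [
        SampleMeta(f"s{i}", groups[i] if roles[i] == "study" else "QC",
                   role=roles[i], dilution=dilutions[i],
                   dilution_stage=dil_stage[i], injection_order=orders[i])
        for i in range(n)
    ]
    mets = [Metabolite(f"M{j}") for j in range(m)]
    return PeakTable(samples, mets, areas, stage=stage)


def test_tss_log_hand_computed_row():
    table = make_table([[2.0, 3.0, 5.0]])
    logt = mp.tss_log(table)
    np.testing.assert_allclose(
        logt.areas[0], [-0.69897, -0.52288, -0.30103], atol=5e-5)


def test_tss_rows_sum_to_one(simulated):
    table, _, _ = simulated
    t = mp.tss(table)
    np.testing.assert_allclose(t.areas.sum(axis=1), 1.0, atol=1e-9)


def test_all_equal_row_gives_log_of_one_over_m():
    m = 7
    table = make_table([[4.0] * m])
    logt = mp.tss_log(table)
    np.testing.assert_allclose(logt.areas[0], np.log10(1.0 / m), rtol=1e-12)


def test_tss_scale_invariance_per_sample():
    base = np.array([[1.0, 2.0, 7.0], [3.0, 3.0, 4.0]])
    doubled = base.copy()
    doubled[0] *= 2
    a = mp.tss(make_table(base)).areas
    b = mp.tss(make_table(doubled)).areas
    np.testing.assert_allclose(a[0], b[0], rtol=1e-12)


def test_tss_zero_total_sample_errors():
    with pytest.raises(SchemaError):
        mp.tss(make_table([[0.0, 0.0], [1.0, 2.0]]))


def test_log_zero_handling_half_minimum():
    table = make_table([[0.0, 8.0], [2.0, 8.0], [4.0, 4.0]])
    t = mp.tss(table)
    logt = mp.log_transform(t)
    # the zero entry is replaced by half the smallest positive TSS value
    col = t.areas[:, 0]
    expected = np.log10(col[col > 0].min() / 2.0)
    assert logt.areas[0, 0] == pytest.approx(expected)


def test_stage_order_enforced(simulated):
    table, _, _ = simulated
    with pytest.raises(StageError):
        mp.log_transform(table)           # raw -> log skips tss
    t = mp.tss(table)
    with pytest.raises(StageError):
        mp.tss(t)                          # tss twice
    logt = mp.log_transform(t)
    with pytest.raises(StageError):
        mp.qc_normalize(logt)              # backwards


def test_qc_normalize_requires_two_qcs():
    table = make_table(np.ones((3, 2)), roles=["study", "study", "qc_pooled"])
    with pytest.raises(InsufficientQcError):
        mp.qc_normalize(table)


def test_qc_normalize_identity_without_drift_or_noise():
    """Noiseless constant QCs: areas unchanged to 1e-9 relative."""
    n, m = 10, 4
    rng = np.random.default_rng(0)
    areas = rng.lognormal(10, 0.3, size=(n, m))
    qc_rows = [2, 5, 8]
    areas[qc_rows] = areas.mean(axis=0)    # identical QC injections
    roles = ["qc_pooled" if i in qc_rows else "study" for i in range(n)]
    table = make_table(areas, roles=roles)
    corrected, report = mp.qc_normalize(table)
    np.testing.assert_allclose(corrected.areas, areas, rtol=1e-9)
    assert not any(m_.fit_degenerate for m_ in report.metrics)


def test_qc_normalize_removes_exact_linear_drift():
    """QC areas exactly linear (1.0 -> 1.2): residual QC CV% < 1 %."""
    n, m = 30, 3
    rng = np.random.default_rng(1)
    base = rng.lognormal(10, 0.2, size=(1, m))
    orders = np.arange(1, n + 1)
    drift = 1.0 + 0.2 * (orders - 1) / (n - 1)
    qc_rows = list(range(0, n, 5))
    areas = np.vstack([
        base[0] * drift[i] * (1.0 if i in qc_rows else
                              rng.lognormal(0, 0.2, size=m))
        for i in range(n)])
    roles = ["qc_pooled" if i in qc_rows else "study" for i in range(n)]
    table = make_table(areas, roles=roles, orders=list(orders))
    corrected, report = mp.qc_normalize(table)
    for metric in report.metrics:
        assert metric.cv_percent < 1.0


def test_qc_normalize_order_consistency():
    """Shuffling row order (keeping each row's injection metadata) does not
    change any sample's corrected value."""
    design = mp.SimDesign(n_metabolites=10, n_planted={})
    table, _ = mp.simulate_peak_table(design, 4)
    corrected, _ = mp.qc_normalize(table)
    perm = np.random.default_rng(0).permutation(table.n_samples)
    shuffled = table.subset_samples(perm)
    corrected2, _ = mp.qc_normalize(shuffled)
    lookup = dict(zip(corrected2.sample_ids, corrected2.areas))
    for sid, row in zip(corrected.sample_ids, corrected.areas):
        np.testing.assert_allclose(row, lookup[sid], rtol=1e-9)


def test_qc_filter_cv_gate(config):
    design = mp.SimDesign(n_metabolites=6, n_planted={})
    table, _ = mp.simulate_peak_table(design, 9)
    corrected, report = mp.qc_normalize(table)
    report.metrics[2].cv_percent = 45.0    # force one failure
    filtered = mp.qc_filter(corrected, report, config)
    assert filtered.n_metabolites == 5
    assert report.metrics[2].metabolite in report.excluded
    assert report.metrics[2].kept is False


def test_qc_filter_noiseless_table_keeps_everything(config):
    design = mp.SimDesign(cv_technical=0.001, n_metabolites=20,
                          n_planted={})
    table, _ = mp.simulate_peak_table(design, 10)
    corrected, report = mp.qc_normalize(table)
    filtered = mp.qc_filter(corrected, report, config)
    assert filtered.n_metabolites == 20
    assert report.excluded == []
    # perfect dilution linearity is reflected in the report
    assert all(m.linearity_r2_pre > 0.99 for m in report.metrics)
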