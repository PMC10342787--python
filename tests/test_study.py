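import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionpace import (
    CohortSpec,
    ResultsTable,
    SYNCAV_OFFSETS,
    build_table2,
    make_cohort,
    mean_vat_by_offset,
    optimal_offset,
    optimized_column,
    paired_ci,
    paired_t_summary,
    relative_decrease,
    run_study,
)


def table_from_matrix(data: dict[str, list[float]], patients=None) -> ResultsTable:
    vat = pd.DataFrame(data)
    vat.index = patients or [f"P{i+1:02d}" for i in range(len(vat))]
    vat.index.name = "patient_id"
    return ResultsTable(vat=vat, metrics=pd.DataFrame())


def synthetic_offset_table(curves: list[dict[int, float]]) -> ResultsTable:
    data = {f"syncav_{o}": [c[o] for c in curves] for o in SYNCAV_OFFSETS}
    return table_from_matrix(data)


@pytest.fixture(scope="module")
def single_patient_table():
    cohort = make_cohort(CohortSpec(n_patients=1))
    return run_study(cohort)


def test_single_patient_table_is_complete(single_patient_table):
    assert single_patient_table.vat.shape == (1, 14)
    assert not single_patient_table.vat.isna().any().any()


def test_native_column_matches_calibration_target(single_patient_table):
    cohort = make_cohort(CohortSpec(n_patients=1))
    native = float(single_patient_table.vat.iloc[0]["native"])
    assert abs(native - cohort[0].target_native_vat_ms) <= 1.0


def test_study_is_deterministic(single_patient_table):
    again = run_study(make_cohort(CohortSpec(n_patients=1)))
    pd.testing.assert_frame_equal(single_patient_table.vat, again.vat)


# --- paired statistics ----------------------------------------------------

def test_paired_ci_matches_closed_form_on_random_data():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(3, 30))
        a = rng.normal(150, 20, size=n)
        b = rng.normal(140, 15, size=n)
        table = table_from_matrix({"m_a": list(a), "m_b": list(b)})
        s = paired_t_summary(table, "m_a", "m_b")
        d = a - b
        mean, sd = d.mean(), d.std(ddof=1)
        tq = stats.t.ppf(0.975, n - 1)
        assert s.mean_diff_ms == pytest.approx(mean, abs=1e-9)
        assert s.ci95_low_ms == pytest.approx(mean - tq * sd / np.sqrt(n), abs=1e-9)
        assert s.ci95_high_ms == pytest.approx(mean + tq * sd / np.sqrt(n), abs=1e-9)
        # paired-mean identity holds to machine precision
        assert s.mean_diff_ms == pytest.approx(a.mean() - b.mean(), abs=1e-9)


def test_reported_ci_lower_bound_recovered():
    """mean 40.9, SD 25.7, n 14 -> 95% CI lower bound 26.1 at 1 d.p."""
    lo, hi = paired_ci(40.9, 25.7, 14)
    assert round(lo, 1) == 26.1
    assert hi == pytest.approx(55.8, abs=0.1)  # printed value used unrounded inputs


def test_identical_columns_are_degenerate():
    col = [150.0, 160.0, 170.0]
    table = table_from_matrix({"m_a": col, "m_b": col})
    s = paired_t_summary(table, "m_a", "m_b")
    assert s.degenerate
    assert s.mean_diff_ms == 0.0
    assert (s.ci95_low_ms, s.ci95_high_ms) == (0.0, 0.0)
    assert s.p_value == 1.0


def test_relative_decrease_reported_values():
    assert relative_decrease(40.9, 181.6) == 22.5
    assert relative_decrease(63.2, 181.6) == 34.8
    assert relative_decrease(22.3, 140.6) == 15.9
    assert relative_decrease(0.0, 123.0) == 0.0
    with pytest.raises(ValueError):
        relative_decrease(1.0, 0.0)


# --- offset optimization --------------------------------------------------

def test_optimal_offset_u_curve():
    curve = {o: 200.0 - 1.0 * o if o <= 40 else 160.0 + (o - 40) for o in SYNCAV_OFFSETS}
    table = synthetic_offset_table([curve])
    assert optimal_offset(table, "P01") == 40


def test_optimal_offset_tie_prefers_smaller():
    curve = {o: 100.0 if o in (30, 50) else 150.0 for o in SYNCAV_OFFSETS}
    table = synthetic_offset_table([curve])
    assert optimal_offset(table, "P01") == 30


def test_optimal_offset_monotone_curve_hits_boundary():
    curve = {o: 300.0 - o for o in SYNCAV_OFFSETS}
    table = synthetic_offset_table([curve])
    assert optimal_offset(table, "P01") == 110


def test_optimal_offset_missing_mode_raises(single_patient_table):
    table = ResultsTable(
        vat=single_patient_table.vat.drop(columns=["syncav_60"]),
        metrics=pd.DataFrame(),
    )
    with pytest.raises(ValueError):
        optimal_offset(table, table.vat.index[0])


def test_optimized_column_dominates_every_fixed_offset():
    rng = np.random.default_rng(9)
    curves = [
        {o: float(rng.uniform(100, 200)) for o in SYNCAV_OFFSETS} for _ in range(6)
    ]
    table = synthetic_offset_table(curves)
    opt = optimized_column(table)
    for o in SYNCAV_OFFSETS:
        assert (opt <= table.vat[f"syncav_{o}"] + 1e-12).all()
    # hence the mean reduction from any baseline is maximal for optimized
    assert opt.mean() == pytest.approx(
        min(np.mean([c[o] for c in curves]) for o in SYNCAV_OFFSETS), abs=1e-9
    ) or opt.mean() <= min(np.mean([c[o] for c in curves]) for o in SYNCAV_OFFSETS)


def test_mean_vat_by_offset_layout(single_patient_table):
    curve = mean_vat_by_offset(single_patient_table)
    assert list(curve.index) == list(SYNCAV_OFFSETS)


# --- summary table --------------------------------------------------------

def test_build_table2_layout_and_identities(single_patient_table):
    cohort = make_cohort(CohortSpec(n_patients=5))
    table = run_study(cohort)
    t2 = build_table2(table)
    assert len(t2) == 14
    assert list(t2.index[:3]) == ["native", "rv_only", "biv"]
    biv = t2.loc["biv"]
    assert (biv["diff_to_biv_ms"], biv["ci95_low_ms"], biv["ci95_high_ms"]) == (0, 0, 0)
    assert biv["p_value"] == 1.0
    biv_mean = table.vat["biv"].mean()
    for label in t2.index:
        expected = round(float(table.vat[label].mean() - biv_mean), 1)
        assert t2.loc[label, "diff_to_biv_ms"] == pytest.approx(expected, abs=0.05)
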