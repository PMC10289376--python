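"""Case aggregation, group tests, regressions and histograms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocurve.cohort import (
    CaseMorphometry,
    DegenerateVarianceError,
    aggregate_case,
    aggregate_cases_from_frame,
    aggregate_curvature_table,
    correlate,
    curvature_histogram,
    group_compare,
    normality_check,
    read_curvature_workbook,
    run_cohort_analysis,
)
from neurocurve.geometry import CurvatureProfile
from neurocurve.model import CaseRecord

from conftest import welch_oracle


def profile(curv, trace_id="T0", radius=0.5, length=30.0, excluded=False):
    return CurvatureProfile(
        trace_id=trace_id, arc_positions=np.empty(0),
        point_curvatures=np.empty(0), neurite_curvature=curv,
        neurite_radius=radius, trace_length=length, n_points=30,
        excluded=excluded)


def case(case_id, mean=0.4, sd=0.1, radius=0.5, values=None):
    vals = np.asarray(values if values is not None
                      else [mean - sd, mean, mean + sd], dtype=float)
    return CaseMorphometry(
        case_id=case_id, n_neurites=vals.size,
        mean_curvature=float(vals.mean()), sd_curvature=float(vals.std(ddof=1)),
        median_curvature=float(np.median(vals)), max_curvature=float(vals.max()),
        mean_radius=radius, total_length=100.0, curvatures=vals)


def record(case_id, group, age=50.0, score=0.0, dose=None):
    return CaseRecord(case_id, group, age, "F", score, dose)


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_case_hand_arithmetic():
    cm = aggregate_case([profile(c) for c in (0.2, 0.4, 0.6)], "S1")
    assert cm.mean_curvature == pytest.approx(0.4)
    assert cm.sd_curvature == pytest.approx(0.2)
    assert cm.median_curvature == pytest.approx(0.4)
    assert cm.max_curvature == pytest.approx(0.6)
    assert cm.n_neurites == 3


def test_aggregate_case_equal_values_zero_sd():
    cm = aggregate_case([profile(0.3)] * 5, "S1")
    assert cm.sd_curvature == 0.0


def test_aggregate_case_drops_excluded_and_requires_two():
    profs = [profile(0.2), profile(0.3), profile(9.9, excluded=True)]
    assert aggregate_case(profs, "S1").n_neurites == 2
    with pytest.raises(ValueError, match="S2"):
        aggregate_case([profile(0.2)], "S2")


def test_aggregate_case_gamma_monte_carlo(rng):
    """Sample mean/SD of 10000 gamma draws recover the generating
    moments within 3 standard errors."""
    shape, scale = 4.0, 0.1
    vals = rng.gamma(shape, scale, size=10_000)
    cm = aggregate_case([profile(v) for v in vals], "MC")
    mean, sd = shape * scale, math.sqrt(shape) * scale
    se_mean = sd / 100.0
    se_sd = sd / math.sqrt(2 * (10_000 - 1))
    assert abs(cm.mean_curvature - mean) < 3 * se_mean
    assert abs(cm.sd_curvature - sd) < 3 * se_sd


def test_aggregation_associative_across_datasets():
    """Pooling neurites in one go or concatenating dataset-level pools
    gives the identical case summary."""
    a = [profile(c) for c in (0.2, 0.5, 0.3)]
    b = [profile(c) for c in (0.6, 0.4)]
    pooled = aggregate_case(a + b, "S1")
    concat = aggregate_case(list(a) + list(b), "S1")
    assert pooled == concat
    frame = pd.DataFrame({
        "dataset_id": ["S1A"] * 3 + ["S1B"] * 2,
        "trace_id": [f"T{i}" for i in range(5)],
        "trace_length_um": 30.0,
        "neurite_curvature_um-1": [0.2, 0.5, 0.3, 0.6, 0.4],
        "neurite_radius_um": 0.5,
        "n_points": 30, "excluded_flag": False})
    from_frame = aggregate_cases_from_frame(frame)
    assert len(from_frame) == 1
    assert from_frame[0].mean_curvature == pytest.approx(pooled.mean_curvature)
    assert from_frame[0].sd_curvature == pytest.approx(pooled.sd_curvature)


# ---------------------------------------------------------------------------
# Welch comparison


def test_welch_textbook_example():
    """{1,2,3} vs {2,3,4}: t = -1.2247, df = 4, two-sided p ~ 0.288."""
    cases = [CaseMorphometry(f"S{i}", 2, float(v), 0.1, float(v), float(v),
                             0.5, 10.0, np.array([v, v], float))
             for i, v in ((1, 1.0), (2, 2.0), (3, 3.0))]
    cases += [CaseMorphometry(f"N{i}", 2, float(v), 0.1, float(v), float(v),
                              0.5, 10.0, np.array([v, v], float))
              for i, v in ((1, 2.0), (2, 3.0), (3, 4.0))]
    records = [record(f"S{i}", "schizophrenia") for i in (1, 2, 3)]
    records += [record(f"N{i}", "control") for i in (1, 2, 3)]
    res = group_compare(cases, records, "mean_curvature")
    assert res.t_statistic == pytest.approx(-1.224744871, abs=1e-6)
    assert res.df == pytest.approx(4.0)
    assert res.p_value == pytest.approx(0.2878641347, abs=1e-6)


def test_welch_identical_groups():
    vals = [0.3, 0.4, 0.5]
    cases = ([CaseMorphometry(f"S{i}", 2, v, 0.1, v, v, 0.5, 10.0,
                              np.array([v, v])) for i, v in enumerate(vals)]
             + [CaseMorphometry(f"N{i}", 2, v, 0.1, v, v, 0.5, 10.0,
                                np.array([v, v])) for i, v in enumerate(vals)])
    records = ([record(f"S{i}", "schizophrenia") for i in range(3)]
               + [record(f"N{i}", "control") for i in range(3)])
    res = group_compare(cases, records, "mean_curvature")
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_welch_degenerate_variance_raises():
    cases = ([CaseMorphometry(f"S{i}", 2, 0.5, 0.1, 0.5, 0.5, 0.5, 10.0,
                              np.array([0.5, 0.5])) for i in range(3)]
             + [CaseMorphometry(f"N{i}", 2, 0.3, 0.1, 0.3, 0.3, 0.5, 10.0,
                                np.array([0.3, 0.3])) for i in range(3)])
    records = ([record(f"S{i}", "schizophrenia") for i in range(3)]
               + [record(f"N{i}", "control") for i in range(3)])
    with pytest.raises(DegenerateVarianceError):
        group_compare(cases, records, "mean_curvature")


def test_welch_requires_two_cases_per_group():
    cases = [case("S1"), case("N1"), case("N2")]
    records = [record("S1", "schizophrenia"), record("N1", "control"),
               record("N2", "control")]
    with pytest.raises(ValueError, match="schizophrenia"):
        group_compare(cases, records, "mean_curvature")


def test_welch_agrees_with_hand_formula(rng):
    """Agreement with the independently coded Welch-Satterthwaite
    formula to 1e-10 on 100 random small samples."""
    for _ in range(100):
        nx, ny = rng.integers(2, 9, size=2)
        x = rng.normal(0.5, rng.uniform(0.05, 0.4), nx)
        y = rng.normal(0.4, rng.uniform(0.05, 0.4), ny)
        cases = ([CaseMorphometry(f"S{i}", 2, v, 0.1, v, v, 0.5, 10.0,
                                  np.array([v, v])) for i, v in enumerate(x)]
                 + [CaseMorphometry(f"N{i}", 2, v, 0.1, v, v, 0.5, 10.0,
                                    np.array([v, v])) for i, v in enumerate(y)])
        records = ([record(f"S{i}", "schizophrenia") for i in range(nx)]
                   + [record(f"N{i}", "control") for i in range(ny)])
        res = group_compare(cases, records, "mean_curvature")
        t, df, p = welch_oracle(x, y)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_group_test_unit_of_analysis_guard():
    """Inflating one case's neurite count must not change its weight."""
    base_vals = {"S1": 0.5, "S2": 0.6, "S3": 0.55,
                 "N1": 0.3, "N2": 0.4, "N3": 0.35}
    records = [record(c, "schizophrenia" if c.startswith("S") else "control")
               for c in base_vals]

    def build(n_neurites_s1):
        cases = []
        for cid, v in base_vals.items():
            n = n_neurites_s1 if cid == "S1" else 3
            vals = np.full(n, v)
            cases.append(CaseMorphometry(cid, n, v, 0.0, v, v, 0.5, 10.0, vals))
        return group_compare(cases, records, "mean_curvature")

    assert build(3).t_statistic == pytest.approx(build(300).t_statistic)


# ---------------------------------------------------------------------------
# normality, correlation, histograms


def test_shapiro_level_on_normal_samples():
    """For normal 8-point samples the test rejects at ~5%: p > 0.05 in
    >= 90% of 200 seeded draws."""
    hits = 0
    for seed in range(200):
        vals = np.random.default_rng(seed).normal(0.15, 0.03, 8)
        _, p = normality_check(vals)
        hits += p > 0.05
    assert hits >= 180


def test_shapiro_rejects_strong_bimodality(rng):
    vals = np.concatenate([rng.normal(0.0, 0.05, 25), rng.normal(2.0, 0.05, 25)])
    _, p = normality_check(vals)
    assert p < 0.05


def test_shapiro_domain_errors():
    with pytest.raises(ValueError):
        normality_check([1.0, 2.0])
    with pytest.raises(ValueError):
        normality_check([1.0] * 10)


def test_correlate_exact_linear():
    cases = [CaseMorphometry(f"S{i}", 2, v, 0.1, v, v, 0.5, 10.0,
                             np.array([v, v])) for i, v in enumerate([1.0, 2.0, 3.0])]
    records = [record(f"S{i}", "schizophrenia", score=2.0 * v)
               for i, v in enumerate([1.0, 2.0, 3.0])]
    res = correlate(cases, records, "mean_curvature", "hallucination_score")
    assert res.pearson_r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)


def test_correlate_exact_anticorrelation():
    xs = [0.0, 1.0, 2.0, 3.0]
    cases = [CaseMorphometry(f"S{i}", 2, x, 0.1, x, x, 0.5, 10.0,
                             np.array([x, x])) for i, x in enumerate(xs)]
    records = [record(f"S{i}", "schizophrenia", score=3.0 - x)
               for i, x in enumerate(xs)]
    res = correlate(cases, records, "mean_curvature", "hallucination_score")
    assert res.pearson_r == pytest.approx(-1.0)


def test_correlate_affine_invariance(rng):
    x = rng.normal(size=10)
    y = 0.7 * x + rng.normal(scale=0.4, size=10)
    cases = [CaseMorphometry(f"S{i}", 2, xi, 0.1, xi, xi, 0.5, 10.0,
                             np.array([xi, xi])) for i, xi in enumerate(x)]
    recs = [record(f"S{i}", "schizophrenia", score=0.0) for i in range(10)]
    base = stats.pearsonr(x, y).statistic
    # affine transform of x: r unchanged; negative scale flips sign
    cases2 = [CaseMorphometry(f"S{i}", 2, -3.0 * xi + 5.0, 0.1, xi, xi, 0.5,
                              10.0, np.array([xi, xi])) for i, xi in enumerate(x)]
    for i, r in enumerate(recs):
        r.hallucination_score = float(y[i]) if y[i] > 0 else 0.0
    y2 = np.array([r.hallucination_score for r in recs])
    r1 = correlate(cases, recs, "mean_curvature", "hallucination_score").pearson_r
    r2 = correlate(cases2, recs, "mean_curvature", "hallucination_score").pearson_r
    assert r2 == pytest.approx(-r1, rel=1e-12)
    assert r1 == pytest.approx(stats.pearsonr(x, y2).statistic, rel=1e-12)


def test_correlate_null_p_uniform(rng):
    """With y independent of x, p-values over repeated draws are
    uniform (Kolmogorov-Smirnov sanity at n = 8)."""
    ps = []
    for _ in range(1000):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        ps.append(stats.pearsonr(x, y).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_correlate_domain_errors():
    cases = [CaseMorphometry(f"S{i}", 2, 0.5, 0.1, 0.5, 0.5, 0.5, 10.0,
                             np.array([0.5, 0.5])) for i in range(4)]
    records = [record(f"S{i}", "schizophrenia", score=float(i)) for i in range(4)]
    with pytest.raises(ValueError, match="zero variance"):
        correlate(cases, records, "mean_curvature", "hallucination_score")
    with pytest.raises(ValueError, match="pairs"):
        correlate(cases[:2], records[:2], "mean_curvature", "hallucination_score")


def test_histogram_hand_example():
    h = curvature_histogram([0.05, 0.15, 0.15, 0.25], bin_width=0.1)
    np.testing.assert_allclose(h.relative_frequencies, [0.25, 0.5, 0.25])
    np.testing.assert_allclose(h.bin_edges, [0.0, 0.1, 0.2, 0.3])


def test_histogram_single_bin_and_boundary():
    h = curvature_histogram([0.05, 0.07, 0.01], bin_width=0.1)
    np.testing.assert_allclose(h.relative_frequencies, [1.0])
    # a value on a bin edge belongs to the right-open upper bin
    h2 = curvature_histogram([0.1, 0.05], bin_width=0.1)
    np.testing.assert_allclose(h2.relative_frequencies, [0.5, 0.5])


def test_histogram_tail_mass_threshold():
    vals = np.arange(0.10, 0.80, 0.01)  # none reaches 0.8
    assert curvature_histogram(vals).tail_mass == 0.0
    assert curvature_histogram([0.5, 0.8, 1.2]).tail_mass == pytest.approx(2 / 3)


def test_histogram_sums_to_one_and_order_invariant(rng):
    vals = rng.gamma(4.0, 0.1, size=500)
    h1 = curvature_histogram(vals)
    h2 = curvature_histogram(rng.permutation(vals))
    assert h1.relative_frequencies.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_array_equal(h1.relative_frequencies,
                                  h2.relative_frequencies)


def test_histogram_bad_bin_width():
    with pytest.raises(ValueError):
        curvature_histogram([0.1, 0.2], bin_width=0.0)


# ---------------------------------------------------------------------------
# full analysis + workbook ingestion


def _small_frame(case_vals):
    rows = []
    for cid, vals in case_vals.items():
        for j, v in enumerate(vals):
            rows.append({"dataset_id": f"{cid}A", "trace_id": f"T{j}",
                         "trace_length_um": 30.0, "neurite_curvature_um-1": v,
                         "neurite_radius_um": 0.4 + 0.1 * v, "n_points": 30,
                         "excluded_flag": False})
    return pd.DataFrame(rows)


def test_run_cohort_analysis_missing_record_lists_cases():
    frame = _small_frame({"S1": [0.4, 0.5], "S2": [0.5, 0.6],
                          "N1": [0.3, 0.4], "N2": [0.2, 0.3]})
    records = [record("S1", "schizophrenia"), record("S2", "schizophrenia"),
               record("N1", "control")]
    with pytest.raises(ValueError, match="N2"):
        run_cohort_analysis(frame, records)


def test_run_cohort_analysis_reports_both_mean_conventions(rng):
    vals = {f"S{i}": rng.gamma(16, 0.035, 20) for i in (1, 2, 3)}
    vals |= {f"N{i}": rng.gamma(16, 0.022, 30) for i in (1, 2, 3)}
    frame = _small_frame(vals)
    records = ([record(f"S{i}", "schizophrenia", age=40 + i, score=3.0)
                for i in (1, 2, 3)]
               + [record(f"N{i}", "control", age=40 + i) for i in (1, 2, 3)])
    rep = run_cohort_analysis(frame, records)
    gm = rep.group_means["schizophrenia"]
    pooled = np.concatenate([vals[f"S{i}"] for i in (1, 2, 3)])
    assert gm["mean_curvature_neurite_pooled"] == pytest.approx(pooled.mean())
    assert gm["mean_curvature_case_mean"] == pytest.approx(
        np.mean([vals[f"S{i}"].mean() for i in (1, 2, 3)]))
    assert {c.parameter for c in rep.comparisons} == {
        "mean_curvature", "sd_curvature", "mean_radius"}
    assert rep.n_tests >= 5


def test_workbook_ingestion_long_and_sheet_layouts(tmp_path, rng):
    """Both supplementary-workbook layouts load into the same long table,
    and its aggregation matches direct per-case computation."""
    data = {f"S{i}": rng.gamma(16, 0.035, 40) for i in (1, 2)}
    data |= {f"N{i}": rng.gamma(16, 0.022, 40) for i in (1, 2)}

    long_path = tmp_path / "long.xlsx"
    pd.DataFrame({
        "case_id": np.repeat(list(data), [len(v) for v in data.values()]),
        "neurite curvature (1/um)": np.concatenate(list(data.values())),
    }).to_excel(long_path, index=False)

    sheet_path = tmp_path / "sheets.xlsx"
    with pd.ExcelWriter(sheet_path) as xw:
        for cid, vals in data.items():
            pd.DataFrame({"curvature": vals}).to_excel(xw, sheet_name=cid,
                                                       index=False)

    t_long = read_curvature_workbook(long_path)
    t_sheet = read_curvature_workbook(sheet_path)
    for table in (t_long, t_sheet):
        cases = {c.case_id: c for c in aggregate_curvature_table(table)}
        assert set(cases) == set(data)
        for cid, vals in data.items():
            assert cases[cid].mean_curvature == pytest.approx(vals.mean())
            assert cases[cid].sd_curvature == pytest.approx(vals.std(ddof=1))
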