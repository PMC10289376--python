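"""Case- and group-level statistics of neurite morphometry.

The unit of analysis for all group comparisons is the **case**, not the
neurite: per-neurite summary curvatures are first pooled over every
dataset belonging to a case (:func:`aggregate_case`), and the two-sample
tests then compare one value per case (n = cases per group).  This keeps
the tests honest about the effective sample size — a case contributing
ten times more neurites does not get ten times the weight.

Implemented procedures:

* Welch's two-sided t-test (unequal variances, Welch–Satterthwaite df)
  for group differences in mean curvature, curvature SD and radius;
* Shapiro–Wilk normality check of case-level values;
* Pearson correlation with ordinary least-squares line for
  structure–covariate relations (curvature SD vs age in controls,
  mean curvature vs hallucination score, mean curvature vs
  antipsychotic dose);
* relative-frequency histograms of per-neurite curvature in fixed-width
  bins (default 0.1 1/μm) with the mass beyond a tail threshold
  (default 0.8 1/μm) reported separately.

No multiple-testing correction is applied; the report states the number
of tests performed so the reader can judge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CurvatureProfile
from .model import CaseRecord, dataset_to_case

__all__ = [
    "CaseMorphometry",
    "GroupComparison",
    "RegressionResult",
    "CurvatureHistogram",
    "CohortReport",
    "DegenerateVarianceError",
    "aggregate_case",
    "aggregate_cases_from_frame",
    "group_compare",
    "normality_check",
    "correlate",
    "curvature_histogram",
    "run_cohort_analysis",
    "read_curvature_workbook",
    "aggregate_curvature_table",
    "TAIL_THRESHOLD",
]

TAIL_THRESHOLD = 0.8  # 1/μm; controls show almost no curvature mass beyond this


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance: the Welch statistic is undefined.

    Raised explicitly (rather than returning ±inf) because in practice
    this signals a misconfigured synthetic cohort or a unit-of-analysis
    mistake, not a real finding.
    """


@dataclass
class CaseMorphometry:
    """Case-level summary of the per-neurite curvature distribution."""

    case_id: str
    n_neurites: int
    mean_curvature: float      # 1/μm
    sd_curvature: float        # 1/μm, sample SD (n-1 denominator)
    median_curvature: float    # 1/μm
    max_curvature: float       # 1/μm
    mean_radius: float         # μm
    total_length: float        # μm
    curvatures: np.ndarray = field(repr=False, compare=False,
                                   default_factory=lambda: np.empty(0))


@dataclass
class GroupComparison:
    """Two-sided Welch's t-test between case-level group values."""

    parameter: str
    mean_schizophrenia: float
    mean_control: float
    t_statistic: float
    df: float
    p_value: float
    n_schizophrenia: int
    n_control: int
    sided: str = "two-sided"


@dataclass
class RegressionResult:
    """Pearson correlation + OLS line between two case-level quantities."""

    predictor: str
    response: str
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass
class CurvatureHistogram:
    """Relative-frequency histogram of per-neurite curvature for one case.

    Bins are right-open ``[k·w, (k+1)·w)`` starting at 0; the last bin is
    extended as far as the data require.  ``tail_mass`` is the fraction
    of neurites with curvature ≥ ``tail_threshold``.
    """

    case_id: str
    bin_edges: np.ndarray          # length n_bins + 1
    relative_frequencies: np.ndarray
    tail_threshold: float
    tail_mass: float


def _case_values(values: Sequence[float], case_id: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError(
            f"case {case_id}: needs ≥ 2 included neurites, got {arr.size}")
    return arr


def aggregate_case(
    profiles: Sequence[CurvatureProfile],
    case_id: str,
) -> CaseMorphometry:
    """Pool per-neurite summaries of all of a case's datasets.

    Excluded profiles are dropped; statistics use every remaining
    neurite of the case regardless of which dataset it came from, so
    aggregation is associative across datasets.  SD uses the sample
    (n-1) denominator.  Raises ``ValueError`` (naming the case) with
    fewer than two included neurites.
    """
    included = [p for p in profiles if not p.excluded]
    curv = _case_values([p.neurite_curvature for p in included], case_id)
    radii = np.array([p.neurite_radius for p in included], dtype=float)
    lengths = np.array([p.trace_length for p in included], dtype=float)
    return CaseMorphometry(
        case_id=case_id,
        n_neurites=curv.size,
        mean_curvature=float(curv.mean()),
        sd_curvature=float(curv.std(ddof=1)),
        median_curvature=float(np.median(curv)),
        max_curvature=float(curv.max()),
        mean_radius=float(radii.mean()),
        total_length=float(lengths.sum()),
        curvatures=curv)


def aggregate_cases_from_frame(
    morphometry: pd.DataFrame,
    case_of_dataset=dataset_to_case,
) -> list[CaseMorphometry]:
    """Aggregate a tidy per-neurite table (``morphometry_frame`` layout)
    into one :class:`CaseMorphometry` per case.

    ``case_of_dataset`` maps dataset labels to case labels (default:
    strip the trailing dataset letter, ``S8A → S8``).
    """
    df = morphometry[~morphometry["excluded_flag"].astype(bool)].copy()
    df["case_id"] = df["dataset_id"].astype(str).map(case_of_dataset)
    out = []
    for case_id, sub in df.groupby("case_id", sort=True):
        curv = sub["neurite_curvature_um-1"].to_numpy(dtype=float)
        curv = _case_values(curv, str(case_id))
        radii = sub["neurite_radius_um"].to_numpy(dtype=float)
        lengths = sub["trace_length_um"].to_numpy(dtype=float)
        out.append(CaseMorphometry(
            case_id=str(case_id), n_neurites=curv.size,
            mean_curvature=float(curv.mean()),
            sd_curvature=float(curv.std(ddof=1)),
            median_curvature=float(np.median(curv)),
            max_curvature=float(curv.max()),
            mean_radius=float(radii.mean()),
            total_length=float(lengths.sum()),
            curvatures=curv))
    return out


_CASE_FIELDS = ("mean_curvature", "sd_curvature", "median_curvature",
                "max_curvature", "mean_radius", "total_length", "n_neurites")
_RECORD_FIELDS = ("age", "hallucination_score", "cpz_dose")


def _field_value(case: Optional[CaseMorphometry], record: Optional[CaseRecord],
                 name: str) -> float:
    if name in _CASE_FIELDS:
        if case is None:
            raise KeyError(f"no morphometry for field {name!r}")
        return float(getattr(case, name))
    if name in _RECORD_FIELDS:
        if record is None:
            raise KeyError(f"no case record for field {name!r}")
        v = getattr(record, name)
        return math.nan if v is None else float(v)
    raise KeyError(f"unknown case-level field {name!r}")


def _records_by_id(records: Sequence[CaseRecord]) -> dict[str, CaseRecord]:
    return {r.case_id: r for r in records}


def group_compare(
    cases: Sequence[CaseMorphometry],
    records: Sequence[CaseRecord],
    parameter: str,
) -> GroupComparison:
    """Two-sided Welch's t-test of *parameter* between the two groups.

    Operates on exactly one value per case.  Group order in the
    statistic is (schizophrenia − control).  Raises ``ValueError`` when
    a group has fewer than two cases, ``DegenerateVarianceError`` when
    both groups are constant.
    """
    recmap = _records_by_id(records)
    groups: dict[str, list[float]] = {"schizophrenia": [], "control": []}
    for case in cases:
        rec = recmap.get(case.case_id)
        if rec is None:
            raise ValueError(f"no cohort record for case {case.case_id}")
        groups[rec.group].append(_field_value(case, rec, parameter))
    sz = np.asarray(groups["schizophrenia"], dtype=float)
    ct = np.asarray(groups["control"], dtype=float)
    for name, arr in (("schizophrenia", sz), ("control", ct)):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} case(s); needs ≥ 2")
    if sz.std(ddof=1) == 0.0 and ct.std(ddof=1) == 0.0:
        raise DegenerateVarianceError(
            f"parameter {parameter!r}: zero variance in both groups")
    res = stats.ttest_ind(sz, ct, equal_var=False)
    return GroupComparison(
        parameter=parameter,
        mean_schizophrenia=float(sz.mean()),
        mean_control=float(ct.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n_schizophrenia=int(sz.size),
        n_control=int(ct.size))


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk test of case-level values; returns (W, p).

    Valid for 3 ≤ n ≤ 5000; a constant vector has no defined statistic
    and raises ``ValueError``.
    """
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def correlate(
    cases: Sequence[CaseMorphometry],
    records: Sequence[CaseRecord],
    x_field: str,
    y_field: str,
    case_filter: Optional[str] = None,
) -> RegressionResult:
    """Pearson correlation and OLS line between two case-level fields.

    Fields may come from the morphometry summary (``mean_curvature``,
    ``sd_curvature``, ...) or the clinical record (``age``,
    ``hallucination_score``, ``cpz_dose``).  ``case_filter`` optionally
    restricts to one group.  Cases with a missing value on either axis
    are dropped; ≥ 3 complete pairs are required and a zero-variance
    axis raises.
    """
    recmap = _records_by_id(records)
    xs, ys = [], []
    for case in cases:
        rec = recmap.get(case.case_id)
        if rec is None:
            raise ValueError(f"no cohort record for case {case.case_id}")
        if case_filter is not None and rec.group != case_filter:
            continue
        x = _field_value(case, rec, x_field)
        y = _field_value(case, rec, y_field)
        if math.isnan(x) or math.isnan(y):
            continue
        xs.append(x)
        ys.append(y)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise ValueError(
            f"correlation {x_field!r}~{y_field!r}: needs ≥ 3 complete pairs, "
            f"got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError(
            f"correlation {x_field!r}~{y_field!r}: zero variance on one axis")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return RegressionResult(
        predictor=x_field, response=y_field,
        pearson_r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept), n=int(x.size))


def curvature_histogram(
    profiles_or_values: Union[Sequence[CurvatureProfile], Sequence[float]],
    bin_width: float = 0.1,
    case_id: str = "",
    tail_threshold: float = TAIL_THRESHOLD,
) -> CurvatureHistogram:
    """Relative-frequency histogram of per-neurite curvature.

    Bins are right-open ``[k·w, (k+1)·w)`` from 0, extended to cover the
    maximum value; frequencies sum to 1 over the included neurites.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be > 0, got {bin_width}")
    vals = []
    for item in profiles_or_values:
        if isinstance(item, CurvatureProfile):
            if not item.excluded:
                vals.append(item.neurite_curvature)
        else:
            vals.append(float(item))
    arr = np.asarray(vals, dtype=float)
    if arr.size == 0:
        raise ValueError(f"case {case_id!r}: no included neurites to bin")
    n_bins = int(np.floor(arr.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin on the right; our last edge sits
    # strictly above max(arr), so every bin behaves right-open
    counts, _ = np.histogram(arr, bins=edges)
    freqs = counts / arr.size
    return CurvatureHistogram(
        case_id=case_id, bin_edges=edges, relative_frequencies=freqs,
        tail_threshold=tail_threshold,
        tail_mass=float(np.mean(arr >= tail_threshold)))


# ---------------------------------------------------------------------------
# Full cohort analysis


@dataclass
class CohortReport:
    """Bundle of every table and test produced by the cohort analysis."""

    per_case: pd.DataFrame
    comparisons: list[GroupComparison]
    regressions: dict[str, RegressionResult]
    histograms: list[CurvatureHistogram]
    group_means: dict[str, dict[str, float]]
    shapiro: dict[str, tuple[float, float]]
    n_tests: int

    def summary_dict(self) -> dict:
        """JSON-serializable summary of all headline numbers."""
        out: dict = {"group_means": self.group_means, "n_tests": self.n_tests}
        out["comparisons"] = {
            c.parameter: {
                "mean_schizophrenia": c.mean_schizophrenia,
                "mean_control": c.mean_control,
                "t": c.t_statistic, "df": c.df, "p": c.p_value,
                "n_schizophrenia": c.n_schizophrenia, "n_control": c.n_control,
            } for c in self.comparisons}
        out["regressions"] = {
            key: {"predictor": r.predictor, "response": r.response,
                  "pearson_r": r.pearson_r, "p": r.p_value,
                  "slope": r.slope, "intercept": r.intercept, "n": r.n}
            for key, r in self.regressions.items()}
        out["shapiro_sd_curvature"] = {
            grp: {"W": w, "p": p} for grp, (w, p) in self.shapiro.items()}
        out["histograms"] = {
            h.case_id: {
                "bin_edges": h.bin_edges.tolist(),
                "relative_frequencies": h.relative_frequencies.tolist(),
                "tail_threshold": h.tail_threshold,
                "tail_mass": h.tail_mass,
            } for h in self.histograms}
        return out


def run_cohort_analysis(
    morphometry: pd.DataFrame,
    records: Sequence[CaseRecord],
    bin_width: float = 0.1,
    age_regression_group: Optional[str] = "control",
    score_regression_group: Optional[str] = None,
    case_of_dataset=dataset_to_case,
) -> CohortReport:
    """Run the full case-control analysis on a per-neurite table.

    Produces per-case summaries, Welch comparisons for mean curvature,
    curvature SD and radius, the age and symptom regressions, Shapiro-
    Wilk normality checks of the per-case curvature SDs, and per-case
    curvature histograms.  The age regression of curvature SD is fitted
    on controls by default (the aging trend from which disease cases
    deviate); the hallucination-score regression uses all cases by
    default.  Deterministic.

    Group mean curvature is reported under two conventions: the
    unweighted mean of per-case means (primary; matches the case-level
    unit of analysis) and the neurite-pooled mean, which weights cases
    by their neurite counts.
    """
    cases = aggregate_cases_from_frame(morphometry, case_of_dataset)
    recmap = _records_by_id(records)
    missing = sorted(c.case_id for c in cases if c.case_id not in recmap)
    if missing:
        raise ValueError(f"cases without cohort records: {missing}")

    per_case = pd.DataFrame([{
        "case_id": c.case_id,
        "group": recmap[c.case_id].group,
        "age": recmap[c.case_id].age,
        "hallucination_score": recmap[c.case_id].hallucination_score,
        "cpz_dose": recmap[c.case_id].cpz_dose,
        "n_neurites": c.n_neurites,
        "mean_curvature_um-1": c.mean_curvature,
        "sd_curvature_um-1": c.sd_curvature,
        "median_curvature_um-1": c.median_curvature,
        "max_curvature_um-1": c.max_curvature,
        "mean_radius_um": c.mean_radius,
        "total_length_um": c.total_length,
    } for c in cases]).sort_values("case_id", kind="stable").reset_index(drop=True)

    comparisons = [group_compare(cases, records, p)
                   for p in ("mean_curvature", "sd_curvature", "mean_radius")]

    regressions: dict[str, RegressionResult] = {}
    regressions["sd_curvature_vs_age"] = correlate(
        cases, records, "age", "sd_curvature", case_filter=age_regression_group)
    regressions["mean_curvature_vs_hallucination_score"] = correlate(
        cases, records, "mean_curvature", "hallucination_score",
        case_filter=score_regression_group)
    # dose check: only medicated cases carry a dose; reported descriptively
    try:
        regressions["mean_curvature_vs_cpz_dose"] = correlate(
            cases, records, "cpz_dose", "mean_curvature")
    except ValueError:
        pass  # too few dosed cases; omit rather than fail the whole report

    shapiro = {}
    for grp in ("schizophrenia", "control"):
        sds = [c.sd_curvature for c in cases if recmap[c.case_id].group == grp]
        if len(sds) >= 3 and np.ptp(sds) > 0:
            shapiro[grp] = normality_check(sds)

    histograms = [curvature_histogram(c.curvatures, bin_width=bin_width,
                                      case_id=c.case_id) for c in cases]

    by_group: dict[str, list[CaseMorphometry]] = {"schizophrenia": [], "control": []}
    for c in cases:
        by_group[recmap[c.case_id].group].append(c)
    group_means = {}
    for grp, gcases in by_group.items():
        pooled = np.concatenate([c.curvatures for c in gcases]) if gcases else np.empty(0)
        group_means[grp] = {
            "mean_curvature_case_mean": float(np.mean([c.mean_curvature for c in gcases])),
            "mean_curvature_neurite_pooled": float(pooled.mean()) if pooled.size else math.nan,
            "mean_radius_case_mean": float(np.mean([c.mean_radius for c in gcases])),
            "n_cases": len(gcases),
            "n_neurites": int(pooled.size),
        }

    n_tests = len(comparisons) + len(regressions) + len(shapiro)
    return CohortReport(per_case=per_case, comparisons=comparisons,
                        regressions=regressions, histograms=histograms,
                        group_means=group_means, shapiro=shapiro, n_tests=n_tests)


# ---------------------------------------------------------------------------
# Supplementary-style curvature workbooks


def read_curvature_workbook(path) -> pd.DataFrame:
    """Read a per-neurite curvature workbook into a long-format table.

    Accepts either layout commonly used for supplementary per-neurite
    data: (a) long format — one sheet with ``case_id`` and a curvature
    column (any column whose name contains "curvature"); or (b) one
    sheet per case, the sheet name being the case label and the first
    numeric column holding that case's per-neurite curvatures.  Returns
    a DataFrame with columns ``case_id`` and ``curvature_um-1``.
    """
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    frames = []
    first = next(iter(sheets.values()))
    lower = {c.lower(): c for c in first.columns if isinstance(c, str)}
    curv_col = next((orig for low, orig in lower.items() if "curvature" in low), None)
    if len(sheets) == 1 and "case_id" in lower and curv_col is not None:
        df = first.rename(columns={lower["case_id"]: "case_id",
                                   curv_col: "curvature_um-1"})
        frames.append(df[["case_id", "curvature_um-1"]])
    else:
        for name, df in sheets.items():
            num = df.select_dtypes("number")
            if num.shape[1] == 0:
                continue
            vals = num.iloc[:, 0].dropna()
            frames.append(pd.DataFrame({
                "case_id": str(name), "curvature_um-1": vals.to_numpy()}))
    if not frames:
        raise ValueError(f"{path}: no curvature data found in workbook")
    out = pd.concat(frames, ignore_index=True)
    out["case_id"] = out["case_id"].astype(str)
    out["curvature_um-1"] = out["curvature_um-1"].astype(float)
    return out


def aggregate_curvature_table(table: pd.DataFrame) -> list[CaseMorphometry]:
    """Aggregate a long (case_id, curvature_um-1) table per case.

    Used for curvature-only inputs such as supplementary workbooks;
    radius and length summaries are NaN since the table carries none.
    """
    out = []
    for case_id, sub in table.groupby("case_id", sort=True):
        curv = _case_values(sub["curvature_um-1"].to_numpy(dtype=float), str(case_id))
        out.append(CaseMorphometry(
            case_id=str(case_id), n_neurites=curv.size,
            mean_curvature=float(curv.mean()),
            sd_curvature=float(curv.std(ddof=1)),
            median_curvature=float(np.median(curv)),
            max_curvature=float(curv.max()),
            mean_radius=math.nan, total_length=math.nan,
            curvatures=curv))
    return out
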