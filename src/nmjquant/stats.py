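"""Group comparisons with the normality/variance-gated test-selection tree.

Two fiber-level samples are compared with Student's t test when both pass
a Shapiro-Wilk normality check and an F test finds equal variances; with
Welch's t test when only the variance condition fails; and with the
Mann-Whitney U test when either group is non-normal (alpha 0.05 for both
gatekeeper tests).  Summary tables report mean ± SEM per group with the
selected test and a p < 0.05 significance flag; no multiple-testing
correction is applied across table rows, which is stated in every emitted
header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "PercentChange",
    "build_summary_table",
    "choose_test",
    "compare_groups",
    "decision_tree_consistent",
    "mean_sem",
    "percent_change",
]

ALPHA = 0.05

#: significance marker per selected test (documented in emitted headers)
TEST_MARKERS = {"mann_whitney": "#", "student_t": "*", "welch_t": "+"}


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    test_name: str  # "student_t" | "welch_t" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    shapiro_p: tuple[float, float]
    f_test_p: float
    n: tuple[int, int]
    note: str = ""


@dataclass(frozen=True)
class PercentChange:
    """Signed percent change with its half-up integer rounding."""

    value: float
    rounded: int


def mean_sem(values: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and SEM (sample SD with n−1 denominator over √n).

    For a single value the SEM is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    m = float(np.mean(v))
    if v.size == 1:
        return m, float("nan")
    return m, float(np.std(v, ddof=1) / math.sqrt(v.size))


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of variance equality, larger variance on top."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        f, d1, d2 = va / vb, a.size - 1, b.size - 1
    else:
        f, d1, d2 = vb / va, b.size - 1, a.size - 1
    return float(min(2.0 * sps.f.sf(f, d1, d2), 1.0))


def choose_test(
    a: GroupSample, b: GroupSample, alpha: float = ALPHA
) -> tuple[str, dict[str, float]]:
    """Select the comparison test for two samples.

    Shapiro-Wilk on each group first: any p below ``alpha`` selects the
    Mann-Whitney U test.  Otherwise a two-sided F test on the variances:
    p below ``alpha`` selects Welch's t, else Student's t.  Groups too
    small for the normality test fall back to Mann-Whitney with a note.
    """
    diag: dict[str, float] = {}
    if a.n < 3 or b.n < 3:
        diag.update(shapiro_p_a=float("nan"), shapiro_p_b=float("nan"),
                    f_test_p=float("nan"))
        diag["note"] = "sample too small for normality testing"
        return "mann_whitney", diag
    sw_a = float(sps.shapiro(a.values).pvalue)
    sw_b = float(sps.shapiro(b.values).pvalue)
    diag.update(shapiro_p_a=sw_a, shapiro_p_b=sw_b)
    if sw_a < alpha or sw_b < alpha:
        diag["f_test_p"] = float("nan")
        return "mann_whitney", diag
    f_p = _f_test(a.values, b.values)
    diag["f_test_p"] = f_p
    if f_p < alpha:
        return "welch_t", diag
    return "student_t", diag


def compare_groups(a: GroupSample, b: GroupSample, alpha: float = ALPHA) -> TestResult:
    """Run the decision tree and the selected two-sided test on two samples."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 values")
    note = ""
    if np.ptp(a.values) == 0 and np.ptp(b.values) == 0:
        note = "degenerate-input: both samples constant"
    test, diag = choose_test(a, b, alpha)
    note = note or str(diag.get("note", ""))
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
    elif test == "welch_t":
        res = sps.ttest_ind(a.values, b.values, equal_var=False)
    else:
        res = sps.ttest_ind(a.values, b.values, equal_var=True)
    p = float(res.pvalue)
    if math.isnan(p):
        p, note = 1.0, note or "degenerate-input: undefined p-value"
    return TestResult(
        test_name=test,
        statistic=float(res.statistic),
        p_value=p,
        significant=bool(p < ALPHA),
        shapiro_p=(diag.get("shapiro_p_a", float("nan")),
                   diag.get("shapiro_p_b", float("nan"))),
        f_test_p=diag.get("f_test_p", float("nan")),
        n=(a.n, b.n),
        note=note,
    )


def decision_tree_consistent(tr: TestResult, alpha: float = ALPHA) -> bool:
    """Check that the recorded gatekeeper p-values imply the recorded test."""
    sw_a, sw_b = tr.shapiro_p
    if math.isnan(sw_a) or math.isnan(sw_b):
        return tr.test_name == "mann_whitney"
    if sw_a < alpha or sw_b < alpha:
        return tr.test_name == "mann_whitney"
    if tr.f_test_p < alpha:
        return tr.test_name == "welch_t"
    return tr.test_name == "student_t"


def percent_change(reference_mean: float, test_mean: float) -> PercentChange:
    """Signed percent change of ``test_mean`` relative to ``reference_mean``.

    The rounded field carries the half-up (half away from zero) integer
    percent alongside the unrounded value.
    """
    if reference_mean == 0:
        raise ValueError("percent change undefined for zero reference")
    value = 100.0 * (test_mean - reference_mean) / reference_mean
    rounded = int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return PercentChange(value=value, rounded=rounded)


#: measure -> (fiber-table column, restricted to GMEPP-exhibiting fibers?)
TABLE_MEASURES: dict[str, tuple[str, bool]] = {
    "RMP (mV)": ("rmp", False),
    "EPPs amplitude (mV)": ("mean_epp", False),
    "EPPs amplitude NOR (mV)": ("mean_epp_nor", False),
    "Quantal content NOR": ("quantal_content", False),
    "MEPPs amplitude (mV)": ("mean_mepp", False),
    "MEPPs rise-time (ms)": ("mepp_rise", False),
    "MEPPs decay-time (ms)": ("mepp_decay", False),
    "MEPPs frequency (s^-1)": ("mepp_freq", False),
    "GMEPPs frequency (s^-1)": ("gmepp_freq", True),
    "Fr(GMEPPs)/Fr(MEPPs)": ("gmepp_mepp_ratio", True),
}


def _measure_values(frame: pd.DataFrame, column: str, gmepp_only: bool) -> np.ndarray:
    sub = frame
    if gmepp_only and "has_gmepps" in frame:
        sub = frame[frame["has_gmepps"].astype(bool)]
    if column not in sub:
        return np.empty(0)
    vals = sub[column].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def build_summary_table(
    groups: dict[str, pd.DataFrame],
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Group summary: one row per measure with mean ± SEM and pairwise tests.

    Every non-reference group is compared against the first (reference)
    group with the decision-tree-selected test.  Measures restricted to
    GMEPP-exhibiting fibers (GMEPP frequency and the GMEPP/MEPP ratio) use
    only those fibers.  Rows with missing data carry NaN cells and no test.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    measures = measures or list(TABLE_MEASURES)
    labels = list(groups)
    ref = labels[0]
    rows = []
    for measure in measures:
        column, gmepp_only = TABLE_MEASURES[measure]
        row: dict[str, object] = {"measure": measure}
        samples: dict[str, np.ndarray] = {}
        for lab in labels:
            vals = _measure_values(groups[lab], column, gmepp_only)
            samples[lab] = vals
            if vals.size:
                m, s = mean_sem(vals)
            else:
                m, s = float("nan"), float("nan")
            row[f"{lab}_mean"] = m
            row[f"{lab}_sem"] = s
            row[f"{lab}_n"] = vals.size
        for lab in labels[1:]:
            if samples[ref].size >= 2 and samples[lab].size >= 2:
                tr = compare_groups(GroupSample(ref, samples[ref]),
                                    GroupSample(lab, samples[lab]))
                row[f"{lab}_test"] = tr.test_name
                row[f"{lab}_p"] = tr.p_value
                row[f"{lab}_significant"] = tr.significant
                row[f"{lab}_marker"] = (
                    TEST_MARKERS[tr.test_name] if tr.significant else ""
                )
            else:
                row[f"{lab}_test"] = ""
                row[f"{lab}_p"] = float("nan")
                row[f"{lab}_significant"] = False
                row[f"{lab}_marker"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def render_summary(table: pd.DataFrame) -> str:
    """Human-readable rendering of a summary table (mean ± SEM with markers).

    Values are mean ± SEM; significance at p < 0.05 against the reference
    (first) group is marked '#' (Mann-Whitney U), '*' (Student's t) or
    '+' (Welch's t).  No correction across rows is applied.
    """
    labels = [c[:-5] for c in table.columns if c.endswith("_mean")]
    lines = [
        "Values are mean +/- SEM; p < 0.05 vs the first group marked "
        "# (Mann-Whitney U), * (Student t), + (Welch t); "
        "no multiple-testing correction across rows.",
        "",
    ]
    for _, row in table.iterrows():
        cells = []
        for lab in labels:
            cell = f"{row[f'{lab}_mean']:.3g} ± {row[f'{lab}_sem']:.2g}"
            marker = row.get(f"{lab}_marker", "")
            if isinstance(marker, str) and marker:
                cell += marker
            cells.append(f"{lab}: {cell} (n={int(row[f'{lab}_n'])})")
        lines.append(f"{row['measure']:<26} " + " | ".join(cells))
    return "\n".join(lines) + "\n"
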