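"""Per-study two-group statistics: location tests and standardized mean
differences.

The location test follows the classical gated procedure: an F-test of the
variance ratio decides between the pooled-variance Student's t-test (variances
homogeneous) and the Mann-Whitney U test (variances unequal).  Effect sizes
are standardized mean differences (Cohen's d, or Hedges' g after the
small-sample correction J = 1 - 3/(4N - 9)), with the usual large-sample
sampling variance v = (n1+n0)/(n1*n0) + y^2 / (2(n1+n0)).

Sign convention throughout: case minus control, so upregulation in cases
gives a positive SMD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from metaexpr.expression_io import ArmSummary, ExpressionCohort

ESTIMATORS = ("cohen_d", "hedges_g")

#: combined sample size at or below which the Mann-Whitney branch uses the
#: exact permutation distribution instead of the normal approximation
MW_EXACT_MAX_N = 12


class DegenerateStudyError(ValueError):
    """Raised when a study's pooled SD is zero (no within-group spread)."""


@dataclass(frozen=True)
class TwoGroupTestResult:
    statistic: float
    p: float
    test_used: str  # student_t | mann_whitney
    variance_test_p: float


@dataclass(frozen=True)
class StudyEffect:
    """One study's standardized mean difference and its sampling variance."""

    study_id: str
    y: float
    v: float
    n_case: int
    n_ctrl: int
    estimator: str = "hedges_g"

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"study {self.study_id}: variance must be > 0")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.v))


def two_group_test(
    case_values, ctrl_values, alpha_var: float = 0.05
) -> TwoGroupTestResult:
    """Variance-gated two-sided test of a location difference.

    A two-sided F-test of the variance ratio at level ``alpha_var`` gates
    the choice: not rejected -> pooled-variance Student's t; rejected ->
    Mann-Whitney U (exact permutation null for combined n <= 12, otherwise
    the tie-corrected normal approximation with continuity correction).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")

    s2x = float(np.var(x, ddof=1))
    s2y = float(np.var(y, ddof=1))
    if s2x == 0.0 and s2y == 0.0:
        # no within-group spread: identical constants -> no evidence either way
        if float(np.mean(x)) == float(np.mean(y)):
            return TwoGroupTestResult(0.0, 1.0, "student_t", 1.0)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return TwoGroupTestResult(float(res.statistic), float(res.pvalue), "mann_whitney", 0.0)

    if s2x == 0.0 or s2y == 0.0:
        var_p = 0.0  # infinite variance ratio
    else:
        f = s2x / s2y
        cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
        var_p = float(2 * min(cdf, 1 - cdf))

    if var_p < alpha_var:
        n = len(x) + len(y)
        method = "exact" if n <= MW_EXACT_MAX_N and not _has_ties(x, y) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TwoGroupTestResult(
            float(res.statistic), float(res.pvalue), "mann_whitney", var_p
        )
    t = stats.ttest_ind(x, y, equal_var=True)
    return TwoGroupTestResult(float(t.statistic), float(t.pvalue), "student_t", var_p)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def hedges_j(n_total: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4N - 9)."""
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def smd_from_summaries(
    case: ArmSummary,
    ctrl: ArmSummary,
    estimator: str = "hedges_g",
    study_id: str = "",
) -> StudyEffect:
    """Standardized mean difference from per-arm (n, mean, SD) summaries.

    d = (mean_case - mean_ctrl) / s_p with the pooled SD
    s_p^2 = ((n1-1) s1^2 + (n0-1) s0^2) / (n1+n0-2); Hedges' g = J * d.
    The sampling variance v = N/(n1*n0) + y^2/(2N) is evaluated at the
    chosen estimator's value.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    n1, n0 = case.n, ctrl.n
    n = n1 + n0
    sp2 = ((n1 - 1) * case.sd**2 + (n0 - 1) * ctrl.sd**2) / (n - 2)
    if sp2 <= 0:
        raise DegenerateStudyError(
            f"degenerate_study: {study_id or '<unnamed>'} has pooled SD 0"
        )
    d = (case.mean - ctrl.mean) / np.sqrt(sp2)
    y = d * hedges_j(n) if estimator == "hedges_g" else d
    v = n / (n1 * n0) + y**2 / (2.0 * n)
    return StudyEffect(
        study_id=study_id, y=float(y), v=float(v), n_case=n1, n_ctrl=n0,
        estimator=estimator,
    )


def smd_from_cohort(
    cohort: ExpressionCohort, gene: str, estimator: str = "hedges_g"
) -> StudyEffect:
    """SMD of one gene in one cohort, via per-arm summaries of its row."""
    case = cohort.arm_values(gene, "case")
    ctrl = cohort.arm_values(gene, "control")
    return smd_from_summaries(
        ArmSummary(len(case), float(np.mean(case)), float(np.std(case, ddof=1))),
        ArmSummary(len(ctrl), float(np.mean(ctrl)), float(np.std(ctrl, ddof=1))),
        estimator=estimator,
        study_id=cohort.cohort_id,
    )


def effects_from_literature(studies, estimator: str = "hedges_g") -> list[StudyEffect]:
    """StudyEffects for a list of literature summary studies."""
    return [
        smd_from_summaries(s.case, s.control, estimator=estimator, study_id=s.study_id)
        for s in studies
    ]
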