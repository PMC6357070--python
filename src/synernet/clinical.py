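"""Clinical group comparison: relative change, ANCOVA LS means, ANOVA, chi-square.

The treatment effect on each outcome is expressed as the relative change
(percent) between baseline and the week-4 follow-up within each subject, and
arms are compared by one-way ANCOVA with the subject's baseline value as the
covariate, reporting adjusted least-squares means evaluated at the grand
mean of the baseline. Baseline categorical characteristics are compared by
Pearson chi-square without continuity correction; continuous ones by
classical one-way ANOVA. Skewed variables may be natural-log transformed
before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .datatypes import ClinicalTable, ValidationError


@dataclass
class AncovaResult:
    """Adjusted LS means (percent relative change) per arm and overall group test."""

    ls_means: dict[str, float]
    se: dict[str, float]
    p_group: float
    df_resid: int
    outcome: str = ""


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p: float


def relative_change(baseline: float, week4: float) -> float:
    """Percent change from baseline: 100 x (week4 - baseline) / baseline."""
    b = np.asarray(baseline, dtype=float)
    if np.any(b == 0):
        raise ValidationError("relative change undefined at baseline = 0")
    return 100.0 * (np.asarray(week4, dtype=float) - b) / b


def log_transform_if_skewed(
    values: np.ndarray | pd.Series, skew_threshold: float = 1.0
) -> tuple[np.ndarray, bool]:
    """Natural-log transform a sample iff its |skewness| exceeds the threshold.

    Returns the (possibly transformed) values and a flag recording whether
    the transform was applied. Bias-corrected sample skewness is used.
    """
    arr = np.asarray(values, dtype=float)
    skew = sps.skew(arr, bias=False)
    if abs(skew) <= skew_threshold:
        return arr, False
    bad = arr[arr <= 0]
    if bad.size:
        raise ValidationError(
            f"cannot log-transform skewed sample containing non-positive value {bad[0]!r}"
        )
    return np.log(arr), True


def one_way_ancova(table: ClinicalTable, outcome: str) -> AncovaResult:
    """One-way ANCOVA of percent relative change with baseline as covariate.

    Fits ``relative_change ~ arm + baseline`` by ordinary least squares and
    evaluates the adjusted least-squares mean of each arm at the grand mean
    of the baseline covariate. The overall group p-value is the partial F
    test of the arm effects.
    """
    sub = table.outcome_frame(outcome)
    arms = sorted(sub["arm"].unique())
    if len(arms) < 2:
        raise ValidationError("ANCOVA needs at least 2 arms")
    if (sub.groupby("arm").size() < 2).any():
        raise ValidationError("every arm needs at least 2 subjects")
    rc = relative_change(sub["baseline"].to_numpy(), sub["week4"].to_numpy())
    baseline = sub["baseline"].to_numpy(dtype=float)

    arm_dummies = pd.get_dummies(sub["arm"], dtype=float)[arms]
    X_full = np.column_stack([np.ones(len(sub)), arm_dummies.to_numpy()[:, 1:], baseline])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValidationError("singular ANCOVA design (collinear arm/baseline structure)")

    model = sm.OLS(rc, X_full).fit()
    grand = baseline.mean()
    ls_means: dict[str, float] = {}
    se: dict[str, float] = {}
    for i, arm in enumerate(arms):
        x = np.zeros(X_full.shape[1])
        x[0] = 1.0
        if i > 0:
            x[i] = 1.0
        x[-1] = grand
        ls_means[arm] = float(x @ model.params)
        se[arm] = float(np.sqrt(x @ model.cov_params() @ x))

    # partial F test: arm columns jointly zero
    X_red = np.column_stack([np.ones(len(sub)), baseline])
    reduced = sm.OLS(rc, X_red).fit()
    df_num = len(arms) - 1
    df_den = int(model.df_resid)
    f = ((reduced.ssr - model.ssr) / df_num) / (model.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return AncovaResult(ls_means, se, p, df_den, outcome)


def one_way_anova(groups: list[np.ndarray]) -> float:
    """Classical one-way ANOVA F-test p-value across >=2 groups."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValidationError("every group needs at least 2 values")
    if all(np.var(a) == 0 for a in arrs):
        means = [a.mean() for a in arrs]
        if np.ptp(means) == 0:
            raise ValidationError("degenerate: zero variance everywhere with equal means")
    return float(sps.f_oneway(*arrs).pvalue)


def chi_square_independence(counts: np.ndarray | pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(float(res.statistic), int(res.dof), float(res.pvalue))


def clinical_results_table(
    table: ClinicalTable, skew_threshold: float = 1.0
) -> pd.DataFrame:
    """Run the ANCOVA over every outcome; long results frame for export.

    Columns: outcome, arm, ls_mean, se, p_group, df_resid.
    """
    rows = []
    for outcome in table.outcomes:
        res = one_way_ancova(table, outcome)
        for arm in sorted(res.ls_means):
            rows.append(
                (outcome, arm, res.ls_means[arm], res.se[arm], res.p_group, res.df_resid)
            )
    return pd.DataFrame(
        rows, columns=["outcome", "arm", "ls_mean", "se", "p_group", "df_resid"]
    )
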