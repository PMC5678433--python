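"""Cohort statistics: matching, ANCOVA, regression and exact tests.

The statistical layer of the pipeline mirrors a standard neuroimaging
case-control design: controls are matched to cases by minimising total
Euclidean distance in (gestational age, postmenstrual age) space; group
differences in volumes and gyrification are tested with per-outcome
ANCOVA (ordinary least squares with a group indicator and PMA covariate);
continuous demographics use the Mann-Whitney U test, categorical ones
Fisher's exact test; associations with oxygen delivery use simple linear
regression; repeated NIRS readings are summarised by Pearson correlation.
Regional (four-lobe) families use a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "AncovaResult",
    "RegressionResult",
    "MannWhitneyResult",
    "MatchingResult",
    "match_controls",
    "ancova_group_effect",
    "linreg",
    "bonferroni_threshold",
    "mann_whitney",
    "fisher_exact",
    "repeatability",
    "apply_exclusions",
    "count_percent",
]


@dataclass
class AncovaResult:
    outcome: str
    group_effect: float  # CHD minus control, in outcome units
    group_p: float
    ci_low: float
    ci_high: float
    covariates: tuple[str, ...]
    n_case: int
    n_control: int
    n_dropped: int = 0


@dataclass
class RegressionResult:
    x: str
    y: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class MannWhitneyResult:
    p_value: float
    statistic: float
    method: str  # "exact" or "asymptotic"
    all_tied: bool = False


@dataclass
class MatchingResult:
    pairs: pd.DataFrame  # case_id, control_id, distance
    total_distance: float


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame) -> MatchingResult:
    """One-to-one case-control assignment minimising total Euclidean
    distance in (GA, PMA) space.

    Solved as a linear assignment problem (globally optimal, not greedy);
    rows are ordered by subject_id before solving so ties break
    deterministically.
    """
    for df, name in ((cases, "cases"), (pool, "pool")):
        for col in ("subject_id", "ga_wk", "pma_wk"):
            if col not in df.columns:
                raise ValueError(f"{name} table lacks column {col!r}")
        if df[["ga_wk", "pma_wk"]].isna().any().any():
            raise ValueError(f"{name} table has missing GA/PMA values")
    if len(pool) < len(cases):
        raise ValueError(
            f"control pool ({len(pool)}) smaller than the case list ({len(cases)})"
        )
    cases = cases.sort_values("subject_id").reset_index(drop=True)
    pool = pool.sort_values("subject_id").reset_index(drop=True)
    ca = cases[["ga_wk", "pma_wk"]].to_numpy(float)
    po = pool[["ga_wk", "pma_wk"]].to_numpy(float)
    cost = np.linalg.norm(ca[:, None, :] - po[None, :, :], axis=2)
    rows, cols = optimize.linear_sum_assignment(cost)
    pairs = pd.DataFrame(
        {
            "case_id": cases.loc[rows, "subject_id"].to_numpy(),
            "control_id": pool.loc[cols, "subject_id"].to_numpy(),
            "distance": cost[rows, cols],
        }
    )
    return MatchingResult(pairs=pairs, total_distance=float(cost[rows, cols].sum()))


def ancova_group_effect(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("pma_wk",),
    extra_covariates: tuple[str, ...] = (),
) -> AncovaResult:
    """OLS model ``outcome ~ group + covariates`` with the group coded
    control=0, CHD=1, so the effect reads CHD minus control.

    Rows with any missing value among the model columns are dropped
    (listwise deletion); the dropped count is reported, never silent.
    """
    covs = tuple(covariates) + tuple(extra_covariates)
    cols = [outcome, "group", *covs]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns {missing_cols}")
    sub = table[cols].dropna()
    n_dropped = len(table) - len(sub)
    groups = set(sub["group"])
    if not {"control", "CHD"} <= groups:
        raise ValueError("both 'control' and 'CHD' groups are required")
    n_case = int((sub["group"] == "CHD").sum())
    n_control = int((sub["group"] == "control").sum())
    if min(n_case, n_control) < 3:
        raise ValueError("need >= 3 subjects per group with complete data")

    y = sub[outcome].to_numpy(float)
    X = np.column_stack(
        [(sub["group"] == "CHD").to_numpy(float)]
        + [sub[c].to_numpy(float) for c in covs]
    )
    X = sm.add_constant(X, prepend=True)
    names = ["const", "group_chd", *covs]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design matrix; check collinearity among {names}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    effect = float(fit.params[1])
    p = float(fit.pvalues[1])
    # degenerate null: outcome fitted exactly with a zero group coefficient
    # (e.g. constant outcome) — the t test is 0/0 noise, report p = 1
    scale = max(1.0, float(np.abs(y).max()))
    if abs(effect) < 1e-10 * scale and np.sqrt(fit.ssr / max(fit.df_resid, 1)) < 1e-10 * scale:
        effect, p = 0.0, 1.0
    return AncovaResult(
        outcome=outcome,
        group_effect=effect,
        group_p=p,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        covariates=covs,
        n_case=n_case,
        n_control=n_control,
        n_dropped=n_dropped,
    )


def linreg(table: pd.DataFrame, x: str, y: str) -> RegressionResult:
    """Simple OLS of ``y`` on ``x`` over complete pairs: slope, intercept,
    R^2 (squared Pearson correlation) and the two-sided slope p-value."""
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete (x, y) pairs")
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError(f"zero variance in {x!r}")
    res = stats.linregress(xv, yv)
    return RegressionResult(
        x=x,
        y=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(sub),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m (e.g. 0.05 over 4 lobes -> 0.0125)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


_EXACT_MAX_PRODUCT = 400


def mann_whitney(xs, ys) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the sample-size product is <= 400 and
    there are no cross-sample ties; otherwise the normal approximation
    with tie correction.  The branch taken is reported in the result.
    All values tied across both samples yields p = 1 with a flag.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([xs, ys])
    if np.ptp(combined) == 0:
        return MannWhitneyResult(
            p_value=1.0, statistic=xs.size * ys.size / 2.0, method="degenerate", all_tied=True
        )
    has_ties = len(np.unique(combined)) < combined.size
    use_exact = (xs.size * ys.size <= _EXACT_MAX_PRODUCT) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    return MannWhitneyResult(
        p_value=float(min(res.pvalue, 1.0)), statistic=float(res.statistic), method=method
    )


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the sum of hypergeometric probabilities no larger than the observed
    table's."""
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("table margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def repeatability(first, second) -> RegressionResult:
    """Agreement of paired repeated measurements: Pearson correlation, its
    square, and the regression of second on first."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape:
        raise ValueError("readings must be paired (equal length)")
    if first.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(first) == 0 or np.ptp(second) == 0:
        raise ValueError("zero variance in one of the readings")
    res = stats.linregress(first, second)
    return RegressionResult(
        x="first_reading",
        y="second_reading",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=first.size,
    )


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cohort intake filter: exclude subjects with arterial ischaemic stroke
    on MRI and subjects whose pregnancy cannot be dated (missing GA).

    Returns the retained table and an accounting dict
    (recruited / excluded_stroke / excluded_undatable / retained).
    """
    recruited = len(table)
    stroke = (
        table["arterial_stroke"].fillna(False).astype(bool)
        if "arterial_stroke" in table.columns
        else pd.Series(False, index=table.index)
    )
    undatable = (
        table["ga_wk"].isna()
        if "ga_wk" in table.columns
        else pd.Series(False, index=table.index)
    )
    undatable = undatable & ~stroke  # count each exclusion once, stroke first
    kept = table[~stroke & ~undatable].copy()
    return kept, {
        "recruited": recruited,
        "excluded_stroke": int(stroke.sum()),
        "excluded_undatable": int(undatable.sum()),
        "retained": len(kept),
    }


def count_percent(k: int, n: int) -> tuple[int, int]:
    """(count, percent rounded to the nearest integer), e.g. 5 of 14 -> 36%."""
    if n <= 0 or k < 0 or k > n:
        raise ValueError("need 0 <= k <= n with n > 0")
    return k, int(math.floor(100.0 * k / n + 0.5))
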