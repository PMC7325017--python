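"""Cohort-level statistics for thickness-change tables.

Implements the analysis battery applied to the per-patient table:
normality-gated location tests (Student/Welch t or exact Mann-Whitney /
Wilcoxon), one- and two-sample t tests computable directly from printed
summary statistics (mean, SD, n), Spearman correlation matrices,
collinearity diagnostics (VIF), standardized multiple linear regression
with optional backward elimination, two-way mixed absolute-agreement ICC,
and a noncentral-t power/sample-size solver.

Rank tests use full enumeration (all group labelings, or all sign
assignments for the paired case) for combined n <= 12 and a tie-corrected
normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RegressionResult",
    "one_sample_test_summary",
    "two_sample_test_summary",
    "mann_whitney_test",
    "wilcoxon_signed_test",
    "rank_tests",
    "test_router",
    "spearman_matrix",
    "vif",
    "ols_standardized",
    "icc",
    "sample_size_two_groups",
]

EXACT_ENUMERATION_LIMIT = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    """Standardized OLS fit: beta per predictor, p-values, adjusted R^2."""

    beta: Dict[str, float]
    p_values: Dict[str, float]
    adjusted_r2: float
    r2: float
    included: List[str]
    response: str


# --------------------------------------------------------------------------
# t tests from summary statistics
# --------------------------------------------------------------------------


def one_sample_test_summary(mean, sd, n, mu0=0.0) -> TestResult:
    """One-sample t test against ``mu0`` from summary statistics."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    se = sd / math.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t, float(p), "one-sample t", df=df)


def two_sample_test_summary(
    m1, s1, n1, m2, s2, n2, variant: str = "pooled"
) -> TestResult:
    """Independent two-sample t from summary statistics.

    ``variant='pooled'`` is the classical equal-variance Student test;
    ``'welch'`` uses the Welch-Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be > 0")
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        label = "two-sample t (pooled)"
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        label = "two-sample t (Welch)"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t, float(p), label, df=df)


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact by enumeration of all C(n_x + n_y, n_x) group labelings (average
    ranks, so ties are handled) when the combined sample size is at most
    12; otherwise a tie-corrected normal approximation with continuity
    correction. Two-sided p is twice the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    nx, ny = len(x), len(y)
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_obs = _u_statistic(ranks[:nx], nx)

    if n <= EXACT_ENUMERATION_LIMIT:
        us = np.array(
            [
                ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
                for idx in itertools.combinations(range(n), nx)
            ]
        )
        eps = 1e-9
        p_lo = np.mean(us <= u_obs + eps)
        p_hi = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return TestResult(u_obs, float(p), "Mann-Whitney U (exact)", df=None)

    mu = nx * ny / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(u_obs, 1.0, "Mann-Whitney U (normal)", flags=["all tied"])
    z = (u_obs - mu - math.copysign(0.5, u_obs - mu)) / math.sqrt(sigma2)
    if u_obs == mu:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u_obs, float(min(p, 1.0)), "Mann-Whitney U (normal)")


def wilcoxon_signed_test(
    x: Sequence[float], y: Optional[Sequence[float]] = None, mu0: float = 0.0
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired or one-sample data.

    Zero differences are dropped (the classical Wilcoxon treatment). Exact
    by enumerating all 2^m sign assignments for m <= 12 non-zero
    differences, else normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - mu0 if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return TestResult(0.0, 1.0, "Wilcoxon signed-rank", flags=["all zero"])
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if m <= EXACT_ENUMERATION_LIMIT:
        ws = np.array(
            [
                np.sum(ranks[np.array(signs, dtype=bool)])
                for signs in itertools.product([0, 1], repeat=m)
            ]
        )
        eps = 1e-9
        p = min(
            1.0,
            2.0 * min(np.mean(ws <= w_obs + eps), np.mean(ws >= w_obs - eps)),
        )
        return TestResult(w_obs, float(p), "Wilcoxon signed-rank (exact)")
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w_obs - mu - math.copysign(0.5, w_obs - mu)) / math.sqrt(sigma2)
    if w_obs == mu:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w_obs, float(min(p, 1.0)), "Wilcoxon signed-rank (normal)")


def rank_tests(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    paired: bool = False,
) -> TestResult:
    """Distribution-free location test: Mann-Whitney, or Wilcoxon if paired
    (or one-sample when ``y`` is omitted)."""
    if y is None or paired:
        return wilcoxon_signed_test(x, y)
    return mann_whitney_test(x, y)


# --------------------------------------------------------------------------
# normality-gated dispatch
# --------------------------------------------------------------------------


def test_router(
    values: Sequence[float],
    grouping: Optional[Sequence] = None,
    alpha_norm: float = 0.05,
    mu0: float = 0.0,
    t_variant: str = "pooled",
) -> TestResult:
    """Shapiro-Wilk-gated dispatch between t and rank tests.

    One sample (``grouping=None``): one-sample t against ``mu0`` when
    normality is not rejected at ``alpha_norm``, else Wilcoxon signed-rank.
    Two groups: t test (pooled or Welch) when neither group rejects
    normality, else Mann-Whitney. Groups too small for Shapiro-Wilk (n < 3)
    fall back to the rank path with a flag.
    """
    values = np.asarray(values, dtype=float)
    if grouping is None:
        groups = [values]
    else:
        grouping = np.asarray(grouping)
        labels = pd.unique(grouping)
        if len(labels) != 2:
            raise ValueError("grouping must define exactly 2 groups")
        groups = [values[grouping == lab] for lab in labels]

    flags: List[str] = []
    normal = True
    for g in groups:
        if len(g) < 3:
            flags.append("group too small for normality check")
            normal = False
            break
        if np.ptp(g) == 0:
            flags.append("constant group")
            normal = False
            break
        if sps.shapiro(g).pvalue < alpha_norm:
            normal = False

    if grouping is None:
        (g,) = groups
        if normal:
            res = one_sample_test_summary(g.mean(), g.std(ddof=1), len(g), mu0)
        else:
            res = wilcoxon_signed_test(g, mu0=mu0)
    else:
        a, b = groups
        if normal:
            res = two_sample_test_summary(
                a.mean(), a.std(ddof=1), len(a),
                b.mean(), b.std(ddof=1), len(b),
                variant=t_variant,
            )
        else:
            res = mann_whitney_test(a, b)
    res.flags.extend(flags)
    return res


# --------------------------------------------------------------------------
# correlation, collinearity, regression
# --------------------------------------------------------------------------


def spearman_matrix(table: pd.DataFrame, columns: Sequence[str]):
    """Pairwise Spearman rho (average-rank ties) with two-sided p-values.

    Returns ``(rho, p, flags)`` DataFrames/list; constant columns yield NaN
    entries and are flagged.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 rows for correlation")
    cols = list(columns)
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    flags: List[str] = []
    data = table[cols].to_numpy(dtype=float)
    constant = [c for i, c in enumerate(cols) if np.ptp(data[:, i]) == 0]
    flags.extend(f"constant column: {c}" for c in constant)
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in constant or cols[j] in constant:
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, p = sps.spearmanr(data[:, i], data[:, j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pmat, index=cols, columns=cols),
        flags,
    )


def vif(table: pd.DataFrame, predictors: Sequence[str]) -> Dict[str, float]:
    """Variance inflation factors: 1 / (1 - R^2) of each predictor on the
    rest (with intercept). Exact collinearity yields ``inf``."""
    preds = list(predictors)
    if len(table) < len(preds) + 2:
        raise ValueError("need at least p + 2 rows for VIF")
    import statsmodels.api as sm

    out: Dict[str, float] = {}
    for j, col in enumerate(preds):
        others = [c for c in preds if c != col]
        if not others:
            out[col] = 1.0
            continue
        X = sm.add_constant(table[others].to_numpy(dtype=float))
        fit = sm.OLS(table[col].to_numpy(dtype=float), X).fit()
        r2 = min(fit.rsquared, 1.0)
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (a - a.mean()) / sd


def ols_standardized(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    backward_alpha: Optional[float] = None,
) -> RegressionResult:
    """OLS on z-scored response and predictors (standardized beta).

    Dummy predictors are z-scored like any other column, matching the
    convention of standardized coefficients in common statistics packages.
    With ``backward_alpha`` set, predictors are eliminated one at a time
    (largest p first) until all remaining p-values fall below the
    threshold; the fit of the surviving subset is reported.
    """
    import statsmodels.api as sm

    preds = list(predictors)
    if len(table) <= len(preds) + 1:
        raise ValueError("need more rows than predictors + 1")
    y = _zscore(table[response].to_numpy(dtype=float))

    def fit_subset(cols: List[str]):
        X = np.column_stack([_zscore(table[c].to_numpy(dtype=float)) for c in cols])
        rank = np.linalg.matrix_rank(np.corrcoef(X.T)) if len(cols) > 1 else 1
        if rank < len(cols):
            raise ValueError(f"singular design among predictors {cols}")
        model = sm.OLS(y, sm.add_constant(X)).fit()
        beta = dict(zip(cols, model.params[1:]))
        pvals = dict(zip(cols, model.pvalues[1:]))
        return model, beta, pvals

    current = preds
    model, beta, pvals = fit_subset(current)
    if backward_alpha is not None:
        while len(current) > 1 and max(pvals.values()) > backward_alpha:
            worst = max(pvals, key=pvals.get)
            current = [c for c in current if c != worst]
            model, beta, pvals = fit_subset(current)
        if len(current) == 1 and max(pvals.values()) > backward_alpha:
            current, beta, pvals = [], {}, {}
    if current:
        adj_r2, r2 = float(model.rsquared_adj), float(model.rsquared)
    else:
        adj_r2 = r2 = 0.0
    return RegressionResult(
        beta=beta,
        p_values=pvals,
        adjusted_r2=adj_r2,
        r2=r2,
        included=current,
        response=response,
    )


# --------------------------------------------------------------------------
# reliability and power
# --------------------------------------------------------------------------


def icc(measurements, form: str = "A-1") -> TestResult:
    """Two-way mixed, absolute-agreement, single-measure ICC — ICC(A,1).

    ``measurements`` is an (n items x k raters) array. Computed from the
    two-way ANOVA mean squares (rows, columns, error); a constant table is
    flagged with NaN.
    """
    if form != "A-1":
        raise ValueError("only the two-way absolute-agreement single-measure "
                         "form (A-1) is implemented")
    M = np.asarray(measurements, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 items and >= 2 raters")
    n, k = M.shape
    grand = M.mean()
    if np.ptp(M) == 0:
        return TestResult(float("nan"), float("nan"), "ICC(A,1)",
                          flags=["constant measurements"])
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # F test of the row effect, the customary significance check
    f = msr / mse if mse > 0 else float("inf")
    p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1))) if np.isfinite(f) else 0.0
    return TestResult(float(val), p, "ICC(A,1)")


def two_sample_t_power(n: int, effect_d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t at n per group (noncentral t)."""
    df = 2 * n - 2
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    nc = effect_d * math.sqrt(n / 2.0)
    return float(1.0 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_groups(
    effect_d: float, power: float = 0.80, alpha: float = 0.05, max_n: int = 100000
) -> int:
    """Smallest n per group so the two-sample t reaches the target power."""
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect size must be > 0")
    for n in range(2, max_n + 1):
        if two_sample_t_power(n, effect_d, alpha) >= power:
            return n
    raise ValueError(f"required n exceeds max_n = {max_n}")
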