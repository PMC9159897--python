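"""Predictor-association statistics for the CHANGE/NO CHANGE outcome.

Covers the analysis battery applied once each patient has been dichotomised
by the control-chart rules: Pearson chi-square with Cramér's V, Fisher's
exact test, odds ratios with Woolf confidence intervals, one-way ANOVA with
eta-squared, Pearson-correlation screening, a linear-probability OLS
regression on the 0/1 outcome, and the linear-by-linear trend statistic for
ordered categories.

Effect-size interpretation follows the conventional bands: Cramér's V weak
<= 0.2, moderate 0.2-0.6, strong >= 0.6; eta-squared small ~0.01, medium
~0.06, large >= 0.14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tables import ContingencyTable, DegenerateTableError

__all__ = [
    "AssociationResult",
    "AnovaResult",
    "RegressionResult",
    "OddsRatioResult",
    "pearson_chi_square",
    "fisher_exact_2x2",
    "cramers_v",
    "odds_ratio_2x2",
    "one_way_anova",
    "pearson_correlation",
    "ols_regression",
    "linear_by_linear",
    "analyze_2x2",
    "cramers_v_band",
    "eta_squared_band",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


def _as_table(table: ContingencyTable | np.ndarray | Sequence) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def cramers_v_band(v: float) -> str:
    """Interpretation band for Cramér's V (boundary 0.2 counts as weak)."""
    if v <= 0.2:
        return "weak"
    if v < 0.6:
        return "moderate"
    return "strong"


def eta_squared_band(eta2: float) -> str:
    if eta2 >= 0.14:
        return "large"
    if eta2 >= 0.06:
        return "medium"
    if eta2 >= 0.01:
        return "small"
    return "negligible"


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio for a 2x2 table with a Woolf (log-scale) 95% CI.

    The orientation follows the trial's reporting convention: with
    treatment on the rows (APT first) and outcome on the columns (CHANGE
    first), ``odds_ratio`` is the odds of NO CHANGE under APT over the odds
    of NO CHANGE under ABAT; ``reciprocal`` is the headline "times higher"
    figure for CHANGE under APT.
    """

    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    log_se: float | None
    ci_available: bool = True
    continuity_corrected: bool = False

    @property
    def reciprocal(self) -> float:
        return 1.0 / self.odds_ratio


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square statistic bundle for one contingency table."""

    chi_square: float
    df: int
    p_value: float
    cramers_v: float
    n: int
    fisher_p: float | None = None
    odds_ratio: OddsRatioResult | None = None

    @property
    def effect_band(self) -> str:
        return cramers_v_band(self.cramers_v)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float

    @property
    def effect_band(self) -> str:
        return eta_squared_band(self.eta_squared)


@dataclass(frozen=True)
class RegressionResult:
    params: np.ndarray  # intercept first
    param_names: tuple[str, ...]
    pvalues: np.ndarray
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    f_pvalue: float


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns ``(statistic, df, p)``.  A zero row or column margin raises
    :class:`~rehabspc.tables.DegenerateTableError`.
    """
    t = _as_table(table)
    t.require_nondegenerate()
    chi2, p, df, _ = stats.chi2_contingency(t.counts, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Two-sidedness by the probability-mass method: the sum of
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher exact test needs a 2x2 table, got {t.shape}")
    return float(stats.fisher_exact(t.counts, alternative="two-sided").pvalue)


def cramers_v(chi_square: float, n: int, r: int, c: int) -> float:
    """Cramér's V: ``sqrt(chi2 / (N * min(r-1, c-1)))``."""
    if n <= 0:
        raise ValueError("N must be positive")
    k = min(r - 1, c - 1)
    if k < 1:
        raise ValueError("need at least 2 rows and 2 columns")
    return math.sqrt(chi_square / (n * k))


def odds_ratio_2x2(
    table,
    continuity_correction: bool = False,
) -> OddsRatioResult:
    """Sample odds ratio of a 2x2 table with the Woolf 95% CI.

    With counts ``[[a, b], [c, d]]`` the ratio is ``(b/a) / (d/c)`` — the
    odds of the second column's outcome in row 1 over row 2, matching the
    reporting orientation of the reference tables (NO CHANGE odds, APT over
    ABAT).  The CI is ``exp(log OR +/- 1.959964 * sqrt(1/a+1/b+1/c+1/d))``.
    With a zero cell the CI (and OR) are unavailable unless
    ``continuity_correction`` adds 0.5 to every cell (Haldane-Anscombe).
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"odds ratio needs a 2x2 table, got {t.shape}")
    cells = t.counts.astype(float)
    corrected = False
    if np.any(cells == 0):
        if not continuity_correction:
            a, b, c, d = cells.ravel()
            with np.errstate(divide="ignore", invalid="ignore"):
                orr = (b * c) / (a * d) if a * d > 0 else math.inf
            return OddsRatioResult(
                odds_ratio=float(orr),
                ci_low=None,
                ci_high=None,
                log_se=None,
                ci_available=False,
            )
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells.ravel()
    orr = (b / a) / (d / c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - Z_95 * log_se)
    hi = math.exp(math.log(orr) + Z_95 * log_se)
    return OddsRatioResult(
        odds_ratio=float(orr),
        ci_low=float(lo),
        ci_high=float(hi),
        log_se=float(log_se),
        ci_available=True,
        continuity_corrected=corrected,
    )


def analyze_2x2(table, continuity_correction: bool = False) -> AssociationResult:
    """Full statistic bundle for a 2x2 table: chi-square, Fisher, V, OR."""
    t = _as_table(table)
    chi2, df, p = pearson_chi_square(t)
    r, c = t.shape
    v = cramers_v(chi2, t.n, r, c)
    fisher_p = fisher_exact_2x2(t) if t.shape == (2, 2) else None
    orr = odds_ratio_2x2(t, continuity_correction) if t.shape == (2, 2) else None
    return AssociationResult(
        chi_square=chi2,
        df=df,
        p_value=p,
        cramers_v=v,
        n=t.n,
        fisher_p=fisher_p,
        odds_ratio=orr,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with the eta-squared effect size.

    ``eta_squared = SS_between / SS_total``.  When every observation in
    every group is identical the decomposition is degenerate; F is defined
    as 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if df_within < 1:
        raise ValueError("need at least one group with >= 2 observations")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ss_between + ss_within
    if ss_total == 0.0:
        return AnovaResult(0.0, df_between, df_within, 1.0, 0.0)
    eta2 = ss_between / ss_total
    if ss_within == 0.0:
        return AnovaResult(math.inf, df_between, df_within, 0.0, eta2)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p, float(eta2))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ols_regression(
    design,
    response: Sequence[float],
    names: Sequence[str] | None = None,
) -> RegressionResult:
    """Linear-probability OLS of a 0/1 outcome on predictor columns.

    A constant is prepended.  This mirrors the trial's analysis choice of
    an ordinary-least-squares fit to the dichotomous outcome rather than a
    logistic model.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(response) == X.shape[1]:
        X = X.T
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("design and response lengths differ")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if Xc.shape[0] <= Xc.shape[1]:
        raise ValueError("need more observations than coefficients")
    fit = sm.OLS(y, Xc).fit()
    if names is None:
        names = tuple(f"x{i+1}" for i in range(X.shape[1]))
    return RegressionResult(
        params=np.asarray(fit.params),
        param_names=("const",) + tuple(names),
        pvalues=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
    )


def linear_by_linear(
    table,
    row_scores: Sequence[float] | None = None,
    col_scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Mantel-Haenszel linear-by-linear trend statistic for ordered tables.

    ``(N - 1) * r**2`` where r is the Pearson correlation of the row/column
    scores over the N individual observations; compared to chi-square with
    1 df.  Default scores are 1..r and 1..c.
    """
    t = _as_table(table)
    r, c = t.shape
    row_scores = np.asarray(row_scores if row_scores is not None else np.arange(1, r + 1), float)
    col_scores = np.asarray(col_scores if col_scores is not None else np.arange(1, c + 1), float)
    if row_scores.size != r or col_scores.size != c:
        raise ValueError("score lengths must match table shape")
    if np.unique(row_scores).size < 2 or np.unique(col_scores).size < 2:
        raise ValueError("scores must not be constant")
    n = t.n
    w = t.counts.astype(float)
    p_r = w.sum(axis=1)
    p_c = w.sum(axis=0)
    mean_r = (row_scores * p_r).sum() / n
    mean_c = (col_scores * p_c).sum() / n
    cov = (w * np.outer(row_scores - mean_r, col_scores - mean_c)).sum()
    var_r = (p_r * (row_scores - mean_r) ** 2).sum()
    var_c = (p_c * (col_scores - mean_c) ** 2).sum()
    if var_r == 0 or var_c == 0:
        raise ValueError("degenerate score distribution (all mass at one level)")
    r_corr = cov / math.sqrt(var_r * var_c)
    statistic = (n - 1) * r_corr**2
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p
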