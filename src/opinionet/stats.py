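"""Group-difference statistics as auditable formulas.

Implements the estimators an opinion-polarization analysis reports: partial
eta-squared and its noncentral-F confidence interval, one-way ANOVA, Wilks'
lambda MANOVA with Rao's F approximation, binary logistic regression with
Wald odds-ratio intervals, Pearson chi-square independence tests and Pearson
correlations. Effect-size conversions are exposed separately so printed
(F, df) and lambda values can be converted and checked directly.

Conventions: sample (n-1) variances throughout; all p-values two-sided; no
multiple-testing correction is applied by default. The eta-squared CI maps
the noncentrality parameter lambda to eta^2 via lambda / (lambda + df1 +
df2 + 1); the function is isolated so an alternative convention can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "EffectSizeResult",
    "LogisticResult",
    "CorrelationResult",
    "partial_eta_sq",
    "eta_sq_from_wilks",
    "eta_sq_ci",
    "oneway_anova",
    "wilks_manova",
    "difference_scores",
    "logistic_fit",
    "chi_square_independence",
    "pearson_corr",
]


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    df: int
    p: float


@dataclass
class EffectSizeResult:
    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float
    wilks_lambda: float | None = None
    ci_level: float | None = None
    ci: tuple[float, float] | None = None


@dataclass
class LogisticResult:
    """ML logistic fit: coefficients, Wald SEs, odds ratios and model fit."""

    params: pd.Series
    se: pd.Series
    or_: pd.Series
    or_ci: pd.DataFrame  # columns lo, hi
    p_values: pd.Series
    model_chi_sq: AssociationResult
    pct_correct: float
    llf: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared recovered from an F ratio: F*df1 / (F*df1 + df2)."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def eta_sq_from_wilks(lam: float) -> float:
    """Multivariate eta-squared 1 - lambda (exact for two-group designs)."""
    if not 0 < lam <= 1:
        raise ValueError("Wilks lambda must lie in (0, 1]")
    return 1.0 - lam


def _lambda_to_eta(nc: float, df1: float, df2: float) -> float:
    return nc / (nc + df1 + df2 + 1)


def eta_sq_ci(F: float, df1: int, df2: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-F confidence interval for partial eta-squared.

    Finds noncentrality bounds at which the observed F sits at the
    (1+level)/2 and (1-level)/2 quantiles of the noncentral F distribution,
    then maps each bound through lambda / (lambda + df1 + df2 + 1). The lower
    bound is floored at 0 (one-sided effects cannot be negative).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")

    def solve(target: float) -> float:
        # cdf is decreasing in nc; nc s.t. P(F' <= F | nc) = target
        if sps.ncf.cdf(F, df1, df2, 0.0) <= target:
            return 0.0
        hi = max(10.0, 4 * F * df1)
        while sps.ncf.cdf(F, df1, df2, hi) > target:
            hi *= 2
            if hi > 1e8:
                raise RuntimeError(
                    f"noncentrality inversion diverged (F={F}, df=({df1},{df2}))"
                )
        return optimize.brentq(
            lambda nc: sps.ncf.cdf(F, df1, df2, nc) - target, 0.0, hi, xtol=1e-10
        )

    lo_nc = solve((1 + level) / 2)
    hi_nc = solve((1 - level) / 2)
    return (max(0.0, _lambda_to_eta(lo_nc, df1, df2)),
            _lambda_to_eta(hi_nc, df1, df2))


def oneway_anova(groups: Sequence[Sequence[float]]) -> EffectSizeResult:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    N = sum(a.size for a in arrs)
    g = len(arrs)
    if N <= g:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1, df2 = g - 1, N - g
    if ssw == 0 and ssb == 0:
        raise ValueError("zero variance everywhere; F undefined")
    if ssw == 0:
        return EffectSizeResult(F=np.inf, df1=df1, df2=df2, p=0.0, eta_sq=1.0)
    F = (ssb / df1) / (ssw / df2)
    return EffectSizeResult(
        F=float(F), df1=df1, df2=df2,
        p=float(sps.f.sf(F, df1, df2)),
        eta_sq=partial_eta_sq(F, df1, df2),
    )


def wilks_manova(Y: np.ndarray | pd.DataFrame, groups: Sequence) -> EffectSizeResult:
    """Wilks' lambda one-way MANOVA with Rao's F approximation.

    lambda = det(E) / det(E + H) with E the within-group and H the
    between-group cross-product matrices; eta^2 = 1 - lambda^(1/s). With one
    outcome this reduces exactly to the one-way ANOVA F test.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(groups)
    if len(labels) != len(Y):
        raise ValueError("groups length must match rows of Y")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    n, p = Y.shape
    q = len(uniq) - 1
    v = n - len(uniq)
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for gval in uniq:
        sub = Y[labels == gval]
        mean_g = sub.mean(axis=0)
        dev = sub - mean_g
        E += dev.T @ dev
        dg = (mean_g - grand)[:, None]
        H += len(sub) * (dg @ dg.T)
    det_e = np.linalg.det(E)
    if det_e <= 0 or not np.isfinite(det_e):
        raise np.linalg.LinAlgError(
            "within-group cross-product matrix is singular; "
            "use fewer outcomes or more cases"
        )
    lam = det_e / np.linalg.det(E + H)
    lam = float(min(max(lam, np.finfo(float).tiny), 1.0))
    # Rao's approximation (exact for p <= 2 or q <= 2)
    if p * p + q * q - 5 > 0:
        s = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        s = 1.0
    w = v + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * s - (p * q - 2) / 2
    lam_root = lam ** (1.0 / s)
    F = (1 - lam_root) / lam_root * df2 / df1
    return EffectSizeResult(
        F=float(F), df1=float(df1), df2=float(df2),
        p=float(sps.f.sf(F, df1, df2)),
        eta_sq=float(1 - lam_root),
        wilks_lambda=lam,
    )


def difference_scores(outcomes_by_wave: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Successive-wave difference scores for repeated-measures analysis.

    Given per-wave frames (cases x outcomes, identical index and columns),
    returns a cases x (outcomes * (waves-1)) frame of wave-to-wave changes;
    feeding it to :func:`wilks_manova` with group labels tests the
    group x time interaction multivariately.
    """
    if len(outcomes_by_wave) < 2:
        raise ValueError("need >= 2 waves")
    first = outcomes_by_wave[0]
    for f in outcomes_by_wave[1:]:
        if not f.index.equals(first.index) or list(f.columns) != list(first.columns):
            raise ValueError("waves must share index and columns")
    parts = []
    for t in range(1, len(outcomes_by_wave)):
        diff = outcomes_by_wave[t] - outcomes_by_wave[t - 1]
        diff.columns = [f"{c}_d{t}" for c in first.columns]
        parts.append(diff)
    return pd.concat(parts, axis=1)


def logistic_fit(X: np.ndarray | pd.DataFrame, y: Sequence[int],
                 names: Sequence[str] | None = None) -> LogisticResult:
    """Binary logistic regression by maximum likelihood with Wald inference.

    Adds an intercept, fits by Newton iterations to tolerance 1e-8, and
    reports exp(B) odds ratios with Wald CIs, the likelihood-ratio model
    chi-square against the intercept-only model, and percent correctly
    classified at a 0.5 probability cutoff.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must contain both classes coded 0/1")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        if names is None:
            names = [f"x{i + 1}" for i in range(X.shape[1])]
    const_cols = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const_cols:
        raise ValueError(f"constant predictor(s) duplicate the intercept: {const_cols}")
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    if np.abs(fit.bse).max() > 1e4:
        raise ValueError("quasi-perfect separation: a Wald SE exploded")
    index = ["intercept"] + list(names)
    params = pd.Series(fit.params, index=index)
    se = pd.Series(fit.bse, index=index)
    z = sps.norm.ppf(0.975)
    or_ci = pd.DataFrame({
        "lo": np.exp(params - z * se), "hi": np.exp(params + z * se),
    }, index=index)
    lr = 2 * (fit.llf - fit.llnull)
    df = len(names)
    phat = fit.predict(design)
    pct = float(np.mean((phat >= 0.5) == (y == 1.0)) * 100)
    return LogisticResult(
        params=params, se=se, or_=np.exp(params), or_ci=or_ci,
        p_values=pd.Series(fit.pvalues, index=index),
        model_chi_sq=AssociationResult(float(lr), df, float(sps.chi2.sf(lr, df))),
        pct_correct=pct, llf=float(fit.llf),
    )


def chi_square_independence(table: np.ndarray | Sequence[Sequence[float]],
                            correction: bool = False) -> AssociationResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the margin product; ``correction`` applies the
    Yates continuity correction (2x2 tables only).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row/column margin; statistic undefined")
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if correction:
        if obs.shape != (2, 2):
            raise ValueError("continuity correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return AssociationResult(stat, df, float(sps.chi2.sf(stat, df)))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share length n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return CorrelationResult(r, n, 0.0)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return CorrelationResult(r, n, float(2 * sps.t.sf(abs(t), n - 2)))
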