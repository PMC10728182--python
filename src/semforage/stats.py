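"""Supporting inferential statistics for the foraging analysis.

Pearson correlations with classical t-tests, the default (JZS-style)
Bayes factor for a correlation under a stretched symmetric beta prior,
the exact binomial test, and OLS multiple regression with an optional
interaction term and optional log-transform of time-valued predictors.
A tidy per-participant table ties the MVT metrics to covariates such as
age so every correlation in the analysis is a single call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps
import statsmodels.api as sm

from .coding import CodedDataset
from .foraging import HoldPolicy, TimingPolicy, mvt_analysis

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "pearson_correlation",
    "jzs_correlation_bf",
    "exact_binomial",
    "ols_regression",
    "participant_table",
]


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_two_sided: float
    bf10: float | None = None

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass
class RegressionResult:
    params: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    df_resid: int
    r_squared: float
    terms: list[str]


def pearson_correlation(x, y, bayes: bool = False, kappa: float = 1.0) -> CorrelationResult:
    """Pearson r with its t-test (and optionally the correlation Bayes factor)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    p = 2 * sps.t.sf(abs(t), df)
    bf = jzs_correlation_bf(r, n, kappa) if bayes else None
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_two_sided=float(p), bf10=bf)


def _log_r_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Log sampling density of Pearson r given true rho (up to a rho-free constant).

    Uses the exact small-sample density of the sample correlation from a
    bivariate normal, whose rho-dependent part is
    (1-rho^2)^((n-1)/2) (1-rho r)^(-(n-3/2)) 2F1(1/2, 1/2; n-1/2; (1+rho r)/2).
    """
    rho = np.asarray(rho, dtype=float)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (
        (n - 1) / 2.0 * np.log1p(-rho * rho)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp)
    )


def jzs_correlation_bf(r: float, n: int, kappa: float = 1.0) -> float:
    """Default Bayes factor BF10 for H1: rho != 0 against H0: rho = 0.

    The prior on rho is the stretched symmetric beta: rho = 2x - 1 with
    x ~ Beta(1/kappa, 1/kappa); kappa = 1 gives the uniform prior on
    (-1, 1).  The marginal likelihood under H1 is computed by adaptive
    quadrature of the exact sampling density of r; values below 1 favor
    the null.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    a = 1.0 / kappa
    log_f0 = _log_r_density(r, np.array(0.0), n)

    def integrand(rho: float) -> float:
        prior = sps.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0
        return float(np.exp(_log_r_density(r, np.array(rho), n) - log_f0)) * prior

    val, err = integrate.quad(integrand, -1.0, 1.0, limit=200,
                              points=[float(r)], epsabs=1e-12, epsrel=1e-9)
    if not np.isfinite(val) or val <= 0:
        raise ArithmeticError(
            f"Bayes factor quadrature failed (value={val}, abserr={err})"
        )
    return float(val)


def exact_binomial(k: int, n: int, p0: float, alternative: str = "greater") -> float:
    """Exact binomial tail probability.

    ``greater``: P(X >= k); ``less``: P(X <= k); ``two-sided``: sum of all
    outcome probabilities not exceeding P(X = k) (the standard exact
    two-sided convention).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if alternative == "greater":
        return float(sps.binom.sf(k - 1, n, p0))
    if alternative == "less":
        return float(sps.binom.cdf(k, n, p0))
    if alternative == "two-sided":
        return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    raise ValueError(f"unknown alternative {alternative!r}")


def ols_regression(
    y,
    X: pd.DataFrame,
    interaction: tuple[str, str] | None = None,
    log_transform: list[str] | None = None,
) -> RegressionResult:
    """OLS with classical standard errors on a named design.

    ``interaction`` adds the product of two named predictors;
    ``log_transform`` applies the natural log to the named (time-valued)
    predictors before fitting (and before forming the interaction).
    """
    X = X.copy().astype(float)
    if log_transform:
        for col in log_transform:
            X[col] = np.log(X[col])
    if interaction is not None:
        a, b = interaction
        X[f"{a}:{b}"] = X[a] * X[b]
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = design.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear terms: {worst}")
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    return RegressionResult(
        params=fit.params,
        t_values=fit.tvalues,
        p_values=fit.pvalues,
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        terms=list(design.columns),
    )


def participant_table(
    dataset: CodedDataset,
    ages: dict[str, float] | pd.Series | None = None,
    timing_policy: TimingPolicy = "fold",
    hold_policy: HoldPolicy = "hold",
) -> pd.DataFrame:
    """Tidy per-participant table of MVT metrics and covariates.

    Columns: participant, age (if provided), switch_time_ms, leave_time_ms,
    optimal_leave_ms, abs_deviance_ms, rel_deviance, signed_deviance_ms,
    max_rate_per_ms, n_clusters, total_animals.
    """
    results = mvt_analysis(dataset, scope="participant",
                           timing_policy=timing_policy, hold_policy=hold_policy)
    totals = {
        pid: sum(cl.n_valid for cl in lists)
        for pid, lists in dataset.by_participant().items()
    }
    rows = []
    for res in results:
        row = {
            "participant": res.label,
            "switch_time_ms": res.switch_time_mean_ms,
            "leave_time_ms": res.empirical_leave_mean_ms,
            "optimal_leave_ms": res.optimal_leave_ms,
            "abs_deviance_ms": res.abs_deviance_ms,
            "rel_deviance": res.relative_deviance,
            "signed_deviance_ms": res.signed_deviance_ms,
            "max_rate_per_ms": res.max_rate_per_ms,
            "n_clusters": res.n_clusters,
            "total_animals": totals[res.label],
        }
        if ages is not None:
            row["age"] = float(ages[res.label])
        rows.append(row)
    return pd.DataFrame(rows)
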