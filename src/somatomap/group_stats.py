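"""Group-level statistics: bootstrap effect sizes, TOST equivalence with
33%-power bounds, and iterative factor-model variable exclusion.

The factor procedure fits a maximum-likelihood factor model with promax
(oblique) rotation and repeatedly removes the worst-loading variable —
first variables whose maximal absolute loading falls below the cutoff,
then cross-loading offenders — refitting after every exclusion until all
retained variables load at least the cutoff on exactly one factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import nct
from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeResult:
    hedges_g: float
    cohens_d: float
    ci_low: float
    ci_high: float
    n_boot: int

    def summary(self) -> str:
        return (f"Hedges' g = {self.hedges_g:.3f} "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}] "
                f"(Cohen's d = {self.cohens_d:.3f}, {self.n_boot} resamples)")


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled variance")
    return (a.mean() - b.mean()) / np.sqrt(sp2)


def hedges_g(group_a, group_b) -> float:
    """Small-sample-corrected standardized mean difference.

    g = J x d with J = 1 - 3 / (4 df - 1), df = nA + nB - 2.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    df = len(a) + len(b) - 2
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(J * _cohens_d(a, b))


def hedges_g_boot(group_a, group_b, n_boot: int = 10_000,
                  seed: int = 0, ci: float = 0.95,
                  method: str = "percentile") -> EffectSizeResult:
    """Hedges' g with a bootstrap confidence interval.

    Resamples within each group ``n_boot`` times (default 10,000) and
    reports the percentile interval; ``method='bca'`` applies the
    bias-corrected accelerated interval instead.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    g = hedges_g(a, b)
    d = _cohens_d(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=len(a), replace=True)
        rb = rng.choice(b, size=len(b), replace=True)
        try:
            boots[i] = hedges_g(ra, rb)
        except ZeroDivisionError:
            boots[i] = np.nan
    boots = boots[np.isfinite(boots)]
    alpha = 1.0 - ci
    if method == "percentile":
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    elif method == "bca":
        from scipy.stats import norm
        z0 = norm.ppf(np.mean(boots < g))
        # jackknife acceleration
        pooled = [(np.delete(a, i), b) for i in range(len(a))] + \
                 [(a, np.delete(b, i)) for i in range(len(b))]
        jack = np.array([hedges_g(x, y) for x, y in pooled])
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        acc = num / den if den else 0.0
        za, zb = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
        p_lo = norm.cdf(z0 + (z0 + za) / (1 - acc * (z0 + za)))
        p_hi = norm.cdf(z0 + (z0 + zb) / (1 - acc * (z0 + zb)))
        lo, hi = np.quantile(boots, [p_lo, p_hi])
    else:
        raise ValueError("method must be 'percentile' or 'bca'")
    return EffectSizeResult(hedges_g=float(g), cohens_d=float(d),
                            ci_low=float(lo), ci_high=float(hi),
                            n_boot=int(n_boot))


# ---------------------------------------------------------------------------
# equivalence testing
# ---------------------------------------------------------------------------

@dataclass
class TOSTResult:
    t: float
    p: float
    equivalent: bool
    t_lower: float
    t_upper: float
    mean_difference: float


def tost_equivalence(group_a, group_b, delta_low: float, delta_high: float,
                     alpha: float = 0.05) -> TOSTResult:
    """Two one-sided t-tests for equivalence against raw-unit bounds.

    Tests that the mean difference A - B lies inside
    (delta_low, delta_high) with two pooled-variance one-sided t-tests;
    the reported statistic is the less significant of the two (the one
    with the smaller absolute t / larger p).  p < alpha declares
    equivalence: the true difference lies in the indifference area.
    """
    if not delta_low < delta_high:
        raise ValueError("delta_low must be below delta_high")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = a.mean() - b.mean()
    df = na + nb - 2
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0:
        raise ZeroDivisionError("zero pooled variance")
    t_lower = (diff - delta_low) / se    # H0: diff <= delta_low
    t_upper = (diff - delta_high) / se   # H0: diff >= delta_high
    p_lower = t_dist.sf(t_lower, df)
    p_upper = t_dist.cdf(t_upper, df)
    if p_lower >= p_upper:
        t_rep, p_rep = t_lower, p_lower
    else:
        t_rep, p_rep = t_upper, p_upper
    return TOSTResult(t=float(t_rep), p=float(p_rep),
                      equivalent=bool(p_rep < alpha),
                      t_lower=float(t_lower), t_upper=float(t_upper),
                      mean_difference=float(diff))


def _power_two_sample_t(d: float, na: int, nb: int, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at effect size d."""
    df = na + nb - 2
    ncp = d * np.sqrt(na * nb / (na + nb))
    tc = t_dist.ppf(1.0 - alpha / 2.0, df)
    p = nct.sf(tc, df, ncp) + nct.cdf(-tc, df, ncp)
    if np.isnan(p):  # extreme noncentrality: power has saturated
        p = 1.0
    return float(p)


def power33_bounds(n_a: int, n_b: int, alpha: float = 0.05,
                   power: float = 0.33):
    """Symmetric equivalence bounds at the 33%-power effect size.

    Returns (-d*, +d*) in Cohen's d units, where d* is the effect size a
    two-sample t-test with these group sizes detects with the requested
    power; solved from the noncentral t distribution.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be at least 2")
    f = lambda d: _power_two_sample_t(d, n_a, n_b, alpha) - power
    hi = 0.5
    while f(hi) < 0 and hi < 64:
        hi *= 2
    d_star = optimize.brentq(f, 1e-6, hi, xtol=1e-10)
    return (-float(d_star), float(d_star))


# ---------------------------------------------------------------------------
# iterative factor model
# ---------------------------------------------------------------------------

@dataclass
class FactorModelResult:
    retained: list
    loadings: pd.DataFrame          # retained variables x factors (rotated)
    psi: pd.Series                  # specific variances of retained variables
    exclusion_trace: list = field(default_factory=list)
    converged: bool = True
    heywood: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["iterative factor model",
                 "=" * 46,
                 f"retained variables : {', '.join(self.retained) or '(none)'}",
                 f"mean psi           : "
                 f"{np.nan if self.psi.empty else self.psi.mean():.3f}"]
        for step in self.exclusion_trace:
            lines.append(f"excluded {step['variable']!r} ({step['reason']}, "
                         f"max |loading| = {step['max_abs_loading']:.3f})")
        if self.heywood:
            lines.append(f"Heywood cases: {', '.join(self.heywood)}")
        if not self.loadings.empty:
            lines.append("")
            lines.append(self.loadings.round(3).to_string())
        return "\n".join(lines)


def _ml_promax_loadings(X: np.ndarray, n_factors: int):
    """ML factor extraction + promax rotation (statsmodels numerics)."""
    from statsmodels.multivariate.factor import Factor
    res = Factor(X, n_factor=n_factors, method="ml").fit()
    if n_factors > 1:
        res.rotate("promax")
    return np.asarray(res.loadings), np.asarray(res.uniqueness)


def iterative_factor_model(X, n_factors: int = 2,
                           loading_cutoff: float = 0.4,
                           heywood_tol: float = 1e-3) -> FactorModelResult:
    """Fit a factor model, iteratively excluding weak/cross-loading variables.

    ``X`` is an observations x variables array or DataFrame (standardized
    internally).  Each round fits an ML factor model with promax rotation
    and, if any retained variable fails the acceptance rule — maximal
    absolute loading >= ``loading_cutoff`` on exactly one factor — removes
    the single worst offender (lowest maximal |loading| first, ties by
    variable order; once all maxima pass, the worst cross-loader) and
    refits.  The full exclusion trace is returned; variables whose
    specific variance collapses toward zero are reported as Heywood cases.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        data = X.to_numpy(float)
    else:
        data = np.asarray(X, float)
        names = [f"var{i}" for i in range(data.shape[1])]
    n_obs, n_var = data.shape
    if n_obs <= n_var:
        raise ValueError("need more observations than variables")
    if not n_factors < n_var:
        raise ValueError("n_factors must be below the number of variables")
    data = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)

    retained = list(range(n_var))
    trace: list[dict] = []
    converged = True
    loadings = np.zeros((0, n_factors))
    psi = np.zeros(0)

    while len(retained) > n_factors:
        sub = data[:, retained]
        try:
            loadings, psi = _ml_promax_loadings(sub, n_factors)
        except Exception:
            converged = False
            break
        max_abs = np.max(np.abs(loadings), axis=1)
        n_big = np.sum(np.abs(loadings) >= loading_cutoff, axis=1)

        weak = np.flatnonzero(max_abs < loading_cutoff)
        cross = np.flatnonzero(n_big > 1)
        if weak.size:
            drop = weak[np.argmin(max_abs[weak])]
            reason = "below cutoff"
        elif cross.size:
            # cross-loader whose secondary loading is largest
            second = np.sort(np.abs(loadings[cross]), axis=1)[:, -2]
            drop = cross[np.argmax(second)]
            reason = "cross-loading"
        else:
            break
        trace.append({"variable": names[retained[drop]], "reason": reason,
                      "max_abs_loading": float(max_abs[drop])})
        del retained[drop]
    else:
        if len(retained) <= n_factors and len(retained) > 0:
            try:
                loadings, psi = _ml_promax_loadings(data[:, retained], n_factors)
            except Exception:
                converged = False

    kept = [names[i] for i in retained]
    cols = [f"factor{k + 1}" for k in range(n_factors)]
    ldf = pd.DataFrame(loadings, index=kept[:len(loadings)], columns=cols)
    psi_s = pd.Series(np.clip(psi, 0.0, 1.0), index=kept[:len(psi)], name="psi")
    heywood = [v for v, p in psi_s.items() if p < heywood_tol]
    return FactorModelResult(retained=kept, loadings=ldf, psi=psi_s,
                             exclusion_trace=trace, converged=converged,
                             heywood=heywood)


class IterativeFactorModel:
    """Model-object wrapper around :func:`iterative_factor_model`."""

    def __init__(self, X, n_factors: int = 2, loading_cutoff: float = 0.4):
        self.X = X
        self.n_factors = n_factors
        self.loading_cutoff = loading_cutoff

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_factors: int = 2,
                       loading_cutoff: float = 0.4):
        return cls(df, n_factors=n_factors, loading_cutoff=loading_cutoff)

    def fit(self) -> FactorModelResult:
        return iterative_factor_model(self.X, self.n_factors,
                                      self.loading_cutoff)


def retained_correlations(X: pd.DataFrame, result: FactorModelResult) -> pd.DataFrame:
    """Pearson correlations between the retained variables (convenience)."""
    return X[result.retained].corr(method="pearson")
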