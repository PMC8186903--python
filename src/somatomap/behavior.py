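"""Mislocalization and tactile-acuity analysis.

Five-alternative finger mislocalization trials are condensed into a 5x5
confusion matrix; mislocalizations are grouped by their neighbor distance
to the stimulated finger (N1..N4) and compared to a proportional chance
model with 8:6:4:2 weights (the counts of ordered digit pairs at each
neighbor distance among five fingers) using the G-test of goodness of
fit with Holm-Bonferroni correction.  Signal-detection sensitivity (d')
and response criterion (beta) per finger use the log-linear correction.
Two-point discrimination thresholds come from a binary logistic fit,
read off at the 50% point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .datatypes import BehavioralTrialTable, ConfusionMatrix

#: ordered (stimulated, reported) digit pairs at neighbor distance 1..4
NEIGHBOR_WEIGHTS = np.array([8, 6, 4, 2])


def confusion_from_trials(trials: BehavioralTrialTable) -> ConfusionMatrix:
    """Tally stimulated x reported digit counts; zero-error digits stay 0."""
    df = trials.trials
    if len(df) == 0:
        raise ValueError("empty trial table")
    counts = np.zeros((5, 5))
    for s, r in zip(df["stimulated_digit"], df["reported_digit"]):
        counts[s - 1, r - 1] += 1
    return ConfusionMatrix(counts=counts)


def neighbor_counts(conf: ConfusionMatrix) -> pd.Series:
    """Observed mislocalizations per neighbor distance N1..N4.

    An error reported k fingers away from the stimulated one counts
    toward Nk (e.g. D2 stimulated, D4 reported -> N2).
    """
    out = np.zeros(4)
    for i in range(5):
        for j in range(5):
            k = abs(i - j)
            if k > 0:
                out[k - 1] += conf.counts[i, j]
    return pd.Series(out, index=["N1", "N2", "N3", "N4"])


def chance_expected(total_mislocalizations: float) -> pd.DataFrame:
    """Proportional-chance expectation for N1..N4 mislocalizations.

    The five stimulated digits offer 8 first-, 6 second-, 4 third- and 2
    fourth-neighbor response options in total, so chance distributes the
    observed total proportionally as 8:6:4:2 (fractions of 20).  Rounded
    values are reported alongside for display.
    """
    if total_mislocalizations < 0:
        raise ValueError("total must be non-negative")
    frac = total_mislocalizations * NEIGHBOR_WEIGHTS / NEIGHBOR_WEIGHTS.sum()
    return pd.DataFrame({"expected": frac,
                         "expected_rounded": np.round(frac).astype(int)},
                        index=["N1", "N2", "N3", "N4"])


def g_test(observed, expected):
    """G-test of goodness of fit: G = 2 sum O ln(O/E), df = cells - 1.

    Zero observed cells contribute 0 (the 0 ln 0 limit); the p-value uses
    the chi-square reference distribution.
    """
    O = np.asarray(observed, float)
    E = np.asarray(expected, float)
    if O.shape != E.shape:
        raise ValueError("observed and expected differ in shape")
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    if not np.isclose(O.sum(), E.sum(), rtol=1e-6):
        raise ValueError("observed and expected totals differ")
    nz = O > 0
    G = 2.0 * np.sum(O[nz] * np.log(O[nz] / E[nz]))
    df = O.size - 1
    return float(G), int(df), float(chi2.sf(G, df))


def holm_bonferroni(pvalues, alpha: float = 0.05):
    """Holm-Bonferroni step-down correction over a family of tests.

    Returns (reject flags, adjusted p-values) in the input order.
    """
    from statsmodels.stats.multitest import multipletests
    reject, p_adj, *_ = multipletests(np.asarray(pvalues, float),
                                      alpha=alpha, method="holm")
    return reject, p_adj


@dataclass
class SDTMeasures:
    """Per-finger signal-detection measures from the 5-AFC confusion data."""

    hits: np.ndarray
    misses: np.ndarray
    false_alarms: np.ndarray
    correct_rejections: np.ndarray
    hit_rate: np.ndarray       # after log-linear correction
    fa_rate: np.ndarray        # after log-linear correction
    d_prime: np.ndarray
    beta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hits": self.hits, "misses": self.misses,
            "false_alarms": self.false_alarms,
            "correct_rejections": self.correct_rejections,
            "hit_rate": self.hit_rate, "fa_rate": self.fa_rate,
            "d_prime": self.d_prime, "beta": self.beta,
        }, index=[f"D{i}" for i in range(1, 6)])


def sdt_measures(conf: ConfusionMatrix) -> SDTMeasures:
    """d' and beta per finger with the log-linear correction.

    Hits: the finger was stimulated and reported.  False alarms: the
    finger was reported when another finger was stimulated, pooled over
    all non-target stimulations.  The log-linear correction adds 0.5 to
    the hit and false-alarm counts and 1 to each denominator, so rates
    lie strictly in (0, 1).  d' = z(hit) - z(fa);
    beta = exp((z(fa)^2 - z(hit)^2) / 2).
    """
    c = conf.counts
    total = c.sum()
    hits = np.diag(c).astype(float)
    n_signal = c.sum(axis=1)
    misses = n_signal - hits
    fa = c.sum(axis=0) - hits
    n_noise = total - n_signal
    crej = n_noise - fa

    hr = (hits + 0.5) / (n_signal + 1.0)
    far = (fa + 0.5) / (n_noise + 1.0)
    zh, zf = norm.ppf(hr), norm.ppf(far)
    d_prime = zh - zf
    beta = np.exp((zf ** 2 - zh ** 2) / 2.0)
    return SDTMeasures(hits=hits, misses=misses, false_alarms=fa,
                       correct_rejections=crej, hit_rate=hr, fa_rate=far,
                       d_prime=d_prime, beta=beta)


def mislocalization_percentages(conf: ConfusionMatrix) -> dict:
    """Relative distribution of mislocalizations under both normalizations.

    ``per_digit``: each stimulated digit's errors as a fraction of that
    digit's mislocalizations; ``per_total``: as a fraction of all
    mislocalizations.
    """
    c = conf.counts.copy()
    np.fill_diagonal(c, 0.0)
    row = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_digit = np.where(row > 0, c / row, 0.0) * 100.0
    tot = c.sum()
    per_total = (c / tot if tot > 0 else c) * 100.0
    digits = [f"D{i}" for i in range(1, 6)]
    return {"per_digit": pd.DataFrame(per_digit, index=digits, columns=digits),
            "per_total": pd.DataFrame(per_total, index=digits, columns=digits)}


@dataclass
class TwoPointResult:
    threshold_mm: float
    slope: float
    intercept: float
    estimable: bool
    method: str   # 'logistic' or 'bracket'

    def summary(self) -> str:
        return (f"two-point discrimination threshold: {self.threshold_mm:.3f} mm "
                f"({self.method}; estimable={self.estimable})")


def two_pd_threshold(distances_mm, responses) -> TwoPointResult:
    """50% threshold of a binary logistic fit of 'two felt' vs pin distance.

    Maximum-likelihood logistic regression in distance; the threshold is
    the distance where the fitted curve crosses p = 0.5 (-b0/b1).  With a
    perfect step (complete separation) the MLE diverges, so the midpoint
    of the bracketing distances is returned with ``method='bracket'``;
    all-same responses are flagged non-estimable.
    """
    d = np.asarray(distances_mm, float)
    y = np.asarray(responses, float)
    if d.shape != y.shape:
        raise ValueError("one response per distance required")
    if len(np.unique(d)) < 2 or y.min() == y.max():
        return TwoPointResult(np.nan, np.nan, np.nan, False, "none")

    lo = d[y == 0].max() if np.any(y == 0) else -np.inf
    hi = d[y == 1].min() if np.any(y == 1) else np.inf
    if lo < hi:  # complete separation: a perfect step between lo and hi
        return TwoPointResult(float((lo + hi) / 2.0), np.inf, np.nan,
                              True, "bracket")

    X = sm.add_constant(d)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b0, b1 = res.params
    except Exception:
        return TwoPointResult(np.nan, np.nan, np.nan, False, "none")
    if b1 == 0:
        return TwoPointResult(np.nan, float(b1), float(b0), False, "logistic")
    return TwoPointResult(float(-b0 / b1), float(b1), float(b0),
                          True, "logistic")


def two_pd_threshold_runs(tables) -> float:
    """Average per-run two-point thresholds across runs (NaN-aware)."""
    thr = [two_pd_threshold(t["distance_mm"].to_numpy(),
                            t["two_felt"].to_numpy()).threshold_mm
           for t in tables]
    return float(np.nanmean(thr))
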