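"""Representational similarity of finger maps, and resting-state coupling.

Finger activation patterns are summarized per run as contrast maps from an
ordinary least-squares fit with five HRF-convolved digit regressors; the
5x5 matrix of Pearson correlations between run-1 and run-2 digit patterns
is the between-run representational similarity matrix, summarized by
digit-neighbor distance (N0 same finger .. N4 most distant pair).
Resting-state coupling between finger time series is the normalized
cross-correlation over lags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import StimulusDesign, TimeSeriesMatrix
from .hrf import convolve_hrf, double_gamma_hrf

#: contrast weights: 4 x own digit minus 1 x each other digit
CONTRAST_OWN = 4.0


def finger_betas(ts: TimeSeriesMatrix, design: StimulusDesign,
                 hrf: np.ndarray | None = None,
                 contrast: bool = True) -> np.ndarray:
    """Per-digit per-vertex response maps from an OLS fit (5 x n_vertices).

    With ``contrast=True`` each digit's map is the [4 -1 -1 -1 -1]-style
    contrast of the five digit betas (own digit weighted +4, every other
    digit -1); with ``contrast=False`` the raw betas are returned.
    """
    if hrf is None:
        hrf = double_gamma_hrf(design.tr_s)
    X = convolve_hrf(design.digit_indicator(), hrf,
                     circular=design.kind in ("phase_forward", "phase_reverse"))
    X = np.column_stack([X, np.ones(design.n_volumes)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    beta = beta[:5]  # drop intercept
    if not contrast:
        return beta
    C = -np.ones((5, 5)) + np.eye(5) * (CONTRAST_OWN + 1.0)
    return C @ beta


def between_run_similarity(betas_run1: np.ndarray, betas_run2: np.ndarray,
                           mask: np.ndarray | None = None,
                           fisher_z: bool = False) -> np.ndarray:
    """5x5 Pearson correlations between run-1 and run-2 digit maps.

    Entry (i, j) correlates run-1 digit i with run-2 digit j over the
    masked vertices.  ``fisher_z`` applies atanh elementwise.  Constant
    maps yield NaN entries.
    """
    b1 = np.asarray(betas_run1, float)
    b2 = np.asarray(betas_run2, float)
    if b1.shape != b2.shape or b1.shape[0] != 5:
        raise ValueError("expected two aligned (5, n_vertices) beta arrays")
    if mask is not None:
        mask = np.asarray(mask, bool)
        b1, b2 = b1[:, mask], b2[:, mask]
    out = np.empty((5, 5))
    for i in range(5):
        for j in range(5):
            x, y = b1[i], b2[j]
            if x.std() == 0 or y.std() == 0:
                out[i, j] = np.nan
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1]
    if fisher_z:
        with np.errstate(divide="ignore"):
            out = np.arctanh(out)
    return out


def neighbor_summary(matrix: np.ndarray, ordered: bool = True) -> pd.Series:
    """Mean similarity per neighbor distance N0..N4.

    ``ordered=True`` averages all ordered (i, j) entries with |i-j| = k —
    5, 8, 6, 4, 2 entries for k = 0..4 — matching the between-run matrix,
    which need not be symmetric; ``ordered=False`` averages each unordered
    pair once.
    """
    m = np.asarray(matrix, float)
    if m.shape != (5, 5):
        raise ValueError("expected a 5x5 similarity matrix")
    vals = {}
    for k in range(5):
        ii, jj = np.nonzero(np.abs(np.subtract.outer(range(5), range(5))) == k)
        if not ordered:
            keep = ii <= jj
            ii, jj = ii[keep], jj[keep]
        vals[f"N{k}"] = float(np.nanmean(m[ii, jj]))
    return pd.Series(vals)


def resting_xcorr(series_i: np.ndarray, series_j: np.ndarray,
                  max_lag_trs: int = 130):
    """Normalized cross-correlation of two series over +/-max_lag TRs.

    At each lag the Pearson correlation is computed over the overlapping
    segment (positive lag: ``series_j`` shifted later).  Returns a Series
    indexed by lag, plus the peak lag.
    """
    x = np.asarray(series_i, float)
    y = np.asarray(series_j, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    if n <= max_lag_trs + 2:
        raise ValueError("series shorter than the maximal lag")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series have undefined correlation")
    lags = np.arange(-max_lag_trs, max_lag_trs + 1)
    r = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[:n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[:n + lag]
        r[k] = np.corrcoef(a, b)[0, 1] if (a.std() and b.std()) else np.nan
    series = pd.Series(r, index=lags, name="xcorr")
    peak_lag = int(series.idxmax())
    return series, peak_lag
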