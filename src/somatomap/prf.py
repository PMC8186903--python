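"""1D Gaussian population receptive field (pRF) modeling.

Each vertex's aggregate tuning over the finger axis is modeled as a
Gaussian with center ``x`` (stimulus-space units, bounded to +/-12.5) and
width ``sigma`` (bounded to [0.5, 25]: one tenth of a fingertip interval
up to the whole five-finger space).  The predicted BOLD response is the
HRF-convolved Gaussian drive scaled by a gain and offset by a baseline;
gain and baseline are solved linearly for every candidate (x, sigma), and
the nonlinear pair is optimized by a coarse grid followed by bounded
least squares.

Voxel screening and fitting are exposed both as plain functions and as a
``PRFModel`` / ``PRFResults`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f as f_dist

from .datatypes import (DIGIT_INTERVAL, STIM_SPACE_HALFWIDTH, StimulusDesign,
                        TimeSeriesMatrix, digit_of_position)
from .hrf import convolve_hrf, double_gamma_hrf
from .synth import gaussian_response

X_BOUNDS = (-STIM_SPACE_HALFWIDTH, STIM_SPACE_HALFWIDTH)
SIGMA_BOUNDS = (DIGIT_INTERVAL / 10.0, 25.0)  # 0.5 .. 25 stimulus units


@dataclass
class PRFParams:
    x: float
    sigma: float
    gain: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.sigma < SIGMA_BOUNDS[0]:
            raise ValueError(f"sigma must be >= {SIGMA_BOUNDS[0]}")


@dataclass
class PRFFit:
    params: PRFParams
    goodness: float          # variance explained, clipped to [0, 1]
    converged: bool
    assigned_digit: int      # from center binning into 5-unit intervals


def _regressor(x: float, sigma: float, design: StimulusDesign,
               hrf: np.ndarray | None) -> np.ndarray:
    neural = gaussian_response(design.stimulus_position, x, sigma)
    if hrf is None:
        return neural
    circular = design.kind in ("phase_forward", "phase_reverse")
    return convolve_hrf(neural, hrf, circular=circular)


def prf_predict(params: PRFParams, design: StimulusDesign,
                hrf: np.ndarray | None = None) -> np.ndarray:
    """Predicted series: baseline + gain x HRF-convolved Gaussian drive.

    ``hrf=None`` returns the unconvolved neural prediction.
    """
    if design.stimulus_position is None:
        raise ValueError("design has no stimulus_position")
    return params.baseline + params.gain * _regressor(params.x, params.sigma,
                                                      design, hrf)


def screen_vertices(ts: TimeSeriesMatrix, design: StimulusDesign,
                    alpha: float = 0.05,
                    hrf: np.ndarray | None = None) -> np.ndarray:
    """Omnibus F-test screen: which vertices respond to any finger?

    OLS with five HRF-convolved digit boxcar regressors plus intercept;
    vertices pass when the omnibus F of the five digit effects has
    p < alpha (uncorrected).  Zero-variance series never pass.
    """
    if design.kind == "rest":
        raise ValueError("screening needs a stimulation design")
    if hrf is None:
        hrf = double_gamma_hrf(design.tr_s)
    X = convolve_hrf(design.digit_indicator(), hrf,
                     circular=design.kind in ("phase_forward", "phase_reverse"))
    n = design.n_volumes
    X = np.column_stack([X, np.ones(n)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")

    Y = ts.data
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    rss1 = np.sum((Y - X @ beta) ** 2, axis=0)
    rss0 = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)  # intercept-only model
    p_eff, dfe = 5, n - X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / p_eff) / (rss1 / dfe)
    pvals = f_dist.sf(F, p_eff, dfe)
    mask = np.nan_to_num(pvals, nan=1.0) < alpha
    mask[rss0 == 0] = False  # flat series excluded
    return mask


def _linear_fit(r: np.ndarray, y: np.ndarray):
    """Solve gain (>= 0) and baseline for a fixed regressor; return RSS."""
    A = np.column_stack([r, np.ones_like(r)])
    (g, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    if g < 0:
        g, b = 0.0, y.mean()
    resid = y - (g * r + b)
    return g, b, float(resid @ resid)


def fit_prf(ts_vertex: np.ndarray, design: StimulusDesign,
            bounds=(X_BOUNDS, SIGMA_BOUNDS), n_grid=(25, 12),
            hrf: np.ndarray | None = None, seed: int = 0) -> PRFFit:
    """Fit center and width of a 1D Gaussian pRF to one vertex's series.

    Coarse grid over (x, sigma) — sigma log-spaced — with gain/baseline
    solved linearly per candidate, then bounded nonlinear least-squares
    refinement of (x, sigma).  Deterministic given its inputs; ``seed`` is
    accepted for interface symmetry with the simulators.
    """
    y = np.asarray(ts_vertex, float)
    if hrf is None:
        hrf = double_gamma_hrf(design.tr_s)
    (xlo, xhi), (slo, shi) = bounds

    xs = np.linspace(xlo, xhi, n_grid[0])
    sigmas = np.geomspace(slo, shi, n_grid[1])
    cand = []
    for x in xs:
        for s in sigmas:
            r = _regressor(x, s, design, hrf)
            g, b, rss = _linear_fit(r, y)
            cand.append((rss, x, s, g, b))
    cand.sort(key=lambda c: c[0])
    rss0, x0, s0, g0, b0 = cand[0]

    def resid(theta):
        r = _regressor(theta[0], theta[1], design, hrf)
        g, b, _ = _linear_fit(r, y)
        return y - (g * r + b)

    # a few-point stimulus space identifies (x, sigma) only weakly, so the
    # refinement is multi-started from the best grid candidates at distinct
    # centers and the lowest-RSS solution wins
    starts, seen_x = [], set()
    for rss, x, s, g, b in cand:
        if round(x, 6) in seen_x:
            continue
        seen_x.add(round(x, 6))
        starts.append((x, s))
        if len(starts) == 4:
            break

    converged = True
    x1, s1, g1, b1, rss1 = x0, s0, g0, b0, rss0
    for xs0, ss0 in starts:
        try:
            sol = optimize.least_squares(resid, x0=[xs0, ss0],
                                         bounds=([xlo, slo], [xhi, shi]),
                                         xtol=1e-10, ftol=1e-10)
        except Exception:
            converged = False
            continue
        xr, sr = sol.x
        r = _regressor(xr, sr, design, hrf)
        gr, br, rssr = _linear_fit(r, y)
        if rssr < rss1 - 1e-12 or (rssr < rss1 + 1e-12 and not sol.success):
            x1, s1, g1, b1, rss1 = xr, sr, gr, br, rssr
            if not sol.success:
                converged = False
    if rss1 >= rss0 + 1e-12:  # refinement never improved on the grid
        x1, s1, g1, b1, rss1 = x0, s0, g0, b0, rss0
        converged = False

    tss = float(np.sum((y - y.mean()) ** 2))
    goodness = 0.0 if tss == 0 else float(np.clip(1.0 - rss1 / tss, 0.0, 1.0))
    params = PRFParams(x=float(np.clip(x1, xlo, xhi)),
                       sigma=float(np.clip(s1, slo, shi)),
                       gain=float(g1), baseline=float(b1))
    digit = int(digit_of_position(params.x))
    return PRFFit(params=params, goodness=goodness, converged=converged,
                  assigned_digit=digit)


def summarize_prf(fits, good_threshold: float = 0.2) -> pd.DataFrame:
    """Per-digit mean/SD pRF size over fits retained at a variance-explained
    threshold.  Digits with no retained fit are reported as missing (NaN),
    not zero."""
    rows = []
    for f in fits:
        if f.goodness >= good_threshold:
            rows.append((f.assigned_digit, f.params.sigma))
    df = pd.DataFrame(rows, columns=["digit", "sigma"])
    out = []
    for d in range(1, 6):
        s = df.loc[df.digit == d, "sigma"]
        out.append({"digit": d, "n": len(s),
                    "mean_sigma": s.mean() if len(s) else np.nan,
                    "sd_sigma": s.std(ddof=1) if len(s) > 1 else np.nan,
                    "missing": len(s) == 0})
    return pd.DataFrame(out)


class PRFModel:
    """Population receptive field model for a time-series matrix.

    Parameters
    ----------
    ts : TimeSeriesMatrix
    design : StimulusDesign
        Block or travelling-wave design with stimulus positions.
    bounds, n_grid, hrf
        Passed through to :func:`fit_prf`.
    """

    def __init__(self, ts: TimeSeriesMatrix, design: StimulusDesign,
                 bounds=(X_BOUNDS, SIGMA_BOUNDS), n_grid=(25, 12),
                 hrf: np.ndarray | None = None):
        self.ts = ts
        self.design = design
        self.bounds = bounds
        self.n_grid = n_grid
        self.hrf = hrf if hrf is not None else double_gamma_hrf(design.tr_s)

    def fit(self, alpha: float = 0.05, good_threshold: float = 0.2,
            vertices: np.ndarray | None = None) -> "PRFResults":
        """Screen vertices at ``alpha`` and fit every survivor."""
        screened = screen_vertices(self.ts, self.design, alpha=alpha,
                                   hrf=self.hrf)
        idx = np.flatnonzero(screened)
        if vertices is not None:
            idx = np.intersect1d(idx, np.asarray(vertices, int))
        fits = {int(v): fit_prf(self.ts.data[:, v], self.design,
                                bounds=self.bounds, n_grid=self.n_grid,
                                hrf=self.hrf)
                for v in idx}
        return PRFResults(self, screened, fits, good_threshold)


class PRFResults:
    """Fitted pRF parameters, their fit quality, and per-digit summaries."""

    def __init__(self, model, screened_mask, fits, good_threshold):
        self.model = model
        self.screened_mask = screened_mask
        self.fits = fits
        self.good_threshold = good_threshold

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for v, f in sorted(self.fits.items()):
            rows.append({"vertex": v, "x": f.params.x, "sigma": f.params.sigma,
                         "gain": f.params.gain, "baseline": f.params.baseline,
                         "R2": f.goodness, "digit": f.assigned_digit,
                         "converged": f.converged})
        return pd.DataFrame(rows, columns=["vertex", "x", "sigma", "gain",
                                           "baseline", "R2", "digit",
                                           "converged"])

    def digit_size_table(self) -> pd.DataFrame:
        return summarize_prf(self.fits.values(), self.good_threshold)

    def summary(self) -> str:
        t = self.table
        lines = ["pRF model fit",
                 "=" * 46,
                 f"vertices screened in : {int(self.screened_mask.sum())}"
                 f" / {len(self.screened_mask)}",
                 f"vertices fitted      : {len(t)}",
                 f"retention threshold  : R2 >= {self.good_threshold}"]
        if len(t):
            kept = t[t.R2 >= self.good_threshold]
            lines.append(f"vertices retained    : {len(kept)}")
            lines.append("")
            lines.append(self.digit_size_table().to_string(index=False,
                                                           float_format="%.3f"))
        return "\n".join(lines)
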