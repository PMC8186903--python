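"""Phase-encoded (travelling-wave) analysis.

A periodic finger sweep concentrates the response of every tuned cortical
vertex at the stimulation frequency; the DFT coefficient at that frequency
carries the response amplitude and, in its angle, the position of the
vertex's preferred finger within the cycle.  This module implements
mirror-run averaging, the stimulus-frequency F-ratio, response amplitude
in percent signal, phase-to-digit assignment, the cross-subject (scalar)
F-ratio, the map-consistency dispersion index, surface cluster filtering,
and winner-take-all digit labeling.

Phase convention: ``phase`` is the *delay phase* in [0, 2pi) — the
fraction of the stimulation cycle at which the vertex's response peaks,
multiplied by 2pi.  On a forward run the delay phase increases from D1 to
D5; on a reverse run it decreases.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist

from .datatypes import CortexPatch, FourierMap, TimeSeriesMatrix
from .geometry import vertex_areas


def average_mirror_runs(forward_ts: TimeSeriesMatrix,
                        reverse_ts: TimeSeriesMatrix,
                        shift_trs: int = 2) -> TimeSeriesMatrix:
    """Average a forward run with the time-reversed reverse run.

    The reverse run is reversed scan-by-scan (which mirrors its digit
    sequence onto the forward order and negates its hemodynamic delay),
    circularly time-shifted by ``shift_trs`` volumes to compensate for
    that delay, and averaged timepoint-wise with the forward run.

    The metadata of the result records the residual phase origin
    ``tr x (shift_trs - 1) / 2`` seconds — the net delay left in the
    averaged series once the opposite hemodynamic delays of the two runs
    have cancelled — which :func:`assign_digits_from_phase` uses as its
    default phase reference.
    """
    if forward_ts.data.shape != reverse_ts.data.shape:
        raise ValueError("forward and reverse runs differ in shape")
    if forward_ts.tr_s != reverse_ts.tr_s:
        raise ValueError("forward and reverse runs differ in TR")
    mirrored = np.roll(reverse_ts.data[::-1], shift_trs, axis=0)
    avg = 0.5 * (forward_ts.data + mirrored)
    meta = dict(forward_ts.meta)
    meta["phase_origin_s"] = forward_ts.tr_s * (shift_trs - 1) / 2.0
    meta["direction"] = "forward"
    return TimeSeriesMatrix(data=avg, tr_s=forward_ts.tr_s, meta=meta)


def fourier_analyze(ts: TimeSeriesMatrix, n_cycles: int,
                    low_freq_cutoff_hz: float = 0.005) -> FourierMap:
    """Stimulus-frequency DFT statistics for every vertex.

    signal = power at the bin of the stimulation frequency; noise = mean
    power over all bins at or above the low-frequency cutoff, excluding
    the signal bin and its 2nd/3rd harmonics.  ``f_ratio`` is their ratio
    (distributed as F(2, 2 x n_noise_bins) under white noise).  The
    response amplitude in percent is the peak-to-peak amplitude of the
    stimulus-frequency component relative to the mean signal level:
    |X_k| x 2 (negative frequencies) x 2 (peak-to-peak) / N / baseline
    x 100.
    """
    data = ts.data
    n, n_vert = data.shape
    if n < 2 * n_cycles:
        raise ValueError("series shorter than two samples per cycle")
    if not 1 <= n_cycles <= n // 2:
        raise ValueError("n_cycles outside the resolvable range")

    baseline = data.mean(axis=0)
    spec = np.fft.rfft(data - baseline, axis=0)
    power = np.abs(spec) ** 2

    freqs = np.fft.rfftfreq(n, d=ts.tr_s)
    noise_bins = np.flatnonzero(freqs >= low_freq_cutoff_hz)
    exclude = {n_cycles, 2 * n_cycles, 3 * n_cycles}
    noise_bins = np.array([b for b in noise_bins if b not in exclude and b > 0])
    if len(noise_bins) == 0:
        raise ValueError("no admissible noise bins; series too short")

    coef = spec[n_cycles]
    signal_power = power[n_cycles]
    noise_power = power[noise_bins].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_ratio = signal_power / noise_power
        amp_pct = np.abs(coef) * 4.0 / n / baseline * 100.0
    # noise-free sinusoid: flagged infinite; zero-variance series: undefined
    pure = noise_power <= signal_power * 1e-12
    f_ratio[pure & (signal_power > 0)] = np.inf
    f_ratio[(signal_power == 0) & (noise_power == 0)] = np.nan
    phase = np.mod(-np.angle(coef), 2.0 * np.pi)

    return FourierMap(coefficient=coef, amplitude_percent=amp_pct, phase=phase,
                      f_ratio=f_ratio, n_cycles=n_cycles,
                      n_noise_bins=len(noise_bins), tr_s=ts.tr_s,
                      meta=dict(ts.meta))


def f_ratio_pvalues(fmap: FourierMap) -> np.ndarray:
    """Per-vertex p-values from the F(2, 2 x n_noise_bins) reference."""
    return f_dist.sf(fmap.f_ratio, 2, 2 * fmap.n_noise_bins)


def hrf_phase_origin_s(hrf: np.ndarray, tr_s: float, cycle_s: float) -> float:
    """Phase origin for a single (non-averaged) run.

    Effective delay of the HRF at the stimulation frequency, minus half a
    TR (the stimulus is sampled at mid-volume while the DFT references
    volume onsets).
    """
    n = max(len(hrf), int(round(cycle_s / tr_s)))
    spec = np.fft.fft(hrf, n=8 * n)
    f0 = 1.0 / cycle_s
    k = int(round(f0 * 8 * n * tr_s))
    lam = -np.angle(spec[k]) / (2 * np.pi * f0)
    return lam - tr_s / 2.0


def assign_digits_from_phase(fmap: FourierMap, direction: str = "forward",
                             hemo_lag_s: float | None = None) -> FourierMap:
    """Bin cycle phase into five equal intervals and label digits.

    The delay phase is converted to a within-cycle time, the hemodynamic
    phase reference is subtracted, and the result is split into five
    equal bins: forward runs map increasing phase to D1..D5, reverse runs
    to D5..D1.  ``hemo_lag_s=None`` uses the ``phase_origin_s`` recorded
    in the map metadata (set by :func:`average_mirror_runs`), falling
    back to 4 s — the nominal hemodynamic delay — when absent.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    cycle_s = fmap.meta.get("cycle_s")
    if cycle_s is None:
        fd = fmap.meta.get("finger_duration_s")
        cycle_s = 5.0 * fd if fd else None
    if cycle_s is None:
        raise ValueError("cycle duration unknown; set meta['cycle_s']")
    if hemo_lag_s is None:
        hemo_lag_s = fmap.meta.get("phase_origin_s", 4.0)

    delay_s = fmap.phase / (2.0 * np.pi) * cycle_s
    tau = np.mod(delay_s - hemo_lag_s, cycle_s)
    if direction == "reverse":
        tau = np.mod(cycle_s - tau, cycle_s)
    digit = np.floor(tau / cycle_s * 5.0).astype(int) + 1
    fmap.assigned_digit = np.clip(digit, 1, 5)
    return fmap


def cross_subject_f_ratio(coefficients) -> float:
    """Scalar cross-subject F-ratio from per-subject complex coefficients.

    Evaluates ``(xav^2 + yav^2) / ([sum((x - xav)^2)/n +
    sum((y - yav)^2)/n] / (2n - 2))`` on the real/imaginary parts, where
    xav/yav are the means over the n subjects.  Zero between-subject
    variance with a nonzero mean is flagged as +inf.
    """
    c = np.asarray(coefficients, complex)
    n = len(c)
    if n < 2:
        raise ValueError("cross-subject F-ratio requires at least 2 subjects")
    x, y = c.real, c.imag
    xav, yav = x.mean(), y.mean()
    num = xav ** 2 + yav ** 2
    denom = (np.sum((x - xav) ** 2) / n + np.sum((y - yav) ** 2) / n) / (2 * n - 2)
    if denom == 0.0:
        return np.inf if num > 0 else np.nan
    return float(num / denom)


def dispersion_index(coefficients) -> float:
    """Map-alignment dispersion index d = |vector mean| / mean |vectors|.

    1.0 for perfectly aligned vectors regardless of amplitude; 0 for
    vectors that cancel.  All-zero input is undefined (NaN).
    """
    c = np.asarray(coefficients, complex)
    denom = np.mean(np.abs(c))
    if denom == 0.0:
        return np.nan
    return float(np.abs(np.mean(c)) / denom)


def _adjacency(patch: CortexPatch) -> sparse.csr_matrix:
    e = patch.edges()
    n = patch.n_vertices
    a = sparse.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    return (a + a.T).tocsr()


def cluster_filter(fmap: FourierMap, patch: CortexPatch,
                   p_threshold: float = 0.01,
                   min_area_mm2: float = 14.0) -> np.ndarray:
    """Surface cluster filter on supra-threshold vertices.

    Vertices with ``p < p_threshold`` (F reference distribution) are
    grouped into edge-connected components; components whose summed
    vertex-wise area falls below ``min_area_mm2`` are discarded.  Returns
    the boolean significance mask (also stored on the map).
    """
    p = f_ratio_pvalues(fmap)
    supra = np.nan_to_num(p, nan=1.0) < p_threshold
    mask = np.zeros(fmap.n_vertices, bool)
    if supra.any():
        adj = _adjacency(patch)[supra][:, supra]
        n_comp, labels = connected_components(adj, directed=False)
        areas = vertex_areas(patch)[supra]
        idx = np.flatnonzero(supra)
        for comp in range(n_comp):
            sel = labels == comp
            if areas[sel].sum() >= min_area_mm2:
                mask[idx[sel]] = True
    fmap.significant = mask
    return mask


def winner_take_all(finger_stat_maps: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Label each vertex by the digit with the maximal statistic.

    ``finger_stat_maps`` is (n_vertices, 5).  Ties resolve to the lowest
    digit index.  Vertices outside ``mask`` get label 0.
    """
    stats = np.asarray(finger_stat_maps, float)
    if stats.ndim != 2 or stats.shape[1] != 5:
        raise ValueError("expected five aligned per-vertex statistic maps")
    labels = np.argmax(stats, axis=1) + 1  # argmax takes the first maximum
    if mask is not None:
        labels = np.where(np.asarray(mask, bool), labels, 0)
    return labels
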