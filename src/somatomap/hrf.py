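"""Canonical double-gamma hemodynamic response function.

The kernel is the community-standard difference of two gamma densities
(response peak near 5-6 s, undershoot near 16 s, peak:undershoot ratio 6),
sampled at the TR and normalized to unit peak so that a neural drive of
amplitude *a* produces a BOLD response of peak amplitude *a*.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma_hrf(tr_s: float, duration_s: float = 32.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     ratio: float = 6.0, oversample: int = 16) -> np.ndarray:
    """Sample the canonical HRF at the TR.

    The continuous kernel is evaluated on a fine grid and averaged within
    each TR so coarse TRs do not alias the early rise.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    dt = tr_s / oversample
    n_tr = int(np.ceil(duration_s / tr_s))
    t = np.arange(n_tr * oversample) * dt
    h = (_gamma.pdf(t, peak_delay, scale=1.0)
         - _gamma.pdf(t, undershoot_delay, scale=1.0) / ratio)
    h = h.reshape(n_tr, oversample).mean(axis=1)
    return h / h.max()


def convolve_hrf(neural: np.ndarray, hrf: np.ndarray,
                 circular: bool = False) -> np.ndarray:
    """Convolve a per-volume neural drive with an HRF kernel.

    ``circular`` treats the drive as periodic over the whole run, which is
    the steady-state limit appropriate for travelling-wave designs (the
    stimulus is strictly periodic, so the cyclic convolution equals the
    response after transients have died out).
    """
    neural = np.asarray(neural, float)
    n = neural.shape[0]
    if circular:
        k = np.zeros(n)
        m = min(n, len(hrf))
        k[:m] += hrf[:m]
        if len(hrf) > n:  # wrap any tail longer than the run
            for i, v in enumerate(hrf[n:]):
                k[i % n] += v
        out = np.fft.irfft(np.fft.rfft(neural, axis=0)
                           * np.fft.rfft(k)[(...,) + (None,) * (neural.ndim - 1)],
                           n=n, axis=0)
        return out
    if neural.ndim == 1:
        return np.convolve(neural, hrf)[:n]
    from scipy.signal import fftconvolve
    return fftconvolve(neural, hrf[:, None], axes=0)[:n]
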