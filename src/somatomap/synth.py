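"""Synthetic-data generators with known ground truth.

Every downstream stage of the package (Fourier mapping, pRF fitting,
geometry, similarity, behavior) can be exercised against data produced
here, where the generating parameters are known exactly.  Defaults follow
the study conditions the pipeline was designed for: a 5-finger
travelling-wave protocol of 20 cycles x 25.6 s (5.12 s per fingertip,
TR 2 s, 256 volumes), a 208-volume blocked design with a 70/30 mix of
2 s / 6 s pauses, 20 mislocalization trials per finger, 3-down/1-up
detection staircases on the Semmes-Weinstein filament ladder, and
two-point discrimination runs with 10 repetitions per pin spacing.

All randomness flows through one ``numpy.random.Generator`` seeded per
call; no global state is touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (DIGIT_CENTERS, STIM_SPACE_HALFWIDTH, BehavioralTrialTable,
                        CortexPatch, StimulusDesign, TimeSeriesMatrix)
from .hrf import convolve_hrf, double_gamma_hrf

#: Semmes-Weinstein monofilament ladder (grams)
FILAMENT_WEIGHTS_G = np.array([0.008, 0.02, 0.04, 0.07, 0.16, 0.4, 0.6,
                               1.0, 1.4, 2.0, 4.0, 6.0])


def filament_log_units(weight_g) -> np.ndarray:
    """Filament weight in log10(0.1 mg) units (1 g = 10,000 x 0.1 mg)."""
    return np.log10(np.asarray(weight_g, float) * 1e4)


# ---------------------------------------------------------------------------
# stimulus designs
# ---------------------------------------------------------------------------

def make_phase_design(direction: str = "forward", n_cycles: int = 20,
                      finger_duration_s: float = 5.12,
                      tr_s: float = 2.0) -> StimulusDesign:
    """Build a travelling-wave (phase-encoded) design.

    One cycle stimulates D1..D5 (forward) or D5..D1 (reverse) for
    ``finger_duration_s`` each; the run is ``n_cycles`` cycles long.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    total_s = 5 * finger_duration_s * n_cycles
    n_vol = total_s / tr_s
    if abs(n_vol - round(n_vol)) > 1e-9:
        raise ValueError(
            f"5 x finger_duration_s ({finger_duration_s}) x n_cycles ({n_cycles}) "
            f"= {total_s} s is not an integer number of TRs ({tr_s} s)")
    n_vol = int(round(n_vol))

    digits = np.arange(1, 6) if direction == "forward" else np.arange(5, 0, -1)
    onsets = []
    for c in range(n_cycles):
        for k, d in enumerate(digits):
            onsets.append((int(d), (c * 5 + k) * finger_duration_s,
                           finger_duration_s))

    mid = (np.arange(n_vol) + 0.5) * tr_s
    epoch = np.floor((mid % (5 * finger_duration_s)) / finger_duration_s).astype(int)
    position = DIGIT_CENTERS[digits[epoch] - 1]

    kind = "phase_forward" if direction == "forward" else "phase_reverse"
    return StimulusDesign(kind=kind, tr_s=tr_s, n_volumes=n_vol,
                          finger_onsets=onsets, stimulus_position=position,
                          meta={"n_cycles": n_cycles,
                                "finger_duration_s": finger_duration_s,
                                "direction": direction})


def _order_without_triples(digits: np.ndarray, rng: np.random.Generator,
                           max_tries: int = 1000) -> np.ndarray:
    """Permute so that no digit appears more than twice consecutively."""
    for _ in range(max_tries):
        perm = rng.permutation(digits)
        run, bad = 1, False
        for a, b in zip(perm[:-1], perm[1:]):
            run = run + 1 if a == b else 1
            if run > 2:
                bad = True
                break
        if not bad:
            return perm
    raise RuntimeError("could not find a digit order without triple repeats "
                       f"in {max_tries} tries")


def make_block_design(n_reps_per_digit: int = 10, p_short_pause: float = 0.7,
                      short_s: float = 2.0, long_s: float = 6.0,
                      stim_s: float = 5.12, tr_s: float = 2.0,
                      seed: int = 0) -> StimulusDesign:
    """Build a blocked design: randomized digit order, mixed pauses.

    Each digit is stimulated ``n_reps_per_digit`` times; a fraction
    ``p_short_pause`` of each digit's trials is followed by the short pause
    and the rest by the long pause (exact per-digit proportions, i.e. the
    pause mix is counterbalanced across fingers).  No digit occurs more
    than twice in a row.
    """
    if n_reps_per_digit < 1:
        raise ValueError("n_reps_per_digit must be positive")
    if not 0.0 <= p_short_pause <= 1.0:
        raise ValueError("p_short_pause must be a probability")
    rng = np.random.default_rng(seed)

    n_short = int(round(p_short_pause * n_reps_per_digit))
    order = _order_without_triples(np.repeat(np.arange(1, 6), n_reps_per_digit), rng)

    # assign pauses per digit: n_short short pauses for each digit, shuffled
    pauses = np.empty(len(order))
    for d in range(1, 6):
        idx = np.flatnonzero(order == d)
        p = np.array([short_s] * n_short + [long_s] * (n_reps_per_digit - n_short))
        pauses[idx] = rng.permutation(p)

    onsets, t = [], 0.0
    for d, pause in zip(order, pauses):
        onsets.append((int(d), t, stim_s))
        t += stim_s + pause
    n_vol = t / tr_s
    if abs(n_vol - round(n_vol)) > 1e-9:
        raise ValueError(f"total duration {t} s is not an integer number of "
                         f"TRs ({tr_s} s); adjust stim/pause durations")
    n_vol = int(round(n_vol))

    mid = (np.arange(n_vol) + 0.5) * tr_s
    position = np.full(n_vol, np.nan)
    for d, onset, dur in onsets:
        position[(mid >= onset) & (mid < onset + dur)] = DIGIT_CENTERS[d - 1]

    return StimulusDesign(kind="block", tr_s=tr_s, n_volumes=n_vol,
                          finger_onsets=onsets, stimulus_position=position,
                          meta={"n_reps_per_digit": n_reps_per_digit,
                                "p_short_pause": p_short_pause, "seed": seed})


def make_rest_design(n_volumes: int = 150, tr_s: float = 2.0) -> StimulusDesign:
    """A resting-state run: no stimulation (default 5 min at TR 2 s)."""
    return StimulusDesign(kind="rest", tr_s=tr_s, n_volumes=n_volumes)


# ---------------------------------------------------------------------------
# cortical patch
# ---------------------------------------------------------------------------

def make_cortex_patch(grid_shape=(10, 10), map_layout: str = "linear_gradient",
                      sigma_range=(1.0, 3.0), gain_range=(1.0, 3.0),
                      baseline: float = 100.0, spacing_mm: float = 1.0,
                      seed: int = 0,
                      preferred_position: np.ndarray | None = None) -> CortexPatch:
    """Triangulated rectangular patch with ground-truth finger tuning.

    ``linear_gradient`` assigns preferred positions monotonically along the
    row axis, spanning the full stimulus space [-12.5, +12.5] — a stand-in
    for the orderly fingertip map in area 3b.  ``custom`` requires
    ``preferred_position`` (one value per vertex).
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    if min(sigma_range) < 0.5:
        raise ValueError("tuning sigma below the 0.5-unit lower bound")
    rng = np.random.default_rng(seed)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    vertices = np.column_stack([rr.ravel() * spacing_mm, cc.ravel() * spacing_mm,
                                np.zeros(rows * cols)])
    faces = []
    for i in range(rows - 1):
        for j in range(cols - 1):
            v00, v01 = i * cols + j, i * cols + j + 1
            v10, v11 = (i + 1) * cols + j, (i + 1) * cols + j + 1
            faces.append((v00, v10, v01))
            faces.append((v01, v10, v11))
    faces = np.array(faces)

    if map_layout == "linear_gradient":
        # row centers span the axis; every vertex in a row shares a position
        row_pos = (np.arange(rows) + 0.5) / rows * 25.0 - STIM_SPACE_HALFWIDTH
        pref = np.repeat(row_pos, cols)
    elif map_layout == "custom":
        if preferred_position is None:
            raise ValueError("custom layout requires preferred_position")
        pref = np.asarray(preferred_position, float)
        if pref.shape != (rows * cols,):
            raise ValueError("preferred_position must have one value per vertex")
    else:
        raise ValueError(f"unknown map_layout {map_layout!r}")

    n = rows * cols
    sigma = rng.uniform(sigma_range[0], sigma_range[1], n)
    gain = rng.uniform(gain_range[0], gain_range[1], n)
    return CortexPatch(vertices=vertices, faces=faces, preferred_position=pref,
                       tuning_sigma=sigma, gain=gain,
                       baseline=np.full(n, float(baseline)))


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def gaussian_response(position: np.ndarray, center: float,
                      sigma: float) -> np.ndarray:
    """1D Gaussian population tuning: exp(-(s - x)^2 / (2 sigma^2)).

    NaN positions (no stimulus on screen) drive zero response.
    """
    out = np.exp(-(position - center) ** 2 / (2.0 * sigma ** 2))
    return np.where(np.isnan(position), 0.0, out)


def simulate_bold(patch: CortexPatch, design: StimulusDesign,
                  noise_sd: float = 0.5, ar1_coef: float = 0.0,
                  seed: int = 0, hrf: np.ndarray | None = None) -> TimeSeriesMatrix:
    """Forward-model BOLD for every vertex of a patch.

    Per vertex, the neural drive is ``gain x exp(-(s(t)-x)^2 / 2 sigma^2)``
    (percent signal units) convolved with the canonical HRF; the series is
    ``baseline x (1 + response/100)`` plus AR(1) Gaussian noise whose
    stationary SD is ``noise_sd`` percent signal.  Travelling-wave designs
    use cyclic convolution (steady-state response to a periodic stimulus);
    blocked designs use linear convolution.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not -1 < ar1_coef < 1:
        raise ValueError("ar1_coef must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    if hrf is None:
        hrf = double_gamma_hrf(design.tr_s)

    n_vol, n_vert = design.n_volumes, patch.n_vertices
    if design.kind == "rest" or design.stimulus_position is None:
        response = np.zeros((n_vol, n_vert))
    else:
        s = design.stimulus_position
        neural = np.empty((n_vol, n_vert))
        for v in range(n_vert):
            neural[:, v] = patch.gain[v] * gaussian_response(
                s, patch.preferred_position[v], patch.tuning_sigma[v])
        circular = design.kind in ("phase_forward", "phase_reverse")
        response = convolve_hrf(neural, hrf, circular=circular)

    noise = rng.standard_normal((n_vol, n_vert)) * noise_sd
    if ar1_coef != 0.0 and noise_sd > 0:
        innov = noise * np.sqrt(1.0 - ar1_coef ** 2)
        noise = np.empty_like(innov)
        noise[0] = innov[0] / np.sqrt(1.0 - ar1_coef ** 2)
        for t in range(1, n_vol):
            noise[t] = ar1_coef * noise[t - 1] + innov[t]

    pct = response + noise
    data = patch.baseline[None, :] * (1.0 + pct / 100.0)
    return TimeSeriesMatrix(data=data, tr_s=design.tr_s,
                            meta={"design_kind": design.kind,
                                  "seed": seed, **design.meta})


def simulate_resting(corr_matrix: np.ndarray, n_volumes: int = 150,
                     n_fingers: int = 5, seed: int = 0) -> TimeSeriesMatrix:
    """Per-finger resting series with a target correlation structure."""
    C = np.asarray(corr_matrix, float)
    if C.shape != (n_fingers, n_fingers):
        raise ValueError("corr_matrix shape does not match n_fingers")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("corr_matrix must be symmetric with unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise ValueError("corr_matrix is not positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_volumes, n_fingers)) @ L.T
    return TimeSeriesMatrix(data=data, tr_s=2.0,
                            meta={"design_kind": "rest", "seed": seed})


# ---------------------------------------------------------------------------
# behavioral simulators
# ---------------------------------------------------------------------------

def simulate_mislocalization(confusion_probs: np.ndarray,
                             n_trials_per_digit: int = 20,
                             seed: int = 0) -> BehavioralTrialTable:
    """Draw 5-AFC finger reports from a row-stochastic confusion model."""
    P = np.asarray(confusion_probs, float)
    if P.shape != (5, 5):
        raise ValueError("confusion_probs must be 5x5")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of confusion_probs must be probabilities summing to 1")
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for d in range(1, 6):
        reports = rng.choice(np.arange(1, 6), size=n_trials_per_digit, p=P[d - 1])
        for r in reports:
            rows.append((d, int(r), trial))
            trial += 1
    df = pd.DataFrame(rows, columns=["stimulated_digit", "reported_digit", "trial"])
    return BehavioralTrialTable(trials=df, n_trials_per_digit=n_trials_per_digit)


class StaircaseResult:
    """Converged estimate and full trial track of a 3-down/1-up run."""

    def __init__(self, threshold_g, threshold_log, converged, track):
        self.threshold_g = threshold_g          # snapped to the filament ladder
        self.threshold_log = threshold_log      # continuous, log10(0.1 mg) units
        self.converged = converged
        self.track = track                      # DataFrame of every trial


def _p_correct(level_log, threshold_log, slope):
    if np.isinf(slope):  # deterministic step observer
        return 1.0 if level_log >= threshold_log else 0.0
    p_detect = 1.0 / (1.0 + np.exp(-slope * (level_log - threshold_log)))
    return 0.5 + 0.5 * p_detect  # 2AFC guessing floor


def simulate_staircase(observer_threshold_g: float = 0.16,
                       psychometric_slope: float = 8.0,
                       start_levels_g=(0.4, 0.02),
                       rule: str = "three_down_one_up", seed: int = 0,
                       max_trials: int = 200) -> StaircaseResult:
    """Simulate two interleaved 3-down/1-up detection staircases.

    Levels move on the discrete Semmes-Weinstein filament ladder; three
    consecutive correct responses step one level down, any incorrect
    response steps one level up.  A staircase stops once the standard
    deviation of the stimulus intensities it visited after its first
    reversal is at most one ladder step; the threshold estimate is the
    mean of those intensities (in log10(0.1 mg) units), snapped to the
    nearest ladder level for the reported weight.  The 3-down/1-up rule
    targets the ~79.4% correct point of the observer.
    """
    if rule != "three_down_one_up":
        raise ValueError("only the three_down_one_up rule is implemented")
    rng = np.random.default_rng(seed)
    ladder_log = filament_log_units(FILAMENT_WEIGHTS_G)
    step = np.mean(np.abs(np.diff(ladder_log)))  # mean ladder step, log units
    thr_log = filament_log_units(observer_threshold_g)

    idx = [int(np.argmin(np.abs(FILAMENT_WEIGHTS_G - s))) for s in start_levels_g]
    streak = [0, 0]
    last_dir = [0, 0]
    reversed_once = [False, False]
    visited: list[list[float]] = [[], []]
    done = [False, False]
    rows = []

    for t in range(max_trials):
        s = t % 2  # alternate staircases
        if done[s]:
            s = 1 - s
            if done[s]:
                break
        lvl = ladder_log[idx[s]]
        correct = rng.random() < _p_correct(lvl, thr_log, psychometric_slope)
        rows.append((t, s, FILAMENT_WEIGHTS_G[idx[s]], lvl, bool(correct)))
        if reversed_once[s]:
            visited[s].append(lvl)

        if correct:
            streak[s] += 1
            if streak[s] == 3:
                streak[s] = 0
                if last_dir[s] == +1:
                    reversed_once[s] = True
                last_dir[s] = -1
                idx[s] = max(idx[s] - 1, 0)
        else:
            streak[s] = 0
            if last_dir[s] == -1:
                reversed_once[s] = True
            last_dir[s] = +1
            idx[s] = min(idx[s] + 1, len(ladder_log) - 1)

        if len(visited[s]) >= 6 and np.std(visited[s]) <= step:
            done[s] = True
        if all(done):
            break

    track = pd.DataFrame(rows, columns=["trial", "staircase", "weight_g",
                                        "log_units", "correct"])
    pooled = visited[0] + visited[1]
    if not pooled:  # never reversed: fall back to all visited levels
        pooled = list(track["log_units"])
    thr_cont = float(np.mean(pooled))
    snapped = float(FILAMENT_WEIGHTS_G[np.argmin(np.abs(ladder_log - thr_cont))])
    return StaircaseResult(threshold_g=snapped, threshold_log=thr_cont,
                           converged=all(done), track=track)


def simulate_2pd(true_threshold_mm: float = 2.5, slope: float = 3.0,
                 pin_distances_mm=None, n_per_distance: int = 10,
                 include_control: bool = False, seed: int = 0) -> pd.DataFrame:
    """Two-point discrimination responses from a logistic observer.

    ``p('two felt') = 1 / (1 + exp(-slope (d - threshold)))``, exactly 0.5
    at the true threshold.  Default pin spacings are 0.7-2.8 mm in 0.3 mm
    steps with 10 repetitions per condition; ``include_control`` adds a
    single-pin condition (distance 0) whose 'two' rate is the lapse floor.
    """
    if pin_distances_mm is None:
        pin_distances_mm = np.arange(0.7, 2.8 + 1e-9, 0.3)
    d = np.asarray(pin_distances_mm, float)
    if np.any(d <= 0):
        raise ValueError("pin distances must be positive")
    if include_control:
        d = np.concatenate([[0.0], d])
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for dist in d:
        if dist == 0.0:
            p = 0.02  # single-pin control: rare 'two' responses
        elif np.isinf(slope):
            p = 1.0 if dist > true_threshold_mm else 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-slope * (dist - true_threshold_mm)))
        for _ in range(n_per_distance):
            rows.append((trial, dist, int(rng.random() < p)))
            trial += 1
    return pd.DataFrame(rows, columns=["trial", "distance_mm", "two_felt"])
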