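"""Core containers shared by all analysis stages.

The stimulus space is a 1D axis spanning [-12.5, +12.5] arbitrary units,
split into five equal 5-unit intervals, one per digit (D1 lowest).  All
containers are plain dataclasses wrapping numpy arrays / pandas frames so
they serialize to text formats without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: half-width of the 1D stimulus axis (units)
STIM_SPACE_HALFWIDTH = 12.5
#: width of the interval occupied by one digit (units)
DIGIT_INTERVAL = 5.0
#: stimulus-space centers of digits D1..D5
DIGIT_CENTERS = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])

DESIGN_KINDS = ("phase_forward", "phase_reverse", "block", "rest")


def digit_of_position(x) -> np.ndarray:
    """Map stimulus-space position(s) to digit labels 1-5 (5-unit bins)."""
    x = np.asarray(x, dtype=float)
    idx = np.floor((x + STIM_SPACE_HALFWIDTH) / DIGIT_INTERVAL).astype(int)
    return np.clip(idx, 0, 4) + 1


@dataclass
class StimulusDesign:
    """Per-volume stimulus state of one fMRI run.

    Attributes
    ----------
    kind : str
        One of ``phase_forward``, ``phase_reverse``, ``block``, ``rest``.
    tr_s : float
        Repetition time in seconds.
    n_volumes : int
    finger_onsets : list of (digit, onset_s, duration_s)
        Stimulation epochs; empty for rest designs.
    stimulus_position : ndarray or None
        Stimulus-space position active in each volume (NaN when nothing
        is presented); None for rest designs.
    """

    kind: str
    tr_s: float
    n_volumes: int
    finger_onsets: list = field(default_factory=list)
    stimulus_position: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.stimulus_position is not None:
            self.stimulus_position = np.asarray(self.stimulus_position, float)
            if self.stimulus_position.shape != (self.n_volumes,):
                raise ValueError("stimulus_position must have one entry per volume")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def frame_times(self) -> np.ndarray:
        """Mid-volume acquisition times in seconds."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr_s

    def digit_indicator(self) -> np.ndarray:
        """(n_volumes, 5) boxcar matrix: volume v had digit d stimulated."""
        out = np.zeros((self.n_volumes, 5))
        mid = self.frame_times
        for digit, onset, dur in self.finger_onsets:
            out[(mid >= onset) & (mid < onset + dur), digit - 1] = 1.0
        return out


@dataclass
class CortexPatch:
    """Triangulated cortical patch with per-vertex ground-truth tuning."""

    vertices: np.ndarray            # (V, 3) mm
    faces: np.ndarray               # (F, 3) int
    preferred_position: np.ndarray  # (V,) stimulus-space units
    tuning_sigma: np.ndarray        # (V,) stimulus-space units, >= 0.5
    gain: np.ndarray                # (V,) % signal change at preferred stimulus
    baseline: np.ndarray            # (V,) raw intensity

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces reference vertices outside the mesh")
        if np.any(self.tuning_sigma < 0.5):
            raise ValueError("tuning_sigma must be >= 0.5 (pRF size lower bound)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2) derived from the faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def true_digit(self) -> np.ndarray:
        return digit_of_position(self.preferred_position)


@dataclass
class TimeSeriesMatrix:
    """Volumes x vertices BOLD matrix with TR metadata."""

    data: np.ndarray  # (n_volumes, n_vertices)
    tr_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class BehavioralTrialTable:
    """Long-format 5-AFC mislocalization trials."""

    trials: pd.DataFrame  # columns: stimulated_digit, reported_digit, trial
    n_trials_per_digit: int = 20

    def __post_init__(self):
        need = {"stimulated_digit", "reported_digit", "trial"}
        if not need.issubset(self.trials.columns):
            raise ValueError(f"trial table needs columns {sorted(need)}")
        for col in ("stimulated_digit", "reported_digit"):
            v = self.trials[col]
            if not v.isin([1, 2, 3, 4, 5]).all():
                raise ValueError(f"{col} outside 1..5")


@dataclass
class FourierMap:
    """Per-vertex stimulus-frequency Fourier statistics."""

    coefficient: np.ndarray        # complex DFT coefficient at the stimulus bin
    amplitude_percent: np.ndarray  # peak-to-peak response amplitude, % of baseline
    phase: np.ndarray              # delay phase in [0, 2pi): fraction of cycle at
                                   # which the response peaks, times 2pi
    f_ratio: np.ndarray            # signal power / mean noise power
    n_cycles: int
    n_noise_bins: int
    tr_s: float
    assigned_digit: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.coefficient)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "vertex": np.arange(self.n_vertices),
            "re": self.coefficient.real,
            "im": self.coefficient.imag,
            "amp_pct": self.amplitude_percent,
            "phase": self.phase,
            "F": self.f_ratio,
        })
        df["digit"] = self.assigned_digit if self.assigned_digit is not None else -1
        df["significant"] = (self.significant if self.significant is not None
                             else np.zeros(self.n_vertices, bool))
        return df


@dataclass
class ConfusionMatrix:
    """5x5 stimulated (rows) x reported (columns) response counts."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (5, 5):
            raise ValueError("confusion matrix must be 5x5")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def trials_per_digit(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def hit_rate(self) -> np.ndarray:
        """Diagonal divided by the number of stimulations of that finger."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.diag(self.counts) / self.trials_per_digit

    @property
    def n_mislocalizations(self) -> float:
        return float(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        digits = [f"D{i}" for i in range(1, 6)]
        return pd.DataFrame(self.counts, index=digits, columns=digits)
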