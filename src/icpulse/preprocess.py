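"""Raw ICP record -> N x 180 matrix of normalized single-beat pulses.

The chain is: zero-phase Butterworth band-pass (0.3-20 Hz) to isolate the
cardiac component, multiscale trough detection (a bounded-scale variant of
the Scholkmann/AMPD multiscale peak detector, run directly on minima) to
find pulse onsets, beat segmentation, and per-beat min-max normalization
with cubic resampling to a fixed 180-point frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

PULSE_LEN = 180
BAND_HZ = (0.3, 20.0)
FILTER_ORDER = 4
#: beat-duration gates, seconds (30-240 bpm; permissive around the 60-80 bpm
#: pulse rates these records typically show)
MIN_BEAT_S = 0.25
MAX_BEAT_S = 2.0


class DegeneratePulseError(ValueError):
    """Raised when a beat is flat (max == min) and cannot be normalized."""


class RecordTooShortError(ValueError):
    """Raised when a record is shorter than the filter warm-up."""


@dataclass
class OnsetDetectorConfig:
    """Multiscale trough detector settings.

    ``L_ms`` is the characteristic duration: the largest comparison scale,
    in milliseconds (default 500, i.e. at least a quarter of a typical beat).
    """
    L_ms: float = 500.0

    def L_samples(self, fs: float) -> int:
        L = int(round(self.L_ms * fs / 1000.0))
        if L < 2:
            raise ValueError("characteristic duration must span >= 2 samples")
        return L


@dataclass
class NormalizedPulse:
    """A single beat mapped to 180 samples in [0, 1], with provenance."""
    values: np.ndarray
    onset_sample: int
    duration_samples: int
    raw_min: float
    raw_max: float

    def norm_index(self, beat_index: int) -> int:
        """Map a sample index within the raw beat to the 180-point frame."""
        return int(round(beat_index * (PULSE_LEN - 1) / (self.duration_samples - 1)))


@dataclass
class PulseMatrix:
    """Temporally ordered normalized pulses; ``array`` gives the N x 180 view."""
    pulses: list[NormalizedPulse] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pulses)

    @property
    def array(self) -> np.ndarray:
        if not self.pulses:
            return np.empty((0, PULSE_LEN))
        return np.stack([p.values for p in self.pulses])

    @property
    def onsets(self) -> np.ndarray:
        return np.array([p.onset_sample for p in self.pulses], dtype=int)


def bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 0.3-20 Hz.

    Applied forward-backward (``sosfiltfilt``) so that subpeak timing is not
    skewed by phase distortion.
    """
    if fs <= 2 * BAND_HZ[1]:
        raise ValueError(f"sampling rate must exceed {2 * BAND_HZ[1]} Hz")
    # warm-up: 3x the time constant of the slow band edge, 1/(2*pi*0.3 Hz)
    if len(x) < 3 * fs / (2 * np.pi * BAND_HZ[0]):
        raise RecordTooShortError("record shorter than band-pass warm-up")
    sos = sps.butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detect_onsets(x: np.ndarray, fs: float,
                  cfg: OnsetDetectorConfig | None = None) -> np.ndarray:
    """Pulse onsets as multiscale troughs of the band-passed signal.

    Builds the local-minima scalogram m(k, i) = 1 iff x[i] < x[i-k] and
    x[i] < x[i+k] for scales k = 1..L, picks the scale lambda with the most
    minima (smallest k on ties), and returns the samples that are minima at
    every scale k <= lambda.  Comparison-only, hence amplitude-scale
    invariant.  A constant signal yields an empty result.
    """
    cfg = cfg or OnsetDetectorConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = min(cfg.L_samples(fs), (n - 1) // 2)
    if L < 1:
        return np.array([], dtype=int)
    counts = np.empty(L, dtype=np.int64)
    all_ok = np.ones(n, dtype=bool)
    all_ok[0] = all_ok[-1] = False
    # running AND over scales, evaluated incrementally so we can stop at the
    # winning scale without storing the full scalogram twice
    m = np.zeros((L, n), dtype=bool)
    for k in range(1, L + 1):
        row = np.zeros(n, dtype=bool)
        row[k:n - k] = (x[k:n - k] < x[:n - 2 * k]) & (x[k:n - k] < x[2 * k:])
        m[k - 1] = row
        counts[k - 1] = int(row.sum())
    if counts.max() == 0:
        return np.array([], dtype=int)
    lam = int(np.argmax(counts)) + 1  # argmax returns the smallest maximizer
    sel = m[:lam].all(axis=0)
    return np.flatnonzero(sel)


def segment(x: np.ndarray, onsets: np.ndarray, fs: float) -> list[tuple[int, np.ndarray]]:
    """Split a record into beats [onset_j, onset_{j+1}).

    Beats outside the 0.25-2 s duration gate are dropped; the tail after the
    last onset is discarded.  Returns (onset_sample, beat_samples) pairs.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) >= 2 and np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    lo, hi = int(np.ceil(MIN_BEAT_S * fs)), int(np.floor(MAX_BEAT_S * fs))
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if lo <= b - a <= hi:
            beats.append((int(a), np.asarray(x[a:b], dtype=float)))
    return beats


def resample_cubic(x: np.ndarray, n_out: int = PULSE_LEN) -> np.ndarray:
    """Piecewise-cubic resampling onto a uniform grid of ``n_out`` points.

    A cubic spline through all samples (not a single global cubic fit, which
    could not represent three subpeaks).  Resampling a grid onto itself is
    the identity.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == n_out:
        return x.copy()
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, n_out)
    return CubicSpline(src, x)(dst)


def normalize(beat: np.ndarray, onset_sample: int = 0) -> NormalizedPulse:
    """Min-max normalize a beat to [0, 1] and resample it to 180 points."""
    beat = np.asarray(beat, dtype=float)
    if len(beat) < 4:
        raise ValueError("beat too short to resample")
    lo, hi = float(beat.min()), float(beat.max())
    if hi <= lo:
        raise DegeneratePulseError("flat beat cannot be normalized")
    values = resample_cubic((beat - lo) / (hi - lo))
    return NormalizedPulse(values=values, onset_sample=int(onset_sample),
                           duration_samples=len(beat), raw_min=lo, raw_max=hi)


def extract_pulses(x: np.ndarray, fs: float,
                   cfg: OnsetDetectorConfig | None = None) -> PulseMatrix:
    """Full preprocessing chain: band-pass, onset detection, segmentation,
    normalization.  Flat beats are silently dropped."""
    filtered = bandpass(x, fs)
    onsets = detect_onsets(filtered, fs, cfg)
    matrix = PulseMatrix()
    for onset, beat in segment(x, onsets, fs):
        try:
            matrix.pulses.append(normalize(beat, onset))
        except DegeneratePulseError:
            continue
    return matrix


class PulseExtractor:
    """Transformer-style wrapper: ``transform(record)`` -> PulseMatrix."""

    def __init__(self, fs: float = 100.0, L_ms: float = 500.0):
        self.fs = fs
        self.L_ms = L_ms

    def fit(self, X=None, y=None):
        return self

    def transform(self, x: np.ndarray) -> PulseMatrix:
        return extract_pulses(x, self.fs, OnsetDetectorConfig(L_ms=self.L_ms))
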