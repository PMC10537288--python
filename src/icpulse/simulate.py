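"""Synthetic 100 Hz ICP records with per-pulse ground truth.

Each heartbeat-induced pulse is modelled as a sum of up to three Gaussian
bumps (the P1/P2/P3 subpeaks) on a flat baseline; beats are concatenated at
a configurable heart rate with per-beat period jitter, then an additive
respiratory sinusoid, a low-frequency baseline drift and broadband noise are
superimposed.  ``degrade`` injects artifact beats (spikes, flat segments,
damped noise) and beats lacking a distinct P1 or P2, flagged non-calculable.

Ground-truth subpeak positions are re-derived from the local maxima of the
rendered noiseless beat, not read off the template parameters: overlapping
Gaussians shift the apexes, and the labels must match what a perfect
detector could recover.  The ground-truth P2/P1 ratio is the quotient of the
min-max-normalized beat at those apexes, so it is exact by construction.

Respiration (default 0.25 Hz) and drift (< 0.1 Hz) both lie outside the
0.3-20 Hz analysis band, so the preprocessing filter can be validated
against them.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import PULSE_LEN, resample_cubic

#: sentinel label pair for pulses without a calculable P2/P1 ratio
SENTINEL = (0, 0)

TRUTH_COLUMNS = ["pulse_id", "onset_sample", "n_samples", "p1_sample",
                 "p2_sample", "p1_norm_idx", "p2_norm_idx", "true_ratio",
                 "calculable"]


@dataclass(frozen=True)
class PulseTemplate:
    """Morphology of one beat: three Gaussian subpeaks on a baseline.

    ``positions`` and ``widths`` are fractions of the beat duration;
    ``amplitudes`` are in the record's pressure units (mmHg-like).
    """
    amplitudes: tuple[float, float, float] = (1.0, 0.8, 0.5)
    positions: tuple[float, float, float] = (0.22, 0.44, 0.67)
    widths: tuple[float, float, float] = (0.07, 0.07, 0.07)
    baseline: float = 0.0

    def __post_init__(self):
        a, p, w = self.amplitudes, self.positions, self.widths
        if any(x < 0 for x in a) or not any(x > 0 for x in a):
            raise ValueError("need nonnegative amplitudes, at least one > 0")
        if not (p[0] < p[1] < p[2]):
            raise ValueError("subpeak positions must be strictly increasing")
        if any(x <= 0 for x in w):
            raise ValueError("subpeak widths must be positive")


@dataclass
class RecordConfig:
    """Synthetic record settings (defaults emulate a quiet adult ICU record).

    ``ratio_trajectory`` maps time in seconds to the target P2/P1 ratio of
    the beat starting at that time (None: constant 0.8).  ``hr_jitter`` is
    the coefficient of variation of the beat period.
    """
    duration_s: float = 60.0
    fs: float = 100.0
    heart_rate_bpm: float = 70.0
    hr_jitter: float = 0.0
    resp_freq_hz: float = 0.25
    resp_amp: float = 0.0
    drift_amp: float = 0.0
    noise_sd: float = 0.0
    artifact_rate: float = 0.0
    missing_subpeak_rate: float = 0.0
    ratio_trajectory: Callable[[float], float] | None = None
    baseline_mmhg: float = 10.0
    pulse_amp: float = 4.0
    #: fixed beat morphology; None draws subpeak positions/widths once per
    #: record from the same distribution as random_template, emulating
    #: between-patient variability
    template: PulseTemplate | None = None
    #: rectified-sine diastolic filling per beat; gives each beat a distinct
    #: V-shaped trough at its boundary, as on real ICP pulses
    diastolic_amp: float = 1.0
    #: correct the P2 amplitude so the rendered beat realizes the ratio
    #: trajectory; False sets subpeak amplitudes directly from the target
    calibrate_ratio: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.fs <= 40.0:
            raise ValueError("sampling rate must exceed twice the 20 Hz band edge")
        if not 40 <= self.heart_rate_bpm <= 140:
            raise ValueError("heart rate must lie in [40, 140] bpm")
        for name in ("hr_jitter", "resp_freq_hz", "resp_amp", "drift_amp",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("artifact_rate", "missing_subpeak_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_pulse(template: PulseTemplate, n_samples: int) -> np.ndarray:
    """Render one noiseless beat of ``n_samples`` points."""
    if n_samples < 20:
        raise ValueError("a beat needs at least 20 samples")
    t = np.arange(n_samples) / n_samples
    w = np.full(n_samples, float(template.baseline))
    for a, p, s in zip(template.amplitudes, template.positions, template.widths):
        if a > 0:
            w += a * np.exp(-((t - p) ** 2) / (2 * s ** 2))
    return w


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict interior local maxima (plateaus contribute their left edge)."""
    idx = sps.argrelextrema(x, np.greater_equal, order=1)[0]
    out = []
    for i in idx:
        if 0 < i < len(x) - 1 and x[i] > x[i - 1] and x[i] >= x[i + 1]:
            out.append(i)
    return np.array(out, dtype=int)


def pulse_landmarks(template: PulseTemplate, n_samples: int,
                    waveform: np.ndarray | None = None):
    """Ground truth for one rendered beat.

    Returns (p1_idx, p2_idx, ratio, calculable) in beat-sample coordinates.
    The apex of each configured subpeak is the local maximum of the rendered
    noiseless waveform nearest its configured position; the ratio is taken
    on the min-max-normalized waveform at those apexes.  The beat is
    calculable iff the first two subpeaks have positive amplitude and map to
    two distinct apexes.  ``waveform`` overrides the rendered beat when the
    caller has added further noiseless components.
    """
    w = make_pulse(template, n_samples) if waveform is None else waveform
    maxima = _local_maxima(w)
    if len(maxima) == 0:
        return None, None, np.nan, False
    apexes = []
    for a, p in zip(template.amplitudes[:2], template.positions[:2]):
        if a <= 0:
            apexes.append(None)
        else:
            apexes.append(int(maxima[np.argmin(np.abs(maxima - p * n_samples))]))
    p1, p2 = apexes
    if p1 is None or p2 is None or p1 >= p2:
        return p1, p2, np.nan, False
    wn = (w - w.min()) / (w.max() - w.min())
    if wn[p1] <= 0:
        return p1, p2, np.nan, False
    return p1, p2, float(wn[p2] / wn[p1]), True


def _norm_index(beat_index: int, n_samples: int) -> int:
    return int(round(beat_index * (PULSE_LEN - 1) / (n_samples - 1)))


def _template_for_ratio(ratio: float, base: PulseTemplate,
                        pulse_amp: float) -> PulseTemplate:
    """Template whose second subpeak targets the requested P2/P1 ratio."""
    a1 = pulse_amp
    return replace(base, amplitudes=(a1, ratio * a1, 0.5 * min(1.0, ratio) * a1))


def _random_geometry(rng: np.random.Generator) -> PulseTemplate:
    """Subpeak positions/widths drawn as in :func:`random_template`."""
    p1 = rng.uniform(0.15, 0.30)
    p2 = p1 + rng.uniform(0.18, 0.30)
    p3 = min(p2 + rng.uniform(0.14, 0.25), 0.88)
    widths = tuple(rng.uniform(0.04, 0.07, size=3))
    return PulseTemplate(positions=(p1, p2, p3), widths=widths)


def generate_record(config: RecordConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a synthetic record and its per-beat ground-truth table.

    Deterministic for a fixed config (including seed).  The truth table has
    columns TRUTH_COLUMNS; raw-coordinate labels are -1 and normalized-frame
    labels the (0, 0) sentinel for non-calculable beats.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = int(round(cfg.duration_s * cfg.fs))
    mean_period = 60.0 / cfg.heart_rate_bpm
    if cfg.duration_s < mean_period:
        raise ValueError("record shorter than one beat")
    base = cfg.template if cfg.template is not None else _random_geometry(rng)
    traj = cfg.ratio_trajectory or (lambda t: 0.8)

    def beat_wave(tmpl: PulseTemplate, n: int) -> np.ndarray:
        w = make_pulse(tmpl, n)
        if cfg.diastolic_amp > 0:
            tt = np.arange(n) / n
            w = w + cfg.diastolic_amp * np.abs(np.sin(np.pi * tt))
        return w

    def calibrated_beat(target: float, n: int):
        """Template realizing ``target`` on the rendered beat: the additive
        diastolic filling and subpeak overlap shift the realized ratio, so
        the P2 amplitude is corrected by two fixed-point iterations."""
        tmpl = _template_for_ratio(target, base, cfg.pulse_amp)
        if not cfg.calibrate_ratio:
            return tmpl, beat_wave(tmpl, n)
        for _ in range(2):
            wave = beat_wave(tmpl, n)
            _, _, realized, calc = pulse_landmarks(tmpl, n, waveform=wave)
            if not calc or not np.isfinite(realized) or realized <= 0:
                break
            a1, a2, a3 = tmpl.amplitudes
            a2 = float(np.clip(a2 * target / realized, 0.05 * a1, 3.0 * a1))
            tmpl = replace(tmpl, amplitudes=(a1, a2, a3))
        return tmpl, beat_wave(tmpl, n)

    signal = np.full(n_total, float(cfg.baseline_mmhg))
    rows = []
    onset = 0
    pulse_id = 0
    while True:
        period = mean_period
        if cfg.hr_jitter > 0:
            period *= max(0.3, 1.0 + cfg.hr_jitter * rng.standard_normal())
        n_beat = int(round(period * cfg.fs))
        if onset + n_beat > n_total:
            # fill the partial tail with an unlabeled truncated beat
            if onset < n_total:
                _, wave = calibrated_beat(traj(onset / cfg.fs), n_beat)
                signal[onset:] += wave[:n_total - onset]
            break
        tmpl, wave = calibrated_beat(traj(onset / cfg.fs), n_beat)
        signal[onset:onset + n_beat] += wave
        p1, p2, ratio, calc = pulse_landmarks(tmpl, n_beat, waveform=wave)
        rows.append({
            "pulse_id": pulse_id,
            "onset_sample": onset,
            "n_samples": n_beat,
            "p1_sample": onset + p1 if calc else -1,
            "p2_sample": onset + p2 if calc else -1,
            "p1_norm_idx": _norm_index(p1, n_beat) if calc else SENTINEL[0],
            "p2_norm_idx": _norm_index(p2, n_beat) if calc else SENTINEL[1],
            "true_ratio": ratio,
            "calculable": calc,
        })
        onset += n_beat
        pulse_id += 1

    t = np.arange(n_total) / cfg.fs
    if cfg.resp_amp > 0:
        signal = signal + cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq_hz * t)
    if cfg.drift_amp > 0:
        walk = np.cumsum(rng.standard_normal(n_total))
        sos = sps.butter(2, 0.1, btype="lowpass", fs=cfg.fs, output="sos")
        walk = sps.sosfiltfilt(sos, walk)
        sd = walk.std()
        if sd > 0:
            signal = signal + cfg.drift_amp * (walk - walk.mean()) / sd
    if cfg.noise_sd > 0:
        signal = signal + cfg.noise_sd * rng.standard_normal(n_total)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if len(truth) == 0:
        raise ValueError("record shorter than one beat")
    signal, truth = degrade(signal, truth, cfg.artifact_rate,
                            cfg.missing_subpeak_rate,
                            seed=int(rng.integers(2 ** 31)))
    return signal, truth


def _artifact_beat(n: int, level: float, kind: int,
                   rng: np.random.Generator) -> np.ndarray:
    """One of three artifact shapes: spike, flat segment, damped noise."""
    if kind == 0:  # sharp movement spike
        beat = np.full(n, level)
        center = rng.integers(n // 4, 3 * n // 4)
        width = max(1, n // 20)
        beat += 8.0 * np.exp(-((np.arange(n) - center) ** 2) / (2 * width ** 2))
        return beat
    if kind == 1:  # flat (sensor saturation / disconnection)
        return np.full(n, level)
    decay = np.exp(-np.arange(n) / (n / 3))  # damped electronic noise
    return level + 3.0 * decay * rng.standard_normal(n)


def degrade(signal: np.ndarray, truth: pd.DataFrame, artifact_rate: float,
            missing_subpeak_rate: float, seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Replace random beats with artifacts or missing-subpeak morphologies.

    Affected beats become non-calculable: raw labels -1, normalized labels
    the (0, 0) sentinel, ratio NaN.  With both rates zero the inputs are
    returned unchanged.
    """
    if not 0 <= artifact_rate <= 1 or not 0 <= missing_subpeak_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if artifact_rate == 0 and missing_subpeak_rate == 0:
        return signal, truth
    rng = np.random.default_rng(seed)
    signal = signal.copy()
    truth = truth.copy()
    for j in truth.index:
        u = rng.random()
        onset = int(truth.at[j, "onset_sample"])
        n = int(truth.at[j, "n_samples"])
        level = float(signal[onset])
        if u < artifact_rate:
            signal[onset:onset + n] = _artifact_beat(
                n, level, int(rng.integers(3)), rng)
        elif u < artifact_rate + missing_subpeak_rate:
            # beat with no distinct P1/P2: single bump or fully merged pair
            if rng.random() < 0.5:
                tmpl = PulseTemplate(amplitudes=(4.0, 0.0, 0.0),
                                     widths=(0.12, 0.07, 0.07))
            else:
                tmpl = PulseTemplate(amplitudes=(4.0, 3.6, 0.0),
                                     positions=(0.38, 0.44, 0.67),
                                     widths=(0.16, 0.16, 0.07))
            signal[onset:onset + n] = level + make_pulse(tmpl, n)
        else:
            continue
        truth.loc[j, ["p1_sample", "p2_sample"]] = -1
        truth.loc[j, ["p1_norm_idx", "p2_norm_idx"]] = SENTINEL
        truth.at[j, "true_ratio"] = np.nan
        truth.at[j, "calculable"] = False
    return signal, truth


# ---------------------------------------------------------------------------
# Labeled pulse datasets (already in the 180-point normalized frame)

def generate_pulse_dataset(n_pulses: int, seed: int, *,
                           ratio_range: tuple[float, float] = (0.6, 1.4),
                           noncalculable_fraction: float = 0.1,
                           noise_sd: float = 0.03,
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Random labeled pulses for training/evaluating the neural stages.

    Each pulse is rendered at a random beat length (70-130 samples, i.e.
    46-86 bpm at 100 Hz) from a randomized three-subpeak template whose P2/P1
    ratio is drawn from ``ratio_range``, corrupted with additive band-limited
    noise of standard deviation ``noise_sd`` (relative to unit pulse
    amplitude; see :func:`_bandlimited_noise`), then
    min-max normalized and cubically resampled to 180 points.  A fraction of
    pulses is non-calculable: single-subpeak, merged-subpeak, noise or spike
    shapes, labeled with the (0, 0) sentinel.

    Returns (X, labels) with X of shape (n_pulses, 180) and labels columns
    (p1, p2, true_ratio, calculable); p1/p2 are in the 180-point frame.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n_pulses, PULSE_LEN))
    rows = []
    for i in range(n_pulses):
        n_beat = int(rng.integers(70, 131))
        if rng.random() < noncalculable_fraction:
            beat, row = _noncalculable_beat(n_beat, rng)
        else:
            beat, row = _calculable_beat(n_beat, ratio_range, rng)
        if noise_sd > 0:
            beat = beat + _bandlimited_noise(len(beat), noise_sd, rng)
        lo, hi = beat.min(), beat.max()
        if hi <= lo:  # pathological flat draw; replace with pure noise
            beat = rng.standard_normal(n_beat)
            row = {"p1": 0, "p2": 0, "true_ratio": np.nan, "calculable": False}
            lo, hi = beat.min(), beat.max()
        X[i] = resample_cubic((beat - lo) / (hi - lo))
        rows.append(row)
    labels = pd.DataFrame(rows)
    labels.index.name = "pulse_id"
    return X, labels


def _bandlimited_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Noise low-passed at the 20 Hz analysis-band edge (fs 100), rescaled
    to standard deviation ``sd``.

    Pulses reaching the neural stages of the real pipeline have passed the
    0.3-20 Hz band-pass, so the corruption on dataset pulses must not
    contain out-of-band power the filter would have removed.
    """
    sos = sps.butter(4, 20.0, btype="lowpass", fs=100.0, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = z.std()
    return z * (sd / s) if s > 0 else z


def random_template(rng: np.random.Generator,
                    ratio_range: tuple[float, float] = (0.6, 1.4),
                    ) -> PulseTemplate:
    """Random plausible three-subpeak template with target ratio in range.

    Subpeak spacings and widths are drawn so the subpeaks stay visibly
    distinct — the defining property of a calculable pulse; beats with
    merged subpeaks belong to the non-calculable class instead.
    """
    geom = _random_geometry(rng)
    ratio = rng.uniform(*ratio_range)
    a3 = rng.uniform(0.3, 0.6) * min(1.0, ratio)
    return replace(geom, amplitudes=(1.0, ratio, a3))


def _calculable_beat(n_beat, ratio_range, rng):
    for _ in range(20):
        tmpl = random_template(rng, ratio_range)
        # diastolic filling as on full records (relative to unit amplitude)
        dia = rng.uniform(0.1, 0.4)
        tt = np.arange(n_beat) / n_beat
        wave = make_pulse(tmpl, n_beat) + dia * np.abs(np.sin(np.pi * tt))
        p1, p2, ratio, calc = pulse_landmarks(tmpl, n_beat, waveform=wave)
        if calc:
            return wave, {
                "p1": _norm_index(p1, n_beat), "p2": _norm_index(p2, n_beat),
                "true_ratio": ratio, "calculable": True}
    raise RuntimeError("could not draw a calculable template")  # pragma: no cover


def _noncalculable_beat(n_beat, rng):
    kind = int(rng.integers(4))
    if kind == 0:  # single subpeak
        tmpl = PulseTemplate(amplitudes=(1.0, 0.0, 0.0),
                             widths=(rng.uniform(0.08, 0.16),) * 3)
        beat = make_pulse(tmpl, n_beat)
    elif kind == 1:  # merged P1/P2
        w = rng.uniform(0.13, 0.2)
        tmpl = PulseTemplate(amplitudes=(1.0, rng.uniform(0.85, 1.1), 0.0),
                             positions=(0.35, 0.45, 0.7), widths=(w, w, w))
        beat = make_pulse(tmpl, n_beat)
    elif kind == 2:  # broadband noise artifact
        beat = 0.4 * rng.standard_normal(n_beat)
    else:  # isolated spike
        beat = _artifact_beat(n_beat, 0.0, 0, rng)
    return beat, {"p1": 0, "p2": 0, "true_ratio": np.nan, "calculable": False}


# ---------------------------------------------------------------------------
# Text I/O (two-column record; delimited truth table)

def write_record(path, signal: np.ndarray, fs: float) -> None:
    t = np.arange(len(signal)) / fs
    df = pd.DataFrame({"time_s": t, "icp": signal})
    df.to_csv(path, index=False, float_format="%.6f")


def read_record(path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return df["icp"].to_numpy(), float(round(fs, 6))


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path)
    truth["calculable"] = truth["calculable"].astype(bool)
    return truth
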