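"""End-to-end framework: raw ICP record in, smoothed P2/P1 series out.

Composition order: band-pass -> onset detection -> segmentation ->
normalization -> pulse selection -> (curvature candidates ->) subpeak
designation -> P2/P1 ratio -> sliding-window smoothing.  Pulses the
selector rejects, and selected pulses on which designation fails (fewer
than two candidates), yield missing raw ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curvature import candidates
from .designation import SubpeakDesignator
from .postprocess import SmoothingConfig, displayed_fraction, smooth
from .preprocess import OnsetDetectorConfig, extract_pulses
from .selection import PulseSelector, select_pulses

log = logging.getLogger("icpulse")


@dataclass
class PipelineConfig:
    """Settings of the assembled framework."""
    threshold: float = 0.5
    mode: str = "curvature"
    onset: OnsetDetectorConfig = field(default_factory=OnsetDetectorConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("decision threshold must be finite")


@dataclass
class FrameworkOutput:
    """Per-pulse table plus the smoothed display series (same length)."""
    per_pulse: pd.DataFrame  # pulse_id, onset_sample, onset_time_s, selected,
    #                          i1, i2, ratio (NaN = missing), smoothed
    fs: float

    @property
    def smoothed(self) -> np.ndarray:
        return self.per_pulse["smoothed"].to_numpy()

    @property
    def displayed_fraction(self) -> float:
        return displayed_fraction(self.smoothed)

    @property
    def ratio_associated_fraction(self) -> float:
        return float(np.mean(~np.isnan(self.per_pulse["ratio"].to_numpy())))


def run_framework(signal: np.ndarray, fs: float, selector: PulseSelector,
                  designator: SubpeakDesignator,
                  config: PipelineConfig | None = None) -> FrameworkOutput:
    """Run the full automated P2/P1 framework on one record."""
    cfg = config or PipelineConfig()
    designator.mode = cfg.mode
    matrix = extract_pulses(signal, fs, cfg.onset)
    if len(matrix) == 0:
        raise ValueError("no heartbeat pulses detected in the record")
    X = matrix.array
    log.info("extracted %d pulses from %.1f s record", len(matrix),
             len(signal) / fs)

    mask = select_pulses(selector, X, cfg.threshold)
    log.info("selection kept %d/%d pulses (threshold %.3f)",
             int(mask.sum()), len(mask), cfg.threshold)

    scores = designator.predict(X[mask]) if mask.any() else np.empty((0, 180))
    rows = []
    k = 0
    for i, pulse in enumerate(matrix.pulses):
        row = {"pulse_id": i, "onset_sample": pulse.onset_sample,
               "onset_time_s": pulse.onset_sample / fs,
               "selected": bool(mask[i]), "i1": -1, "i2": -1,
               "ratio": np.nan}
        if mask[i]:
            cands = candidates(pulse.values) if cfg.mode == "curvature" else None
            res = designator.designate(pulse.values, cands=cands,
                                       scores=scores[k])
            k += 1
            if res is not None:
                row.update(i1=res.i1, i2=res.i2, ratio=res.ratio)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["smoothed"] = smooth(table["ratio"].to_numpy(), cfg.smoothing)
    out = FrameworkOutput(per_pulse=table, fs=fs)
    log.info("ratio assigned to %.1f%% of pulses; displayed time %.1f%%",
             100 * out.ratio_associated_fraction, 100 * out.displayed_fraction)
    return out


def match_truth(per_pulse: pd.DataFrame, truth: pd.DataFrame,
                tol_samples: int = 15) -> pd.DataFrame:
    """Align detected pulses with ground-truth beats by onset proximity.

    Each detected pulse is matched to the nearest true onset within
    ``tol_samples``; unmatched pulses are dropped.  Returns the merged
    table with truth columns suffixed ``_true``.
    """
    t_onsets = truth["onset_sample"].to_numpy()
    rows = []
    for _, row in per_pulse.iterrows():
        j = int(np.argmin(np.abs(t_onsets - row["onset_sample"])))
        if abs(t_onsets[j] - row["onset_sample"]) <= tol_samples:
            merged = row.to_dict()
            for col in ("p1_norm_idx", "p2_norm_idx", "true_ratio",
                        "calculable"):
                merged[col + "_true"] = truth.iloc[j][col]
            rows.append(merged)
    return pd.DataFrame(rows)
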