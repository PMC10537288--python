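"""Sliding-window smoothing of the per-pulse P2/P1 ratio series.

Raw per-pulse ratios are noisy, gappy (rejected pulses are missing) and
occasionally grossly wrong (false-positive pulses reaching the designator).
For display, each pulse is assigned the mean of the trailing 100-pulse
window after discarding values outside a 95% normal confidence band, and
only if at least 50 window values are non-missing — otherwise the displayed
value is missing.  At 60-80 bpm the window spans roughly a minute, which is
also the display delay this causal smoothing introduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SmoothingConfig:
    """Trailing-window smoother settings.

    ``window``: pulses per window; ``min_valid``: minimum non-missing values
    required to display; ``ci_level``: two-sided normal confidence level for
    outlier exclusion (0.95 -> +/- 1.96 sample standard deviations).
    """
    window: int = 100
    min_valid: int = 50
    ci_level: float = 0.95

    def __post_init__(self):
        if not 0 < self.min_valid <= self.window:
            raise ValueError("need 0 < min_valid <= window")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.ci_level / 2.0))


def smooth(values: np.ndarray, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Smoothed display series; missing entries are NaN.

    For each pulse t with a full trailing window [t-window+1, t]: if fewer
    than ``min_valid`` window values are non-missing the output is missing;
    otherwise values outside mean +/- z * sd (sample sd, one pass, computed
    on the raw non-missing window) are discarded and the mean of the
    retained values is output.  Pulses before the first full window are
    missing.  Causal: output at t depends only on pulses <= t.
    """
    cfg = cfg or SmoothingConfig()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty ratio series")
    out = np.full(len(x), np.nan)
    z = cfg.z
    for t in range(cfg.window - 1, len(x)):
        win = x[t - cfg.window + 1:t + 1]
        valid = win[~np.isnan(win)]
        if len(valid) < cfg.min_valid:
            continue
        if len(valid) >= 2:
            m = valid.mean()
            s = valid.std(ddof=1)
            kept = valid[np.abs(valid - m) <= z * s]
            # an all-equal window has s == 0 and keeps everything
            if len(kept) == 0:  # pragma: no cover - kept nonempty by construction
                kept = valid
        else:
            kept = valid
        out[t] = kept.mean()
    return out


def displayed_fraction(values: np.ndarray) -> float:
    """Fraction of non-missing entries in a (smoothed) ratio series."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty ratio series")
    return float(np.mean(~np.isnan(x)))


class RatioSmoother:
    """Transformer-style wrapper around :func:`smooth`."""

    def __init__(self, window: int = 100, min_valid: int = 50,
                 ci_level: float = 0.95):
        self.window = window
        self.min_valid = min_valid
        self.ci_level = ci_level

    def fit(self, X=None, y=None):
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return smooth(values, SmoothingConfig(self.window, self.min_valid,
                                              self.ci_level))


def smooth_series(series: pd.DataFrame, cfg: SmoothingConfig | None = None,
                  value_col: str = "ratio") -> pd.DataFrame:
    """Smooth a per-pulse table in place of its ratio column.

    The input must have strictly increasing ``pulse_id``; the output carries
    the same pulse_ids with a ``smoothed`` column added.
    """
    ids = series["pulse_id"].to_numpy()
    if np.any(np.diff(ids) <= 0):
        raise ValueError("pulse_ids must be strictly increasing")
    out = series.copy()
    out["smoothed"] = smooth(series[value_col].to_numpy(), cfg)
    return out
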