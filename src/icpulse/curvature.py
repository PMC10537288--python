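"""Pulse curvature and candidate-subpeak detection.

The curvature of a sampled pulse p is kappa(p) = p'' / (1 + p'^2)^{3/2},
with derivatives taken by central finite differences on the unit-spaced
180-point index grid (one-sided at the ends).  P1 and P2 lie at local
minima of kappa(p) inside concave zones (p'' < 0) — equivalently at local
maxima of kappa(-p) — so the candidate set is exactly those maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: moving-average width applied before differentiation: second differences
#: amplify interpolation noise, and 5 samples is well below subpeak spacing
SMOOTH_WIDTH = 5


@dataclass
class CandidateSet:
    """Strictly increasing candidate indices with their kappa(-p) values."""
    indices: np.ndarray
    curvature_values: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def kappa(series: np.ndarray) -> np.ndarray:
    """Curvature x'' / (1 + x'^2)^(3/2) on the sample-index grid."""
    x = np.asarray(series, dtype=float)
    if len(x) < 5:
        raise ValueError("series too short for curvature estimation")
    d1 = np.gradient(x)
    d2 = np.gradient(d1)
    return d2 / (1.0 + d1 ** 2) ** 1.5


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge-replicated padding."""
    half = width // 2
    xp = np.pad(x, half, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(xp, kernel, mode="valid")


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior strict local maxima; a plateau contributes its left edge."""
    out = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(out, dtype=int)


def candidates(pulse_values: np.ndarray,
               smooth_width: int = SMOOTH_WIDTH) -> CandidateSet:
    """Candidate subpeaks of a normalized pulse.

    Local maxima of the curvature of the negated (lightly smoothed) pulse,
    restricted to samples where the smoothed second derivative is negative;
    the endpoints, and the half-window margin where the smoother's edge
    padding distorts the derivatives, are excluded.  The set may be empty
    (e.g. a strictly convex pulse has no concave zone).
    """
    p = np.asarray(pulse_values, dtype=float)
    s = _moving_average(p, smooth_width) if smooth_width > 1 else p
    d1 = np.gradient(s)
    d2 = np.gradient(d1)
    # kappa(-p): (-p)'' / (1 + p'^2)^(3/2)
    k_neg = -d2 / (1.0 + d1 ** 2) ** 1.5
    idx = local_maxima(k_neg)
    # concavity gate with a tolerance proportional to the pulse range, so
    # float rounding on piecewise-linear segments cannot fake concavity
    tol = 1e-10 * max(float(np.ptp(p)), 1e-12)
    idx = idx[d2[idx] < -tol]
    margin = smooth_width // 2 + 1
    idx = idx[(idx >= margin) & (idx <= len(p) - 1 - margin)]
    return CandidateSet(indices=idx, curvature_values=k_neg[idx])
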