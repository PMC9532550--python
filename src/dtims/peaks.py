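"""Peak metrology on arrival-time spectra.

Apex times are refined by parabolic interpolation through the three samples
around the discrete maximum; half-maximum crossings are located by linear
interpolation on each flank.  Resolution is R = t_d / t_fwhm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .exceptions import ParameterError, TruncatedPeakError
from .solver import Spectrum
from .theory import PeakSummary

__all__ = ["PeakSet", "measure_fwhm", "find_peaks", "enhancement_ratio"]


@dataclass
class PeakSet:
    """Detected peaks ordered by apex time."""

    peaks: List[PeakSummary] = field(default_factory=list)
    prominence_threshold: float = 0.05

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex (time, height) from a parabola through samples i-1, i, i+1."""
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
    return float(t[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def _cross_left(t, y, i, half, lo=0):
    """Time where y rises through `half` scanning left from apex index i."""
    for j in range(i, lo, -1):
        if y[j - 1] <= half <= y[j]:
            if y[j] == y[j - 1]:
                return float(t[j - 1])
            frac = (half - y[j - 1]) / (y[j] - y[j - 1])
            return float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return None


def _cross_right(t, y, i, half, hi=None):
    hi = len(y) - 1 if hi is None else hi
    for j in range(i, hi):
        if y[j] >= half >= y[j + 1]:
            if y[j] == y[j + 1]:
                return float(t[j + 1])
            frac = (y[j] - half) / (y[j] - y[j + 1])
            return float(t[j] + frac * (t[j + 1] - t[j]))
    return None


def measure_fwhm(spectrum: Spectrum) -> PeakSummary:
    """Apex time, interpolated FWHM, and resolution of the dominant peak.

    The global maximum must be an interior sample with both half-maximum
    crossings inside the record; otherwise the peak is truncated.
    """
    t, y = spectrum.times, spectrum.currents
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise TruncatedPeakError("spectrum maximum lies at the record edge")
    t_apex, height = _parabolic_apex(t, y, i)
    half = height / 2
    left = _cross_left(t, y, i, half)
    right = _cross_right(t, y, i, half)
    if left is None or right is None:
        raise TruncatedPeakError("no half-maximum crossing on one flank")
    return PeakSummary(t_d=t_apex, t_fwhm=right - left, height=height)


def _flank_minima(y: np.ndarray, idx: int, peak_indices: np.ndarray):
    """Indices of the minima bracketing peak `idx` (record edges included)."""
    left_bound = 0
    right_bound = len(y) - 1
    pos = np.searchsorted(peak_indices, idx)
    if pos > 0:
        prev = peak_indices[pos - 1]
        left_bound = prev + int(np.argmin(y[prev:idx + 1]))
    else:
        left_bound = int(np.argmin(y[:idx + 1]))
    if pos < len(peak_indices) - 1:
        nxt = peak_indices[pos + 1]
        right_bound = idx + int(np.argmin(y[idx:nxt + 1]))
    else:
        right_bound = idx + int(np.argmin(y[idx:]))
    return left_bound, right_bound


def find_peaks(spectrum: Spectrum, prominence_threshold: float = 0.05,
               min_separation: float = 0.0) -> PeakSet:
    """Local maxima above a fraction of the global maximum.

    Peaks closer than ``min_separation`` are greedily merged keeping the
    taller (the earlier one on an exact tie).  Each retained peak gets an
    FWHM measured between its flanking minima; where a flank never falls to
    half maximum before its bracketing minimum, the minimum position itself
    bounds the width.
    """
    if not 0 < prominence_threshold < 1:
        raise ParameterError("prominence_threshold must be in (0, 1)")
    t, y = spectrum.times, spectrum.currents
    gmax = float(np.max(y)) if y.size else 0.0
    if gmax <= 0 or np.ptp(y) == 0:
        return PeakSet(peaks=[], prominence_threshold=prominence_threshold)
    idx, _ = _scipy_find_peaks(y, height=prominence_threshold * gmax)
    if idx.size == 0:
        return PeakSet(peaks=[], prominence_threshold=prominence_threshold)

    # greedy merge within min_separation, tallest first, earlier wins ties
    order = sorted(range(len(idx)), key=lambda k: (-y[idx[k]], t[idx[k]]))
    kept: list[int] = []
    for k in order:
        if all(abs(t[idx[k]] - t[j]) >= min_separation for j in kept):
            kept.append(idx[k])
    kept.sort()
    kept_arr = np.asarray(kept)

    summaries = []
    for i in kept:
        lo, hi = _flank_minima(y, i, kept_arr)
        t_apex, height = (
            _parabolic_apex(t, y, i) if 0 < i < len(y) - 1 else (float(t[i]), float(y[i]))
        )
        half = height / 2
        left = _cross_left(t, y, i, half, lo)
        right = _cross_right(t, y, i, half, hi)
        left = float(t[lo]) if left is None else left
        right = float(t[hi]) if right is None else right
        width = max(right - left, np.finfo(float).tiny)
        summaries.append(PeakSummary(t_d=t_apex, t_fwhm=width, height=height))
    return PeakSet(peaks=summaries, prominence_threshold=prominence_threshold)


def enhancement_ratio(pulsed: PeakSummary, counteracted: PeakSummary) -> float:
    """Resolution enhancement ratio α_r = R_counteracted / R_pulsed."""
    return counteracted.R / pulsed.R
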