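"""Oscillation detection: period, amplitude and exact-period averaging.

An "exact period" runs from one maximum of the series to the next maximum
of the same class.  For waveforms that alternate a large and a small peak,
the window runs large-peak to large-peak (spanning exactly one large and
one small peak); cycle averages are time-weighted (trapezoidal) means over
that half-open window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = ["OscillationSummary", "OscillationSettings", "detect_oscillation",
           "exact_period_window", "period_average", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Fewer than the required number of cycles in the series."""


@dataclass
class OscillationSettings:
    prominence_frac: float = 0.05      # of the series range
    large_small_ratio: float = 0.5     # small/large relative height threshold
    tail_fraction: float = 0.5         # analysed portion (end of series)
    amplitude_floor: float = 0.0       # absolute non-oscillatory threshold
    amplitude_floor_rel: float = 1e-9  # relative to |baseline|


@dataclass
class OscillationSummary:
    variable: str
    oscillatory: bool
    period: float | None         # s
    amplitude: float | None      # max - min over one exact period
    baseline: float | None       # cycle mean
    n_cycles: int
    classification: str          # "simple" | "large_small" | "none"
    peak_times: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "variable": self.variable, "oscillatory": self.oscillatory,
            "period": self.period, "amplitude": self.amplitude,
            "baseline": self.baseline, "n_cycles": self.n_cycles,
            "classification": self.classification,
        }


def _classify_peaks(heights: np.ndarray, ratio: float
                    ) -> tuple[str, np.ndarray]:
    """Split peaks into (classification, mask of 'large' peaks)."""
    if heights.size < 4:
        return "simple", np.ones(heights.size, dtype=bool)
    lo, hi = heights.min(), heights.max()
    if hi - lo <= 0:
        return "simple", np.ones(heights.size, dtype=bool)
    rel = (heights - lo) / (hi - lo)
    large = rel > ratio
    # alternating pattern: large peaks at every other position
    idx = np.flatnonzero(large)
    if idx.size >= 2 and np.all(np.diff(idx) == 2) and idx.size >= heights.size // 2 - 1:
        return "large_small", large
    return "simple", np.ones(heights.size, dtype=bool)


def detect_oscillation(t: np.ndarray, x: np.ndarray, variable: str = "",
                       settings: OscillationSettings | None = None
                       ) -> OscillationSummary:
    """Detect a limit-cycle oscillation in a sampled series.

    Only the trailing ``tail_fraction`` of the series is analysed (the rest
    is treated as transient).  Raises :class:`InsufficientDataError` when
    fewer than 3 cycles are found in an otherwise oscillatory series.
    """
    s = settings or OscillationSettings()
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    n0 = int(len(t) * (1.0 - s.tail_fraction))
    tt, xx = t[n0:], x[n0:]
    rng = float(xx.max() - xx.min())
    baseline_guess = float(xx.mean())
    floor = max(s.amplitude_floor, s.amplitude_floor_rel * abs(baseline_guess))
    if rng <= floor:
        return OscillationSummary(variable, False, None, None,
                                  baseline_guess, 0, "none")
    peaks, props = find_peaks(xx, prominence=s.prominence_frac * rng)
    if peaks.size < 3:
        raise InsufficientDataError(
            f"found {peaks.size} peaks in {variable or 'series'}; "
            "need at least 3 detected cycles")
    heights = xx[peaks]
    classification, large_mask = _classify_peaks(heights, s.large_small_ratio)
    anchor = peaks[large_mask]
    if anchor.size < 3:
        classification, anchor = "simple", peaks
    periods = np.diff(tt[anchor])
    period = float(np.mean(periods))
    # amplitude and baseline over one exact period (last full window)
    w0, w1 = tt[anchor[-2]], tt[anchor[-1]]
    in_win = (tt >= w0) & (tt < w1)
    amp = float(xx[in_win].max() - xx[in_win].min())
    baseline = period_average(tt, xx, (w0, w1))
    return OscillationSummary(variable, True, period, amp, baseline,
                              int(anchor.size - 1), classification,
                              peak_times=tt[anchor])


def exact_period_window(t: np.ndarray, x: np.ndarray,
                        anchor_index: int | None = None,
                        settings: OscillationSettings | None = None
                        ) -> tuple[float, float]:
    """Half-open window from one (large-)peak maximum to the next.

    ``anchor_index`` selects which detected same-class peak starts the
    window (default: second to last, giving the final full cycle).
    """
    summary = detect_oscillation(t, x, settings=settings)
    if not summary.oscillatory or summary.peak_times is None:
        raise InsufficientDataError("series is not oscillatory")
    pt = summary.peak_times
    if anchor_index is None:
        anchor_index = len(pt) - 2
    if anchor_index + 1 >= len(pt):
        raise InsufficientDataError("anchor peak has no successor peak")
    return float(pt[anchor_index]), float(pt[anchor_index + 1])


def consecutive_cycle_averages(t: np.ndarray, x: np.ndarray,
                               n_cycles: int = 2,
                               settings: OscillationSettings | None = None
                               ) -> np.ndarray:
    """Means of ``x`` over the last ``n_cycles`` exact periods.

    Used as a stationarity check: on a converged limit cycle consecutive
    cycle averages agree to a small fraction of a percent.
    """
    summary = detect_oscillation(t, x, settings=settings)
    if not summary.oscillatory or summary.peak_times is None:
        raise InsufficientDataError("series is not oscillatory")
    pt = summary.peak_times
    if len(pt) < n_cycles + 1:
        raise InsufficientDataError(
            f"need {n_cycles + 1} same-class peaks, found {len(pt)}")
    return np.array([period_average(t, x, (pt[-i - 2], pt[-i - 1]))
                     for i in range(n_cycles)][::-1])


def period_average(t: np.ndarray, x: np.ndarray,
                   window: tuple[float, float]) -> float:
    """Time-weighted (trapezoidal) mean of ``x`` over ``[t0, t1)``."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    t0, t1 = window
    if not (t[0] <= t0 < t1 <= t[-1] + 1e-12):
        raise ValueError(f"window {window} outside series span")
    x0 = np.interp(t0, t, x)
    x1 = np.interp(t1, t, x)
    inside = (t > t0) & (t < t1)
    ts = np.concatenate([[t0], t[inside], [t1]])
    xs = np.concatenate([[x0], x[inside], [x1]])
    return float(np.trapezoid(xs, ts) / (t1 - t0))
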