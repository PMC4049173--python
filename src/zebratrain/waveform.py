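"""Complex-spike waveform measurements.

The average waveform is the snippet mean, aligned at spike onset and
peak-normalized. Two scalar characteristics are measured on it:

* half-maximum width (HMW): width of the first positive peak at half its
  amplitude, with linear interpolation between samples;
* spike area: trapezoidal integral of the rectified waveform over exactly
  [-0.5, +3] ms around onset.

Onset (t = 0) is operationalized as the last sample before the amplitude
first exceeds 10% of the global peak; the "first peak" is the first local
maximum after onset that exceeds 50% of the global maximum (guarding
against pre-onset noise bumps).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .exceptions import UndefinedMetricError, ValidationError
from .types import AverageWaveform

__all__ = ["average_waveform", "half_max_width", "spike_area"]

AREA_WINDOW_MS = (-0.5, 3.0)
ONSET_FRACTION = 0.1
FIRST_PEAK_FRACTION = 0.5


def _find_onset_index(amplitude: np.ndarray) -> int:
    """Last sample at or below 10% of peak before the first excursion above it."""
    peak = np.max(np.abs(amplitude))
    if peak == 0:
        raise UndefinedMetricError("all-zero waveform has no onset")
    above = np.nonzero(np.abs(amplitude) > ONSET_FRACTION * peak)[0]
    first = int(above[0])
    return max(first - 1, 0)


def average_waveform(snippets: np.ndarray, time_ms: Sequence[float],
                     align_onset: bool = True,
                     n_snippets: Optional[int] = None) -> AverageWaveform:
    """Mean of snippets on a common time axis, onset-aligned and peak-normalized.

    Parameters
    ----------
    snippets : (n, T) or (T,) array
        Waveform snippets already sampled on the common ``time_ms`` axis.
    time_ms : (T,) array
        Uniform time axis in ms.
    align_onset : bool
        If True, the time axis is shifted so the 10%-of-peak onset of the
        *average* lands at t = 0.
    """
    snip = np.asarray(snippets, dtype=float)
    if snip.ndim == 1:
        snip = snip[None, :]
    if snip.ndim != 2 or snip.shape[0] < 1:
        raise ValidationError("snippets must be a non-empty (n, T) array")
    t = np.asarray(time_ms, dtype=float)
    if t.ndim != 1 or t.size != snip.shape[1]:
        raise ValidationError(
            f"time axis length {t.size} does not match snippet length {snip.shape[1]}"
        )
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValidationError("snippet time axis must be uniformly sampled")

    mean = snip.mean(axis=0)
    peak = np.max(np.abs(mean))
    if peak == 0:
        raise ValidationError("average waveform is identically zero")
    mean = mean / peak
    if align_onset:
        t = t - t[_find_onset_index(mean)]
    return AverageWaveform(time_ms=t, amplitude=mean,
                           sample_period_ms=float(dt[0]),
                           n_snippets=n_snippets or snip.shape[0])


def _interp_crossing(t0, t1, y0, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def half_max_width(wf: AverageWaveform) -> float:
    """Width (ms) of the first peak at half its maximum amplitude.

    The first peak is the first local maximum after onset of the positive-
    rectified signal exceeding 50% of the global maximum. Crossings of the
    half-maximum level are linearly interpolated between samples.
    """
    t, y = wf.time_ms, np.maximum(wf.amplitude, 0.0)
    start = int(np.searchsorted(t, 0.0))
    gmax = np.max(y)
    if gmax == 0:
        raise UndefinedMetricError("no positive deflection in waveform")
    peak_idx = None
    for i in range(max(start, 1), y.size - 1):
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > FIRST_PEAK_FRACTION * gmax:
            peak_idx = i
            break
    if peak_idx is None:
        raise UndefinedMetricError("no first peak found after onset")
    half = 0.5 * y[peak_idx]

    # falling crossing after the peak
    fall = None
    for i in range(peak_idx, y.size - 1):
        if y[i] >= half > y[i + 1]:
            fall = _interp_crossing(t[i], t[i + 1], y[i], y[i + 1], half)
            break
    if fall is None:
        raise UndefinedMetricError("first peak has no falling half-maximum crossing")

    # rising crossing before the peak
    rise = None
    for i in range(peak_idx, 0, -1):
        if y[i] >= half > y[i - 1]:
            rise = _interp_crossing(t[i - 1], t[i], y[i - 1], y[i], half)
            break
    if rise is None:
        raise UndefinedMetricError("first peak has no rising half-maximum crossing")
    return float(fall - rise)


def spike_area(wf: AverageWaveform, window_ms=AREA_WINDOW_MS) -> float:
    """Trapezoidal integral of |amplitude| over exactly ``window_ms``.

    The waveform must cover the window; amplitudes at the window edges are
    linearly interpolated so the integration bounds are exact.
    """
    lo, hi = window_ms
    t, y = wf.time_ms, np.abs(wf.amplitude)
    if t[0] > lo + 1e-9 or t[-1] < hi - 1e-9:
        raise ValidationError(
            f"waveform covers [{t[0]:.3f}, {t[-1]:.3f}] ms; "
            f"spike area needs [{lo}, {hi}] ms"
        )
    grid = t[(t > lo) & (t < hi)]
    grid = np.concatenate([[lo], grid, [hi]])
    vals = np.interp(grid, t, y)
    return float(np.trapezoid(vals, grid))
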