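"""Per-cell spike-train statistics and inclusion filters.

Definitions follow the standard extracellular Purkinje-cell conventions:

* firing rate = event count / recording duration (Hz);
* CV = sample SD of interspike intervals (ISIs) / mean ISI, a whole-recording
  regularity measure;
* mean CV2 = mean over consecutive ISI pairs of 2|ISI_{n+1} - ISI_n| /
  (ISI_{n+1} + ISI_n), a regularity measure on the timescale of adjacent
  intervals (expectation 1 for a Poisson train, 0 for a metronome);
* climbing-fiber pause = the minimum, over all complex spikes followed by a
  simple spike, of the latency to that next simple spike (ms);
* stability profile = firing rate in 30-s bins, normalized by the
  whole-recording rate, with bins deviating > 20% flagged.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidConfigError, UndefinedMetricError
from .types import CellMetrics, SpikeTrainRecording, StabilityProfile

__all__ = [
    "firing_rate",
    "isi_cv",
    "mean_cv2",
    "climbing_fiber_pause",
    "stability_profile",
    "apply_inclusion_criteria",
    "compute_cell_metrics",
]


def firing_rate(times: Sequence[float], duration_s: float) -> float:
    """Mean firing rate in Hz: event count divided by recording duration."""
    if duration_s <= 0:
        raise UndefinedMetricError("firing_rate: duration must be > 0")
    return len(np.atleast_1d(np.asarray(times))) / duration_s


def isi_cv(times: Sequence[float]) -> float:
    """Coefficient of variation of the ISIs (sample SD / mean).

    Needs at least 3 events (2 ISIs). The sample (n-1) SD is used.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise UndefinedMetricError("isi_cv: need >= 3 events (2 ISIs)")
    isi = np.diff(t)
    return float(np.std(isi, ddof=1) / np.mean(isi))


def mean_cv2(times: Sequence[float], warn_below: int = 100) -> float:
    """Mean CV2 over consecutive ISI pairs.

    One term needs two consecutive ISIs (3 events); the mean is taken over
    however many terms exist, with a warning when there are fewer than
    ``warn_below`` (the estimate is then noisy).
    """
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise UndefinedMetricError("mean_cv2: need >= 3 events (2 consecutive ISIs)")
    isi = np.diff(t)
    a, b = isi[:-1], isi[1:]
    terms = 2.0 * np.abs(b - a) / (b + a)
    if terms.size < warn_below:
        warnings.warn(
            f"mean_cv2 averaged over only {terms.size} ISI pairs; estimate is noisy",
            stacklevel=2,
        )
    return float(np.mean(terms))


def climbing_fiber_pause(ss_times: Sequence[float], cs_times: Sequence[float],
                         mode: str = "minimum") -> float:
    """Climbing-fiber pause in ms.

    ``mode="minimum"`` (default): the minimum over all complex spikes of the
    latency to the next simple spike — the literal per-recording minimum.
    ``mode="mean"``: the mean of those per-CS latencies, exposed because the
    per-recording minimum and the per-CS average are both in circulation.
    Complex spikes with no subsequent simple spike are skipped.
    """
    ss = np.asarray(ss_times, dtype=float)
    cs = np.asarray(cs_times, dtype=float)
    if cs.size == 0:
        raise UndefinedMetricError("climbing_fiber_pause: no complex spikes")
    idx = np.searchsorted(ss, cs, side="right")
    valid = idx < ss.size
    if not np.any(valid):
        raise UndefinedMetricError(
            "climbing_fiber_pause: no complex spike is followed by a simple spike"
        )
    latencies_s = ss[idx[valid]] - cs[valid]
    if mode == "minimum":
        return float(np.min(latencies_s) * 1e3)
    if mode == "mean":
        return float(np.mean(latencies_s) * 1e3)
    raise InvalidConfigError(f"climbing_fiber_pause: unknown mode {mode!r}")


def stability_profile(times: Sequence[float], duration_s: float,
                      bin_s: float = 30.0, tolerance: float = 0.2) -> StabilityProfile:
    """Firing rate per ``bin_s`` bin, normalized by the whole-recording rate.

    Bins are half-open ``[k*bin, (k+1)*bin)``; a trailing partial bin is
    dropped. Bins whose normalized rate deviates from 1 by more than
    ``tolerance`` are flagged.
    """
    if duration_s < 2 * bin_s:
        raise UndefinedMetricError(
            f"stability_profile: need >= {2 * bin_s:.0f} s ({duration_s} s given)"
        )
    t = np.asarray(times, dtype=float)
    n_bins = int(np.floor(duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / bin_s
    overall = firing_rate(t, duration_s)
    if overall == 0:
        normalized = np.full(n_bins, np.nan)
        flagged = np.zeros(n_bins, dtype=bool)
    else:
        normalized = rates / overall
        flagged = np.abs(normalized - 1.0) > tolerance
    return StabilityProfile(bin_edges_s=edges, bin_rates_hz=rates,
                            normalized=normalized, flagged=flagged,
                            tolerance=tolerance)


def _amplitude_stable(rec: SpikeTrainRecording, tolerance: float = 0.2) -> bool:
    """Max relative deviation of the amplitude series from its median <= 20%.

    A recording without an amplitude series is taken at face value (stable):
    the criterion can only be evaluated when the series was recorded.
    """
    if rec.amplitude_series is None or rec.amplitude_series.shape[0] < 2:
        return True
    amp = rec.amplitude_series[:, 1]
    med = np.median(amp)
    if med <= 0:
        return False
    return bool(np.max(np.abs(amp - med)) / med <= tolerance)


def apply_inclusion_criteria(rec: SpikeTrainRecording,
                             metrics: Optional[CellMetrics] = None):
    """Context-dependent inclusion verdict; returns (included, reasons).

    * in_vivo: duration >= 120 s and stable SS amplitude;
    * in_vitro: duration >= 120 s, whole-recording SS CV < 0.2, and the rate
      changed < 20% between the first and the last 30 s;
    * drug / washin: duration >= 60 s.

    Every violated criterion is returned as a reason code.
    """
    reasons = []
    if rec.context == "in_vivo":
        if rec.duration < 120.0:
            reasons.append("duration")
        if not _amplitude_stable(rec):
            reasons.append("amplitude")
    elif rec.context == "in_vitro":
        if rec.duration < 120.0:
            reasons.append("duration")
        cv = metrics.ss_cv if metrics is not None else (
            isi_cv(rec.ss_times) if rec.n_ss >= 3 else None)
        if cv is None or cv >= 0.2:
            reasons.append("CV")
        if rec.duration >= 60.0:
            first = firing_rate(rec.ss_times[rec.ss_times < 30.0], 30.0)
            last = firing_rate(
                rec.ss_times[rec.ss_times >= rec.duration - 30.0], 30.0)
            if first == 0 or abs(last - first) / first >= 0.2:
                reasons.append("rate_change")
        else:
            reasons.append("rate_change")
    elif rec.context in ("drug", "washin"):
        if rec.duration < 60.0:
            reasons.append("duration")
    else:
        raise InvalidConfigError(f"unknown context {rec.context!r}")
    return (len(reasons) == 0, tuple(reasons))


def compute_cell_metrics(rec: SpikeTrainRecording,
                         cf_pause_mode: str = "minimum") -> CellMetrics:
    """All per-cell statistics plus the inclusion verdict, in one object."""
    def _try(fn, *args, **kw):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn(*args, **kw)
        except UndefinedMetricError:
            return None

    m = CellMetrics(
        cell_id=rec.cell_id,
        ss_rate_hz=firing_rate(rec.ss_times, rec.duration),
        cs_rate_hz=firing_rate(rec.cs_times, rec.duration),
        ss_cv=_try(isi_cv, rec.ss_times),
        ss_mean_cv2=_try(mean_cv2, rec.ss_times),
        cs_cv=_try(isi_cv, rec.cs_times),
        cf_pause_ms=_try(climbing_fiber_pause, rec.ss_times, rec.cs_times,
                         mode=cf_pause_mode),
        ss_stability=_try(stability_profile, rec.ss_times, rec.duration),
    )
    m.included, m.exclusion_reasons = apply_inclusion_criteria(rec, m)
    return m
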