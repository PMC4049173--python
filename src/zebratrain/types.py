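"""Core in-memory containers for recordings and derived per-cell results.

Times are always seconds on disk and in :class:`SpikeTrainRecording`;
latency- and waveform-scale quantities (CF pause, HMW, peri-CS axes) are
milliseconds and say so in their names or docstrings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .exceptions import ValidationError

ZEBRIN_IDENTITIES = ("positive", "negative", "unknown")
CONTEXTS = ("in_vivo", "in_vitro", "drug", "washin")
RESPONSE_TYPES = ("normal", "facilitation", "suppression", "oscillation")


def _as_sorted_times(times, name: str, duration: float) -> np.ndarray:
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name}: expected a 1-d array of event times")
    if arr.size:
        if np.any(np.diff(arr) <= 0):
            idx = int(np.argmax(np.diff(arr) <= 0))
            raise ValidationError(
                f"{name}: times must be strictly increasing (violated at index {idx + 1})"
            )
        if arr[0] < 0 or arr[-1] > duration:
            raise ValidationError(
                f"{name}: times must lie in [0, {duration}] s "
                f"(range is [{arr[0]}, {arr[-1]}])"
            )
    return arr


@dataclass
class SpikeTrainRecording:
    """One cell's labeled simple-spike / complex-spike event times plus metadata.

    Parameters
    ----------
    cell_id : str
        Unique identifier.
    zebrin_identity : {"positive", "negative", "unknown"}
        Zebrin II (aldolase C) band identity of the Purkinje cell.
    lobule : str
        Cerebellar lobule label (free string, e.g. ``"I-III"``, ``"X"``).
    context : {"in_vivo", "in_vitro", "drug", "washin"}
        Experimental context; selects the inclusion criteria that apply.
    duration : float
        Recording length in seconds.
    ss_times, cs_times : array-like
        Strictly increasing simple-/complex-spike times in seconds,
        within ``[0, duration]``.
    amplitude_series : ndarray, optional
        ``(n, 2)`` array of (time_s, relative amplitude) samples used by
        the amplitude-stability inclusion criterion.
    ground_truth : dict, optional
        Generator metadata (drawn rate, response type label, preset name)
        when the recording is synthetic.
    """

    cell_id: str
    zebrin_identity: str
    lobule: str
    context: str
    duration: float
    ss_times: np.ndarray
    cs_times: np.ndarray
    amplitude_series: Optional[np.ndarray] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"{self.cell_id}: duration must be > 0 s")
        if self.zebrin_identity not in ZEBRIN_IDENTITIES:
            raise ValidationError(
                f"{self.cell_id}: zebrin_identity {self.zebrin_identity!r} "
                f"not in {ZEBRIN_IDENTITIES}"
            )
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"{self.cell_id}: context {self.context!r} not in {CONTEXTS}"
            )
        self.ss_times = _as_sorted_times(self.ss_times, f"{self.cell_id}.ss_times", self.duration)
        self.cs_times = _as_sorted_times(self.cs_times, f"{self.cell_id}.cs_times", self.duration)
        if self.amplitude_series is not None:
            amp = np.asarray(self.amplitude_series, dtype=float)
            if amp.ndim != 2 or amp.shape[1] != 2:
                raise ValidationError(
                    f"{self.cell_id}: amplitude_series must be an (n, 2) array"
                )
            self.amplitude_series = amp

    @property
    def n_ss(self) -> int:
        return int(self.ss_times.size)

    @property
    def n_cs(self) -> int:
        return int(self.cs_times.size)


@dataclass
class StabilityProfile:
    """Firing rate in consecutive 30-s bins, normalized by the whole-recording rate."""

    bin_edges_s: np.ndarray          # len n_bins + 1
    bin_rates_hz: np.ndarray
    normalized: np.ndarray           # bin rate / whole-recording rate
    flagged: np.ndarray              # bool, |normalized - 1| > tolerance
    tolerance: float = 0.2


@dataclass
class CellMetrics:
    """Per-cell spike-train statistics and the inclusion verdict."""

    cell_id: str
    ss_rate_hz: float
    cs_rate_hz: float
    ss_cv: Optional[float]
    ss_mean_cv2: Optional[float]
    cs_cv: Optional[float] = None
    cf_pause_ms: Optional[float] = None
    ss_stability: Optional[StabilityProfile] = None
    included: Optional[bool] = None
    exclusion_reasons: tuple = ()

    def as_row(self) -> dict:
        """Flat dict for tabular (CSV) export."""
        return {
            "cell_id": self.cell_id,
            "ss_rate_hz": self.ss_rate_hz,
            "cs_rate_hz": self.cs_rate_hz,
            "ss_cv": self.ss_cv,
            "ss_mean_cv2": self.ss_mean_cv2,
            "cs_cv": self.cs_cv,
            "cf_pause_ms": self.cf_pause_ms,
            "included": self.included,
            "exclusion_reasons": ";".join(self.exclusion_reasons),
        }


@dataclass
class AverageWaveform:
    """Normalized mean spike waveform on a ms time axis with onset at t = 0.

    ``amplitude`` is peak-normalized (max |amplitude| = 1); ``time_ms`` is
    uniformly sampled and should cover at least [-0.5, +3] ms for the
    spike-area measurement.
    """

    time_ms: np.ndarray
    amplitude: np.ndarray
    sample_period_ms: float
    n_snippets: int = 1

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time_ms.shape != self.amplitude.shape:
            raise ValidationError("time_ms and amplitude must have the same shape")
        if self.time_ms.size < 4:
            raise ValidationError("waveform needs at least 4 samples")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("waveform time axis must be uniformly sampled")


@dataclass
class PeriCSProfile:
    """Binned peri-complex-spike simple-spike rate over [-100, +300] ms.

    Rates are in Hz (counts / (n_cs * bin width)); ``baseline_hz`` is the
    mean rate over the pre-CS window [-100, 0) ms.
    """

    bin_edges_ms: np.ndarray
    rates_hz: np.ndarray
    n_cs: int
    baseline_hz: float
    pause_end_ms: Optional[float] = None
    assigned_type: Optional[str] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])


@dataclass
class GroupComparisonResult:
    """Result of a classical group comparison (t, chi2, F, rho, r).

    ``group_summaries`` holds (mean, sd, n) per group where meaningful;
    ``extra`` carries test-specific payload (post-hoc tables, CIs).
    """

    statistic_name: str
    value: float
    df: Any
    p: float
    group_summaries: tuple = ()
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        df = self.df
        df_str = f"{df:g}" if np.isscalar(df) else ",".join(f"{d:g}" for d in df)
        flag = " (degenerate)" if self.degenerate else ""
        return f"{self.statistic_name}({df_str}) = {self.value:.4g}, p = {self.p:.4g}{flag}"
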