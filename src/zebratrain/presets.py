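"""Generative presets for synthetic Purkinje-cell cohorts.

A :class:`CellPreset` collects the across-cell statistics of one population
(zebrin-negative, zebrin-positive, or any custom group): simple-spike (SS)
rate mean/SD across cells, within-cell regularity (gamma-renewal shape),
complex-spike (CS) rate, the enforced climbing-fiber pause, the mix of
post-CS response types, the modulation kernels, and the CS-waveform targets.

The module-level ``ZEBRIN_NEGATIVE`` / ``ZEBRIN_POSITIVE`` presets carry the
published cohort statistics (SS 96.1 +/- 15.4 Hz vs 61.4 +/- 19.3 Hz,
CS 1.13 +/- 0.25 Hz vs 0.92 +/- 0.28 Hz).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidConfigError
from .types import RESPONSE_TYPES, ZEBRIN_IDENTITIES


@dataclass(frozen=True)
class KernelParams:
    """Post-pause SS-rate modulation kernels, one per response type.

    The kernel multiplies the baseline SS rate as a function of time since
    the end of the climbing-fiber pause. ``oscillation_freq_hz=None`` means
    "use the cell's own drawn SS rate", which reproduces the empirical
    signature that oscillating cells ring near their firing frequency.
    """

    facilitation_gain: float = 0.5          # rate multiplied by (1 + gain)
    facilitation_duration_ms: float = 50.0
    suppression_depth: float = 0.5          # rate multiplied by (1 - depth)
    suppression_duration_ms: float = 100.0
    oscillation_depth: float = 0.4
    oscillation_decay_ms: float = 100.0
    oscillation_freq_hz: Optional[float] = None
    duration_ms: float = 300.0              # window over which oscillation acts


@dataclass(frozen=True)
class WaveformParams:
    """Targets for the synthetic complex-spike waveform template.

    ``hmw_ms`` is the half-maximum width of the first positive peak;
    ``area`` the rectified integral over [-0.5, +3] ms (peak-normalized
    amplitude x ms).
    """

    hmw_ms: float = 0.6
    area: float = 1.1
    sample_period_ms: float = 0.02  # 50 kHz


@dataclass(frozen=True)
class CellPreset:
    """Across-cell generative parameters for one synthetic population."""

    zebrin_identity: str = "unknown"
    ss_rate_mean: float = 80.0      # Hz, across-cell mean
    ss_rate_sd: float = 15.0        # Hz, across-cell SD
    ss_shape: float = 4.0           # gamma-renewal shape >= 1 (regularity)
    cs_rate: float = 1.0            # Hz, across-cell mean
    cs_rate_sd: float = 0.0         # Hz, across-cell SD (0 = identical cells)
    cf_pause_ms: float = 10.0       # enforced SS-free interval after each CS
    response_type_probs: tuple = (1.0, 0.0, 0.0, 0.0)  # normal, facil, supp, osc
    kernel_params: KernelParams = field(default_factory=KernelParams)
    waveform_params: WaveformParams = field(default_factory=WaveformParams)
    amplitude_drift: float = 0.0    # fractional amplitude change over the recording
    name: str = "preset"

    def validate(self) -> None:
        probs = np.asarray(self.response_type_probs, dtype=float)
        if probs.size != len(RESPONSE_TYPES) or np.any(probs < 0):
            raise InvalidConfigError(
                f"{self.name}: response_type_probs must be {len(RESPONSE_TYPES)} "
                "non-negative numbers"
            )
        if abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"{self.name}: response_type_probs must sum to 1 (got {probs.sum()!r})"
            )
        if self.zebrin_identity not in ZEBRIN_IDENTITIES:
            raise InvalidConfigError(
                f"{self.name}: zebrin_identity {self.zebrin_identity!r} invalid"
            )
        if not (self.ss_rate_mean > self.cs_rate > 0):
            raise InvalidConfigError(
                f"{self.name}: require ss_rate_mean > cs_rate > 0 "
                f"(got {self.ss_rate_mean}, {self.cs_rate})"
            )
        if self.cs_rate >= 1.0 / CS_REFRACTORY_S:
            raise InvalidConfigError(
                f"{self.name}: cs_rate must be below {1.0 / CS_REFRACTORY_S:.0f} Hz "
                "(CS refractory period)"
            )
        if self.cf_pause_ms < 0:
            raise InvalidConfigError(f"{self.name}: cf_pause_ms must be >= 0")
        if self.ss_shape < 1:
            raise InvalidConfigError(f"{self.name}: ss_shape must be >= 1")
        if self.ss_rate_sd < 0 or self.cs_rate_sd < 0:
            raise InvalidConfigError(f"{self.name}: rate SDs must be >= 0")
        if not 0 <= self.amplitude_drift:
            raise InvalidConfigError(f"{self.name}: amplitude_drift must be >= 0")

    def replace(self, **kw) -> "CellPreset":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


# Absolute refractory period between complex spikes (no physiological CS doublets).
CS_REFRACTORY_S = 0.020


@dataclass(frozen=True)
class WashinSpec:
    """Drug wash-in dynamics: exponential approach to a fractional rate reduction.

    SS rate follows r(t) = r0 * (1 - effect_fraction * (1 - exp(-(t-onset)/tau)))
    for t >= onset.
    """

    drug_onset_s: float
    effect_fraction: float
    time_constant_s: float = 60.0

    def validate(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise InvalidConfigError("effect_fraction must be in [0, 1]")
        if self.drug_onset_s < 0:
            raise InvalidConfigError("drug_onset_s must be >= 0")
        if self.time_constant_s <= 0:
            raise InvalidConfigError("time_constant_s must be > 0")


@dataclass
class PopulationConfig:
    """A cohort spec: (preset, n_cells) groups, a common duration, one seed."""

    presets: list  # list of (CellPreset, n_cells)
    duration_s: float
    seed: int
    washin: Optional[WashinSpec] = None

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be > 0")
        if not self.presets:
            raise InvalidConfigError("presets must be non-empty")
        for preset, n in self.presets:
            if n < 1:
                raise InvalidConfigError(
                    f"preset {preset.name!r}: n_cells must be >= 1 (got {n})"
                )
            preset.validate()
        if self.washin is not None:
            self.washin.validate()
            if self.duration_s <= self.washin.drug_onset_s:
                raise InvalidConfigError("duration_s must exceed washin drug_onset_s")


# Published cohort statistics for the two zebrin populations. Response-type
# mixes follow the reported pattern: facilitation in 17/47 zebrin-negative and
# 6/57 zebrin-positive cells, suppression/oscillation restricted to zebrin-
# positive cells (their exact counts are not printed; modest defaults chosen).
ZEBRIN_NEGATIVE = CellPreset(
    name="zebrin_negative",
    zebrin_identity="negative",
    ss_rate_mean=96.1,
    ss_rate_sd=15.4,
    ss_shape=4.0,
    cs_rate=1.13,
    cs_rate_sd=0.25,
    cf_pause_ms=10.0,
    response_type_probs=(1 - 17 / 47, 17 / 47, 0.0, 0.0),
    waveform_params=WaveformParams(hmw_ms=0.55, area=1.1),
)

ZEBRIN_POSITIVE = CellPreset(
    name="zebrin_positive",
    zebrin_identity="positive",
    ss_rate_mean=61.4,
    ss_rate_sd=19.3,
    ss_shape=4.0,
    cs_rate=0.92,
    cs_rate_sd=0.28,
    cf_pause_ms=10.0,
    response_type_probs=(1 - 6 / 57 - 0.10 - 0.05, 6 / 57, 0.10, 0.05),
    waveform_params=WaveformParams(hmw_ms=0.75, area=1.4),
)
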