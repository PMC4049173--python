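"""Synthetic Purkinje-cell spike-train generator.

Simple spikes (SS) are a gamma-renewal process: one parameter for rate, one
(the shape ``k``) for within-cell regularity, with the Poisson train as the
``k = 1`` special case (mean CV2 = 1, a convenient analytic oracle).
Complex spikes (CS) are homogeneous Poisson with a 20 ms absolute refractory
period. Around each CS the SS train is modified in two steps that mirror the
physiology: every SS inside the climbing-fiber pause ``(cs, cs + pause]`` is
deleted, and the post-pause SS rate is multiplied by a response-type kernel
(normal / facilitation / suppression / oscillation). Sub-unity kernels are
realized by thinning; super-unity parts by superposing a thinned independent
Poisson train (an approximation to an inhomogeneous renewal process).

Across-cell heterogeneity: each cell's SS (and optionally CS) rate is drawn
once from a normal distribution truncated below, so a cohort generated from
a preset reproduces the published across-cell mean +/- SD.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import InvalidConfigError
from .presets import (
    CS_REFRACTORY_S,
    CellPreset,
    KernelParams,
    PopulationConfig,
    WashinSpec,
    WaveformParams,
)
from .types import RESPONSE_TYPES, SpikeTrainRecording

__all__ = [
    "generate_cell",
    "generate_population",
    "generate_washin_series",
    "generate_cs_waveform",
    "WaveformSnippets",
]


# ---------------------------------------------------------------------------
# elementary point processes
# ---------------------------------------------------------------------------

def _gamma_renewal(rng: np.random.Generator, rate_hz: float, shape: float,
                   duration_s: float) -> np.ndarray:
    """Ordinary gamma renewal train on (0, duration]: ISI ~ Gamma(k, 1/(k*r))."""
    if rate_hz <= 0:
        return np.empty(0)
    scale = 1.0 / (shape * rate_hz)
    times = []
    t = 0.0
    # draw in chunks; 3 sigma headroom on the expected count
    while t < duration_s:
        n = max(64, int((duration_s - t) * rate_hz * 1.25) + 32)
        isi = rng.gamma(shape, scale, size=n)
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    times = np.concatenate(times)
    return times[times <= duration_s]


def _poisson_refractory(rng: np.random.Generator, rate_hz: float, duration_s: float,
                        refractory_s: float = CS_REFRACTORY_S) -> np.ndarray:
    """Poisson train with a dead time; ISIs are refractory + Exp with mean
    chosen so that the overall mean rate equals ``rate_hz`` exactly."""
    if rate_hz <= 0:
        return np.empty(0)
    exp_mean = 1.0 / rate_hz - refractory_s
    if exp_mean <= 0:
        raise InvalidConfigError(
            f"rate {rate_hz} Hz incompatible with {refractory_s * 1e3:.0f} ms refractory period"
        )
    times = []
    t = 0.0
    while t < duration_s:
        n = max(16, int((duration_s - t) * rate_hz * 1.5) + 16)
        isi = refractory_s + rng.exponential(exp_mean, size=n)
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    times = np.concatenate(times)
    return times[times <= duration_s]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    """One draw from Normal(mean, sd) truncated at ``lower`` (rejection)."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    raise InvalidConfigError(
        f"truncated normal ({mean}, {sd}) at {lower}: rejection failed"
    )


# ---------------------------------------------------------------------------
# response-type kernels
# ---------------------------------------------------------------------------

def _kernel(response_type: str, kp: KernelParams,
            cell_rate_hz: float) -> Tuple[Optional[Callable], float, float]:
    """Return (m(tau_s), active duration s, max excess above 1) for a type.

    ``tau`` is time since the end of the climbing-fiber pause. ``None``
    means no modulation (normal type).
    """
    if response_type == "normal":
        return None, 0.0, 0.0
    if response_type == "facilitation":
        dur = kp.facilitation_duration_ms / 1e3
        gain = kp.facilitation_gain

        def m(tau):
            return np.where(tau < dur, 1.0 + gain, 1.0)

        return m, dur, gain
    if response_type == "suppression":
        dur = kp.suppression_duration_ms / 1e3
        depth = kp.suppression_depth

        def m(tau):
            return np.where(tau < dur, 1.0 - depth, 1.0)

        return m, dur, 0.0
    if response_type == "oscillation":
        dur = kp.duration_ms / 1e3
        depth = kp.oscillation_depth
        decay = kp.oscillation_decay_ms / 1e3
        freq = kp.oscillation_freq_hz if kp.oscillation_freq_hz is not None else cell_rate_hz

        def m(tau):
            env = np.exp(-np.asarray(tau) / decay)
            out = 1.0 - depth * np.cos(2 * np.pi * freq * np.asarray(tau)) * env
            return np.where(np.asarray(tau) < dur, out, 1.0)

        return m, dur, depth
    raise InvalidConfigError(f"unknown response type {response_type!r}")


def _apply_cs_structure(rng: np.random.Generator, ss: np.ndarray, cs: np.ndarray,
                        pause_s: float, kernel: Optional[Callable],
                        kernel_dur_s: float, max_excess: float,
                        rate_hz: float, duration_s: float) -> np.ndarray:
    """Delete SS inside each CS pause, then thin/boost the post-pause train."""
    if cs.size == 0:
        return ss

    def in_pause(t):
        idx = np.searchsorted(cs, t, side="left") - 1
        prev = np.where(idx >= 0, cs[np.clip(idx, 0, None)], -np.inf)
        return (t - prev > 0) & (t - prev <= pause_s)

    if pause_s > 0:
        ss = ss[~in_pause(ss)]

    if kernel is None:
        return ss

    # thinning for sub-unity kernel values
    idx = np.searchsorted(cs, ss, side="left") - 1
    prev = np.where(idx >= 0, cs[np.clip(idx, 0, None)], -np.inf)
    tau = ss - (prev + pause_s)
    active = (tau >= 0) & (tau < kernel_dur_s)
    keep = np.ones(ss.size, dtype=bool)
    if np.any(active):
        mvals = kernel(tau[active])
        keep_prob = np.minimum(mvals, 1.0)
        keep[active] = rng.random(int(active.sum())) < keep_prob
    ss = ss[keep]

    # superposed thinned Poisson for super-unity kernel values
    if max_excess > 0:
        extras = []
        lam = rate_hz * max_excess
        for c in cs:
            t0 = c + pause_s
            n = rng.poisson(lam * kernel_dur_s)
            if n == 0:
                continue
            cand = t0 + rng.random(n) * kernel_dur_s
            excess = np.maximum(kernel(cand - t0) - 1.0, 0.0)
            acc = cand[rng.random(n) < excess / max_excess]
            extras.append(acc)
        if extras:
            extra = np.concatenate(extras)
            extra = extra[(extra > 0) & (extra <= duration_s)]
            if pause_s > 0:
                extra = extra[~in_pause(extra)]
            ss = np.sort(np.concatenate([ss, extra]))

    # strictly increasing: drop exact duplicates (measure-zero, but be exact)
    if ss.size > 1:
        ss = ss[np.concatenate([[True], np.diff(ss) > 0])]
    return ss


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_cell(preset: CellPreset, duration_s: float, seed: int,
                  cell_id: Optional[str] = None,
                  context: str = "in_vivo") -> SpikeTrainRecording:
    """Generate one labeled recording from a preset.

    The cell's SS rate is drawn once from Normal(ss_rate_mean, ss_rate_sd)
    truncated at 1 Hz; its response type from ``response_type_probs``. The
    drawn rate and type are stored in ``ground_truth``.
    """
    preset.validate()
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be > 0")
    rng = np.random.default_rng(seed)

    ss_rate = _truncated_normal(rng, preset.ss_rate_mean, preset.ss_rate_sd, 1.0)
    cs_rate = _truncated_normal(rng, preset.cs_rate, preset.cs_rate_sd, 0.05)
    rtype = RESPONSE_TYPES[rng.choice(len(RESPONSE_TYPES),
                                      p=np.asarray(preset.response_type_probs, float))]

    cs = _poisson_refractory(rng, cs_rate, duration_s)
    ss = _gamma_renewal(rng, ss_rate, preset.ss_shape, duration_s)

    kernel, kdur, kmax = _kernel(rtype, preset.kernel_params, ss_rate)
    pause_s = preset.cf_pause_ms / 1e3
    ss = _apply_cs_structure(rng, ss, cs, pause_s, kernel, kdur, kmax,
                             ss_rate, duration_s)

    amplitude_series = None
    if preset.amplitude_drift > 0:
        t = np.arange(0.0, duration_s + 1e-9, max(duration_s / 60.0, 1.0))
        amp = 1.0 - preset.amplitude_drift * t / duration_s
        amplitude_series = np.column_stack([t, amp])

    return SpikeTrainRecording(
        cell_id=cell_id or f"{preset.name}_s{seed}",
        zebrin_identity=preset.zebrin_identity,
        lobule="unknown",
        context=context,
        duration=float(duration_s),
        ss_times=ss,
        cs_times=cs,
        amplitude_series=amplitude_series,
        ground_truth={
            "preset": preset.name,
            "seed": int(seed),
            "response_type": rtype,
            "drawn_ss_rate_hz": ss_rate,
            "drawn_cs_rate_hz": cs_rate,
        },
    )


def generate_population(config: PopulationConfig):
    """Generate a cohort; returns (recordings, manifest).

    Per-cell seeds are ``config.seed + index`` across the flattened cohort,
    so any individual cell can be regenerated without its neighbours and the
    whole cohort is reproducible from one seed.
    """
    config.validate()
    recordings = []
    cells_meta = []
    index = 0
    for preset, n_cells in config.presets:
        for j in range(n_cells):
            cell_seed = config.seed + index
            cell_id = f"{preset.name}_{j:03d}"
            if config.washin is not None:
                rec = generate_washin_series(preset, config.washin,
                                             config.duration_s, cell_seed,
                                             cell_id=cell_id)
            else:
                rec = generate_cell(preset, config.duration_s, cell_seed,
                                    cell_id=cell_id)
            recordings.append(rec)
            cells_meta.append({
                "cell_id": rec.cell_id,
                "zebrin_identity": rec.zebrin_identity,
                "lobule": rec.lobule,
                "context": rec.context,
                "duration_s": rec.duration,
                "preset": preset.to_dict(),
                **rec.ground_truth,
            })
            index += 1
    manifest = {
        "seed": int(config.seed),
        "duration_s": float(config.duration_s),
        "n_cells": index,
        "cells": cells_meta,
    }
    return recordings, manifest


def generate_washin_series(preset: CellPreset, spec: WashinSpec,
                           duration_s: float, seed: int,
                           cell_id: Optional[str] = None) -> SpikeTrainRecording:
    """Generate a recording with a drug wash-in rate drop.

    The baseline train is generated as in :func:`generate_cell`, then the SS
    train is thinned with time-varying survival probability
    ``1 - effect_fraction * (1 - exp(-(t - onset)/tau))`` so the SS rate
    relaxes exponentially toward ``(1 - effect_fraction) * r0``.
    """
    spec.validate()
    if duration_s <= spec.drug_onset_s:
        raise InvalidConfigError("duration_s must exceed drug_onset_s")
    rec = generate_cell(preset, duration_s, seed, cell_id=cell_id, context="washin")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD4]))
    t = rec.ss_times
    rel = t - spec.drug_onset_s
    survive = np.ones_like(t)
    after = rel >= 0
    survive[after] = 1.0 - spec.effect_fraction * (
        1.0 - np.exp(-rel[after] / spec.time_constant_s))
    keep = rng.random(t.size) < survive
    rec.ss_times = t[keep]
    rec.ground_truth["washin"] = {
        "drug_onset_s": spec.drug_onset_s,
        "effect_fraction": spec.effect_fraction,
        "time_constant_s": spec.time_constant_s,
    }
    return rec


# ---------------------------------------------------------------------------
# complex-spike waveform snippets
# ---------------------------------------------------------------------------

@dataclass
class WaveformSnippets:
    """Noisy waveform snippets plus the noiseless template they came from."""

    time_ms: np.ndarray       # common axis, onset at 0, covers [-0.5, +3] ms
    snippets: np.ndarray      # (n_snippets, n_samples)
    template: np.ndarray      # noiseless, peak-normalized


def _cs_template(params: WaveformParams) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless CS template: a gaussian first peak with the requested HMW,
    plus smaller after-components scaled to hit the requested rectified area
    over [-0.5, +3] ms. Onset (t = 0) is where the rising edge crosses 10%
    of the peak."""
    hmw = params.hmw_ms
    if hmw <= 0:
        raise InvalidConfigError("waveform hmw_ms must be > 0")
    sigma = hmw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t_peak = sigma * np.sqrt(2.0 * np.log(10.0))  # 10% of peak at t = 0
    dt = params.sample_period_ms
    time = np.arange(-0.5, 3.0 + dt / 2, dt)
    if hmw >= 2.0:
        raise InvalidConfigError("hmw_ms too large for the [-0.5, +3] ms snippet")

    main = np.exp(-0.5 * ((time - t_peak) / sigma) ** 2)
    # after-components: a trough then a late bump, well past the first peak
    c1 = -np.exp(-0.5 * ((time - (t_peak + 4.0 * sigma)) / sigma) ** 2)
    c2 = 0.6 * np.exp(-0.5 * ((time - (t_peak + 7.0 * sigma)) / (2.0 * sigma)) ** 2)

    def area(a):
        return np.trapezoid(np.abs(main + a * (c1 + c2)), time)

    lo, hi = area(0.0), area(0.9)
    if not (lo <= params.area <= hi):
        raise InvalidConfigError(
            f"waveform area {params.area} infeasible for hmw {hmw} ms "
            f"(reachable range [{lo:.3f}, {hi:.3f}])"
        )
    a = 0.0 if params.area <= lo else brentq(lambda x: area(x) - params.area, 0.0, 0.9)
    wf = main + a * (c1 + c2)
    peak = np.max(np.abs(wf))
    if peak == 0:
        raise InvalidConfigError("zero-amplitude waveform template")
    return time, wf / peak


def generate_cs_waveform(params: WaveformParams, seed: int,
                         n_snippets: int = 100,
                         noise_sd: float = 0.05) -> WaveformSnippets:
    """Generate noisy CS waveform snippets around a deterministic template.

    Noise is i.i.d. gaussian per sample with SD ``noise_sd`` (in units of the
    template peak), so averaging ``n`` snippets suppresses it by sqrt(n).
    """
    if n_snippets < 1:
        raise InvalidConfigError("n_snippets must be >= 1")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    time, template = _cs_template(params)
    rng = np.random.default_rng(seed)
    snippets = template[None, :] + rng.normal(0.0, noise_sd,
                                              size=(n_snippets, time.size))
    return WaveformSnippets(time_ms=time, snippets=snippets, template=template)
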