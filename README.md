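# zebratrain

Spike-train analysis for cerebellar Purkinje cells, built around the
comparison of zebrin-negative (Z−) and zebrin-positive (Z+) populations,
plus a synthetic spike-train generator that makes every analysis stage
testable without recorded data.

Purkinje cells fire two spike classes: **simple spikes** (SS, tens of Hz,
intrinsically driven) and **complex spikes** (CS, ~1 Hz, climbing-fiber
evoked, each followed by an SS-free *climbing-fiber pause*). Cells in
zebrin-negative parasagittal bands fire simple spikes markedly faster than
cells in zebrin-positive bands (≈96 vs ≈61 Hz across cells), and the two
populations also differ in CS rate, CS waveform, and the shape of the SS
rate profile after each CS. `zebratrain` implements the analysis chain that
establishes such differences from labeled spike-time data:

- **Per-cell metrics** (`zebratrain.metrics`): firing rate `n/T`; ISI
  coefficient of variation `CV = σ(ISI)/μ(ISI)`; mean
  `CV2 = ⟨2|ISIₙ₊₁ − ISIₙ| / (ISIₙ₊₁ + ISIₙ)⟩` (adjacent-interval
  regularity; 1 for Poisson, 0 for a metronome); climbing-fiber pause
  (minimum post-CS first-SS latency); 30-s stability profiles; the
  in-vivo / in-vitro / drug inclusion criteria.
- **Waveform metrics** (`zebratrain.waveform`): onset-aligned, peak-
  normalized average waveforms; half-maximum width of the first peak
  (FWHM with linear interpolation); rectified spike area over [−0.5, +3] ms.
- **Peri-CS response typing** (`zebratrain.pericomplex`): CS-triggered SS
  histograms over [−100, +300] ms and a configurable four-way classifier
  (normal / facilitation / suppression / oscillation), with a matched-filter
  oscillation detector and full diagnostics.
- **Group statistics** (`zebratrain.stats`): pooled-variance Student *t*
  (raw samples or printed summaries), paired *t*, Pearson χ² without
  continuity correction, Spearman/Pearson correlation, one-way ANOVA with
  Tukey/Bonferroni post hoc, drug wash-in effect (pre = 2 min before onset,
  post = minutes 5–7 after), f–I slope, per-lobule aggregation.
- **Synthetic cohorts** (`zebratrain.synthetic`): gamma-renewal SS trains
  (shape *k* controls regularity), Poisson CS trains with refractory
  period, enforced climbing-fiber pauses, the four post-CS response
  kernels, CS waveform snippets, amplitude drift and drug wash-in dynamics.
  Cohort presets `ZEBRIN_NEGATIVE` / `ZEBRIN_POSITIVE` carry the published
  across-cell statistics.
- **I/O and pipeline** (`zebratrain.io`, `zebratrain.pipeline`,
  CLI `zebratrain`): delimited spike files, JSON manifests, YAML run
  configs, and a deterministic simulate → metrics → typing → stats run.

## Worked example

```python
import numpy as np
from zebratrain import (PopulationConfig, ZEBRIN_NEGATIVE, ZEBRIN_POSITIVE,
                        compute_cell_metrics, generate_population, two_sample_t)

cohort, _ = generate_population(PopulationConfig(
    presets=[(ZEBRIN_NEGATIVE, 47), (ZEBRIN_POSITIVE, 57)],
    duration_s=120.0, seed=1))
metrics = [compute_cell_metrics(rec) for rec in cohort]

neg = np.array([m.ss_rate_hz for m in metrics[:47]])
pos = np.array([m.ss_rate_hz for m in metrics[47:]])
print(f"Z-: {neg.mean():.1f} +/- {neg.std(ddof=1):.1f} Hz")
print(f"Z+: {pos.mean():.1f} +/- {pos.std(ddof=1):.1f} Hz")
print(two_sample_t(neg, pos).summary())
```

prints

```
Z-: 95.4 +/- 15.3 Hz
Z+: 58.0 +/- 18.0 Hz
t(102) = 11.28, p = 1.216e-19
```

i.e. the synthetic Z− cohort fires simple spikes at ~95 Hz, the Z+ cohort
at ~60 Hz (each cell's rate is drawn from the published across-cell
distribution), and a pooled two-sample *t* test on 47 + 57 cells separates
the populations decisively — the same analysis one would run on real
per-cell metrics tables.

The same flow is available from the shell:

```bash
zebratrain simulate --out run/ --seed 1 --n-negative 47 --n-positive 57
zebratrain metrics --manifest run/manifest.json --out run/metrics.csv
zebratrain pericss --manifest run/manifest.json --out run/pericss.csv
zebratrain stats chi2 --table 17,30,6,51
```

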