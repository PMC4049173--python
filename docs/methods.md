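# Methods

This note documents the generative model behind the synthetic cohorts, the
exact definitions of the per-cell metrics, the peri-complex-spike response
classifier, and the numerical and design choices that were genuinely open.
Nothing here states an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model for synthetic recordings

### Simple-spike trains

Simple spikes (SS) are an ordinary **gamma renewal process**: interspike
intervals are i.i.d. Gamma(shape *k*, scale 1/(*k·r*)), so the mean rate is
*r* (Hz) and *k* ≥ 1 controls within-cell regularity with one parameter.
The Poisson train is the *k* = 1 special case, for which mean CV2 has the
closed-form expectation 1 (with *U* = ISIₙ/(ISIₙ+ISIₙ₊₁) ~ Uniform(0,1),
E[2|1−2U|] = 1) — the analytic oracle the regularity tests use. Empirical
mean CV2 is strictly decreasing in *k*; the default *k* = 4 gives CV2 ≈ 0.57,
in the range typical of awake Purkinje-cell recordings.

**Across-cell heterogeneity.** Each cell draws its rate once from
Normal(μ, σ) truncated at 1 Hz, with (μ, σ) taken from the published
across-cell statistics: SS 96.1 ± 15.4 Hz for zebrin-negative and
61.4 ± 19.3 Hz for zebrin-positive cells. A cohort of *n* cells therefore
recovers μ within ~2σ/√n, which is what the cohort-recovery tests assert.

### Complex-spike trains

Complex spikes (CS) are homogeneous Poisson with a **20 ms absolute
refractory period** (no physiological CS doublets). ISIs are
0.02 s + Exp(1/λ − 0.02 s), so the mean rate equals the target λ exactly.
Cohort CS rates are 1.13 ± 0.25 Hz (Z−) and 0.92 ± 0.28 Hz (Z+), drawn per
cell from a truncated normal like the SS rate.

### Climbing-fiber pause and post-CS response kernels

After each CS, every SS in (cs, cs + pause] is deleted (default pause
10 ms); the invariant is enforced exactly and asserted exactly in the
tests. After the pause the SS rate is multiplied by a response-type kernel
m(τ), τ = time since pause end:

| type         | kernel (defaults)                                   |
|--------------|-----------------------------------------------------|
| normal       | m = 1                                               |
| facilitation | m = 1.5 for 50 ms                                   |
| suppression  | m = 0.5 for 100 ms                                  |
| oscillation  | m = 1 − 0.4·cos(2πfτ)·exp(−τ/100 ms), f = cell rate |

Only example histograms of these four shapes are in circulation — no kernel
equations — so these are package choices, selected to be recoverable by the
classifier, and all configurable. Sub-unity kernel values are realized by
thinning; super-unity values by superposing an independent Poisson train at
rate r·(m−1), itself thinned to the kernel shape. The superposition is an
approximation to an inhomogeneous renewal process: it locally Poissonizes
the train inside the boosted window, which is irrelevant to rate-based
analyses and negligible for whole-recording CV2 at ~1 CS/s. The oscillation
frequency defaults to the cell's own firing rate, reproducing the empirical
signature that oscillating cells ring near their (low) SS rate; oscillation
presets should therefore sit in the 35–60 Hz band.

Pause deletion removes a fraction ≈ pause·cs_rate (~1%) of simple spikes,
so measured cohort rates sit slightly below the drawn-rate mean — the same
is true of real recordings, whose published rates also include the pauses.

### Wash-in, amplitude drift, waveform snippets

Drug wash-in thins the SS train with survival probability
1 − e·(1 − exp(−(t−onset)/τ)) (plateau effect fraction *e*, time constant
τ, default 60 s), so the rate relaxes exponentially to (1−e)·r. Note the
5–7 min effect window sits at 1 − ½(e^(−5) − e^(−7)) ≈ 99.7% of plateau,
so measured reductions run ~0.3% of *e* below the nominal plateau.

Amplitude drift writes a linear (time, relative-amplitude) series from 1 to
1 − drift, feeding the amplitude-stability inclusion criterion.

CS waveform snippets are built from a deterministic template: a gaussian
first peak whose σ is set from the target half-maximum width
(σ = HMW / (2√(2 ln 2))), plus a fixed trough-and-bump after-complex whose
common amplitude is solved numerically (Brent) so the rectified area over
[−0.5, +3] ms hits the target; infeasible (HMW, area) pairs are rejected.
Onset t = 0 is placed where the rising edge crosses 10% of the peak.
Snippet noise is i.i.d. gaussian per sample, so averaging n snippets
suppresses it by √n.

## Per-cell metrics: conventions

- **CV** uses the sample (n−1) SD — the convention consistent with the
  t-test machinery used downstream; requires ≥ 2 ISIs.
- **Mean CV2** needs one term (3 spikes); it averages over however many
  terms exist and warns below 100 terms. It is invariant under time
  rescaling (property-tested).
- **Climbing-fiber pause** is the literal per-recording *minimum* over all
  CS of the latency to the next SS, in ms; CS with no subsequent SS are
  skipped. The per-CS *mean* is exposed via `mode="mean"` because both
  readings of "minimum duration between a complex spike and the following
  simple spike" are in circulation. The implementation is tested for exact
  equality against a brute-force double loop.
- **Stability profile**: half-open bins [k·30, (k+1)·30) s, trailing
  partial bin dropped; normalized by the whole-recording rate; bins
  deviating > 20% are flagged.
- **Inclusion criteria** by context — in vivo: duration ≥ 120 s and stable
  SS amplitude (operationalized as max |amp − median|/median ≤ 20%, since
  the criterion is only ever stated qualitatively; a missing amplitude
  series counts as stable because the criterion is then unevaluable);
  in vitro: duration ≥ 120 s, whole-recording CV < 0.2, and < 20% rate
  change between the first and last 30 s; drug/wash-in: duration ≥ 60 s.
  All violated criteria are returned as reason codes.
- SS falling inside CS pauses in *real* data (sorting artifacts) are not
  filtered here; that is the sorter's or generator's job.

## Waveform measurements

The average waveform is the snippet mean, peak-normalized, with the time
axis shifted so the 10%-of-peak onset sits at t = 0. The **first peak** is
the first local maximum after onset of the positive-rectified signal
exceeding 50% of the global maximum (guards against pre-onset noise).
Half-maximum crossings are linearly interpolated between the bracketing
samples (y = half exactly at the interpolated t). **Spike area** is the
trapezoidal integral of |amplitude| over exactly [−0.5, +3] ms, with edge
values interpolated so the bounds are exact; at 50 kHz sampling it is
within 1% of analytic integrals. HMW is invariant under amplitude scaling;
area is linear in amplitude (both property-tested). Peak (not area)
normalization was chosen for the average waveform; HMW is normalization-
invariant either way and area is reported on the peak-normalized signal.

## Peri-CS histogram and response typing

Histograms cover [−100, +300] ms around each CS in 5 ms bins (80 bins;
width configurable, must tile the window). CS closer than 100 ms to the
recording start or 300 ms to its end are dropped so every window is
complete; windows may overlap (plain CS-triggered average). Rates are
counts/(n_cs · bin width); the sum rule
Σ rate·bin·n_cs = total windowed SS count holds exactly. Baseline is the
mean over [−100, 0) ms; pause end is the first post-0 bin whose rate
exceeds 25% of baseline (25% rather than 50% so that a half-depth
suppression does not mask the pause end).

The published four-way typing was done by visual inspection, so the
decision rule here is a package construction, explicit and configurable,
with defaults validated against the generator (held-out seeds; the
recovery requirement is ≥ 90% per type at 20 cells/type, 120 s):

1. Per-bin z = (rate − baseline)/SE over the post-pause window, with
   SE = √(baseline/(n_cs · bin width)) under a Poisson count model.
2. **Facilitation / suppression** fire on ≥ 2 consecutive bins with z > 2
   (resp. < −2).
3. **Oscillation** fires when a phase-locked damped-cosine matched filter —
   the baseline-subtracted profile projected onto
   −cos(2πfτ)·exp(−τ/100 ms), f on a 1 Hz grid over 25–70 Hz — exceeds
   2.7 noise SDs, and the profile has at least one bin above and one below
   |z| = 1.2. The template sign encodes the expected phase (a rate dip at
   pause end), which is what distinguishes ringing from noise peaks.
4. **Conflicts** between the oscillation detector and a run detector are
   resolved by model comparison: the matched-filter score is held against
   the best box-step score (sustained step over 25–150 ms from pause end);
   the better-fitting shape wins. Otherwise oscillation > suppression >
   facilitation, and normal is the fallback.

A plain band-limited periodogram peak (an earlier candidate rule) was
rejected during validation: with ~58 post-pause bins the null distribution
of the in-band maximum is heavy-tailed enough that normal cells exceed a
4× median-power threshold far too often, while phase information goes
unused. The matched filter uses both the expected envelope and the
expected phase and separates the classes cleanly at these counts.

Labels come with full diagnostics (z-scores, run lengths, matched-filter
score and frequency, step score, pause end). Below 50 CS a warning flags
the label as unstable.

`oscillation_signature_check` implements the reported empirical signature
of oscillation-type cells — SS rate within [35, 60] Hz (inclusive) and
whole-recording CV strictly < 0.32.

## Group statistics

All tests are thin wrappers over scipy.stats with the field's reporting
conventions fixed: **pooled-variance** (not Welch) unpaired t — recomputing
published t values from their printed group summaries matches the pooled
form; **no continuity correction** in the 2×2 Pearson χ² (matches the
published 9.835 on [[17,30],[6,51]], where the corrected value would be
≈ 8.6); two-sided p throughout with one-tailed as an explicit option;
post hoc method (Tukey HSD or Bonferroni-corrected pairwise t) always
caller-selected, never defaulted. `two_sample_t` accepts raw samples or
printed (mean, SD, n) summaries and gives identical results for matching
inputs. The wash-in effect is 100·(pre − post)/pre with pre = mean rate
over the 2 min before drug onset and post = mean rate over minutes 5–7
after onset, both literal. Degenerate cases (zero-variance paired
differences, all-identical ANOVA groups) are flagged rather than silently
propagated.

Per-lobule aggregation averages rate/CF-pause/CV2 within lobule and joins
the normalized zebrin staining intensity (soma/background ratio, averaged
ratio-then-average across sections; the raw convention that *high*
intensity means *weak* staining is preserved, never inverted).

## Determinism and problem sizes

Every generator takes an explicit integer seed; cohort cells use
seed + index so any cell can be regenerated alone and cohorts are
byte-identically reproducible (manifest and spike files). The test suite
and the acceptance script run at desk scale by design: cohorts of
47 + 57 cells at 120 s, 20 cells/type for classifier recovery, 24 seeds
for wash-in recovery — sizes at which the 2-SE acceptance bands are a few
percent of the target values.

## Known limitations

- The generator emulates rate structure, regularity, pauses and post-CS
  kernels, but not spike waveform overlap, bursting, behavioral-state
  modulation, or slow nonstationarities; passing recovery tests shows the
  analysis chain is correct and well-calibrated under the stated model,
  not that real recordings satisfy that model.
- Boosted (super-unity) kernel windows are locally Poisson rather than
  renewal (see above).
- The response-type thresholds are tuned to the generator's default
  kernels; markedly different kernel shapes or much lower CS counts will
  need re-validation (all thresholds sit in `ClassifierConfig`).
- Per-cell wash-in effects are deterministic given the spec (no across-cell
  effect heterogeneity); the published across-cell spread of wash-in
  reductions is not emulated.
- Cells are treated as independent units (as in the source analyses);
  there is no mouse-level nesting or mixed-effects modeling.
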