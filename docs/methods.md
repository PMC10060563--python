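# Methods

`painephys` reimplements, as a tested pipeline, the analysis chain that links
chronic-pain-induced depression-like behavior in mice to the intrinsic
excitability of anterior cingulate cortex (ACC) layer 2/3 pyramidal neurons:
current-clamp feature extraction, signed z-score composites for "resilience"
and "neuronal excitability", their per-animal correlation, and the group-level
statistical battery.  Because no per-animal data are published for this kind
of study, the package ships a synthetic cohort generator with full ground
truth, so every downstream estimate is checkable analytically or by
simulation.

## The model neuron and the stimulation protocol

Cells are simulated as leaky integrate-and-fire (LIF) neurons,

    C_m dV/dt = -(V - E_L)/R_m + I(t),

with spike-and-reset at `V_th`, reset to `V_reset`, and absolute refractory
period `t_ref`.  Units are mV, pA, ms, MΩ, pF; the membrane time constant is
τ = R_m·C_m/1000 ms.  An LIF was chosen over conductance-based models
deliberately: its closed forms

* rheobase = (V_th − E_L)/R_m,
* steady deflection ΔV = I·R_m,
* first-spike latency t₁ = τ·ln((V∞−E_L)/(V∞−V_th)),
* interspike interval ISI = t_ref + τ·ln((V∞−V_reset)/(V∞−V_th)),

make every feature extractor testable against an exact oracle.  Spikes are
rendered as a stereotyped 2 ms waveform (0.4 ms linear rise from threshold to
+30 mV, 1.6 ms decay to reset), so spike-shape measurements have a defined
answer (amplitude = peak − threshold, e.g. 80 mV for V_th = −50 mV).

The stimulation protocol is a family of ten square current steps from −300 pA
to +600 pA in 100 pA increments, sampled at 10 kHz.  Step timing is not part
of the protocol definition we inherited, so the package defaults to 200 ms
baseline, 500 ms step, 200 ms post — standard current-clamp practice; 500 ms
exceeds 12τ for the default cells, so the steady state used by the
input-resistance measurement is fully reached.  (The charging residual
e^(−T/τ) falls below 0.5% of ΔV just past 5.3τ.)

**Integration.**  Forward Euler at the sampling interval (0.1 ms), with one
refinement: the threshold-crossing time is interpolated within the sample and
the refractory clock starts there.  Without it, each spike is registered up
to one sample late and the lateness accumulates, which can shift fast-firing
sweeps (~100 spikes per 500 ms) by 2+ spikes relative to the closed form;
with it, simulated counts match the ISI solution to ±1 spike across random
parameter draws.

**Noise.**  `voltage_noise_sd_mV` (default 0.5 mV) is added per sample as
*measurement* noise on the recorded traces, not injected into the dynamics.
This keeps the membrane trajectory deterministic, so the ground truth
attached to each recording (exact spike times, counts, analytic rheobase) is
exact rather than itself an estimate.  Consequence: the generator does not
emulate noise-driven spiking near rheobase, channel noise, or adaptation —
passing tests say nothing about those regimes.

## Feature extraction

* **Spike detection** — upward crossing of −20 mV whose entering slope
  exceeds 20 V/s, reported at the first sample of the fast-slope run (spike
  onset), with a 2 ms lockout.  No criterion is standard across labs; this
  one is robust to 0.5 mV measurement noise because the crossing level sits
  ~50 mV above baseline.  Traces are assumed already low-pass filtered by the
  acquisition chain; optional Savitzky–Golay smoothing applies to the slope
  estimate only.
* **f–I curve** — spikes counted inside the step window per sweep; rate =
  count / step duration.
* **Rheobase** — the minimum current for one action potential, read off a
  monotone shape-preserving cubic (PCHIP) through (current, spike count) over
  the non-negative currents, evaluated on a 1 pA grid.  The search is
  restricted to the interval between the largest zero-count current and the
  smallest spiking current above it, so the estimate always lands in that
  half-open bracket (and hence within one 100 pA grid step of the true LIF
  rheobase).  Silent cells yield `None` plus a `rheobase_undefined` flag —
  never a number; cells spiking at every non-negative step return the
  smallest tested current flagged `rheobase_all_spiking`.
* **Input resistance** — R_in = 1000·ΔV/I in MΩ from the −300 pA sweep, with
  ΔV the mean over the last 100 ms of the step minus the mean over the 100 ms
  pre-step baseline.  The windows average ~1000 samples, which is why 0.5 mV
  sample noise moves R_in well under 1%.
* **Passive/AP shape** — RMP from the pooled pre-step baseline; τ from a
  single-exponential Levenberg–Marquardt fit (analytic Jacobian) to the first
  200 ms of the −300 pA step onset; AP threshold voltage at the last sample
  before dV/dt exceeds 20 V/s, amplitude = peak − threshold, half-width at
  half amplitude with sub-sample interpolation, averaged over the first three
  spikes of the lowest suprathreshold sweep.

Cells without a defined rheobase or a plausible R_in are flagged `excluded`
and never enter the composites.

## Behavioral screen

Per animal the table holds splash-test grooming (≤300 s), tail-suspension and
forced-swim immobility (≤360 s each), and six electronic von Frey
paw-withdrawal threshold (PWT) measures per paw per timepoint.  The inclusion
rule is a two-sided unpaired t-test of ipsilateral vs contralateral measures
(Welch by default): a nerve-injured (SNI) animal is included iff p < 0.05
*and* the ipsilateral mean is lower; a sham animal is included iff p ≥ 0.05.
Which six-vs-six comparison the criterion originally used is not documented;
ipsi-vs-contra within a session is the only one available from a single
timepoint, and the direction guard prevents a paradoxically *less* sensitive
operated paw from counting as a deficit.  Note that sham animals necessarily
fail this screen at the nominal α rate — an inherent property of the rule,
not a generator defect.

## Composites and the correlation

All z-scores use the sample SD (n−1) and are pooled across every experimental
group.  Per animal:

    resilience   = mean( z(splash), −z(TST), −z(FST) )
    excitability = mean over cells of mean( z(R_in), −z(rheobase) )

Signs are chosen so that higher always means "less depressed" / "more
excitable".  The mean (rather than sum) of signed z-scores is used; the two
differ by a constant factor, so the correlation coefficient is identical.
Ephys z-scoring pools across all QC-passing cells before animal averaging
(the documented procedure); z-scoring animal means instead is exposed as
`pooling="animal-means"`.  The final statistic is the ordinary least-squares
line of resilience on excitability with the Pearson r and its two-sided
p-value (Spearman optional).  Constant inputs raise an explicit
`ZeroVarianceError`; missing values exclude the animal with a warning, never
silently.

## Synthetic cohorts

The default cohort mirrors a 2×2 design — surgery (SNI/sham) × housing
(standard SH / extended enrichment ExEE), 4 animals per group, 3–8 cells per
animal.  Each animal draws a latent depression score d (group mean + N(0,
0.3²)) and a latent excitability score x = group shift + β(d − group mean) +
noise, with β = 0.6 by default.  Group means: d = 1.0 for SNI-SH (the
depressed phenotype), 0.2 for SNI-ExEE (largely rescued), 0 for shams; the
excitability shift of 1.0 in SNI-SH maps through the gains (30% R_m, −3 mV
V_th per unit) to a hyperexcitable injured group restored to sham level by
enrichment.  Behavior moves against/with d: splash 90 − 35·d ± 15 s, TST
120 + 60·d ± 20 s, FST 150 + 50·d ± 20 s, clamped to the session lengths.
Ipsilateral PWT follows a per-group time course over days −1, +7, +21, +42,
+56 (collapse to ~1.8 g under SNI-SH, partial recovery to ~3.8 g under
SNI-ExEE, flat ~4.5 g elsewhere); splash/TST/FST are scored at the final day
only.  These magnitudes are the package's choices of plausible effect sizes
for this assay battery; only the directions are anchored.

The **coupling benchmark** (`CohortConfig.coupling_benchmark`) isolates the
correlation mechanism: group means equalized, standardized latents with
corr(d, x) = 0.8, 16 animals × 6 cells, reduced latent-to-parameter gains so
rheobase stays inside the tested current range.  The measured pipeline r is
attenuated below the latent 0.8 by behavioral noise (3 assays), cell-level
noise (6 cells), and rheobase grid quantization — by design these stay small
enough that the recovered mean r lands within ±0.15 of −0.8 (observed ≈
−0.74 over 200 cohorts).  The **null benchmark** sets β = 0 with unit latent
variance; the r-test's false-positive rate then calibrates at α.

A single root seed spawns independent substreams for latents, behavior, and
each animal's cells, so changing the number of cells never reshuffles
behavioral draws; a config + seed reproduces the cohort bit-for-bit.

## Statistics battery

* **Two-way ANOVA** (surgery × housing, interaction) with Type-II sums of
  squares via statsmodels OLS — Type-II because the designs of interest are
  mildly unbalanced (7–8 per cell); it reduces to the classical decomposition
  when balanced.  Zero residual variance is reported as F = ∞ (non-zero
  effect) or 0, with a `zero_residual_variance` flag.
* **Mixed repeated-measures ANOVA** (between: group; within: timepoint) for
  the PWT time course, computed from the classical weighted-means partition:
  group tested against subjects-within-groups, time and group×time against
  the within-subject residual.  Implemented in-package because the available
  library routine fails outright on zero within-subject variance, a
  degenerate path this package must report as F = 0 rather than crash;
  the library remains the cross-check oracle in the tests.  Sphericity is
  uncorrected by default (usual practice for short time courses);
  `gg_correction=True` applies the Greenhouse–Geisser ε.
* **Post-hoc comparisons** over all pairs of design cells, using the fitted
  model's pooled MSE: Tukey (studentized range), Holm–Šídák (step-down
  1−(1−p)^(m−i+1)), or the Benjamini–Krieger–Yekutieli two-stage step-up FDR.
  The adaptive BKY stage can legitimately produce corrected values *below*
  the raw p (its m₀ estimate discounts true nulls); by default the reported
  values are floored at the raw p — a conservative convention that preserves
  the p_adj ≥ p contract users expect — with `clip_at_raw=False` exposing the
  uncapped two-stage values.
* **Unpaired t-tests** default to the Student pooled-variance form, so the
  reported df is n_A + n_B − 2 (the convention in the figure captions this
  battery mirrors); Welch is optional.  Zero-variance inputs resolve to
  t = 0, p = 1 (equal means, flagged) or ±∞, p = 0.

## What the validation does and does not show

The acceptance studies (see `scripts/acceptance.py`) demonstrate: exact
recovery of R_in and τ from noiseless and realistically noisy LIF traces;
rheobase bracketing within one current-grid step; spike counts within ±1 of
the closed-form ISI solution; bit-exactness of the composite statistics
against textbook formulas; recovery of a known animal-level coupling
(r ≈ −0.8) with correct sign in 100% of 200 cohorts; null calibration of the
r-test and of the ANOVA interaction test; and reproduction of the qualitative
group pattern (lowest resilience and highest excitability in SNI-SH) in
essentially all default cohorts.  Problem sizes — 200 cohorts for the
correlation studies, 100 for the pattern study, 1000 null datasets at 4
observations per cell for ANOVA calibration — were chosen to keep Monte-Carlo
error well below the tested margins.

They do **not** show robustness to real-recording pathologies: bridge-balance
errors, electrode drift, sag/rebound (no h-current in the LIF), adaptation,
seal quality, or morphology-dependent heterogeneity.  The generator's group
effect sizes are plausible, not fitted; published F and p values from any
particular animal cohort are not reproduction targets, since the underlying
per-animal data are unavailable.
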