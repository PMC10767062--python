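# Methods

This note records the models, conventions and open design choices behind
`cortrack`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Envelope extraction

The acoustic feature is the amplitude envelope obtained from a cochleagram:
the waveform is decomposed by a bank of gammatone band-pass filters whose
centre frequencies are equally spaced on the ERB-rate scale,
`ERBrate(f) = 21.4·log10(1 + 0.00437·f)`; each subband envelope is the
magnitude of the analytic (Hilbert) signal of the filtered waveform; the
subband envelopes are averaged into a single nonnegative envelope.  The
bank defaults to 38 filters between 30 Hz and 7.5 kHz — common cochleagram
practice; the count and range are configurable because no single canonical
choice exists.  The analytic-magnitude operator was chosen over
half-wave-rectification-plus-smoothing because it is parameter-free and
exactly homogeneous in amplitude.

The envelope is then band-passed 1–9 Hz with a 4th-order Butterworth
filter applied forward–backward (zero phase; the effective magnitude
response is squared) and resampled to the 64 Hz analysis rate with a
delay-compensated polyphase FIR.  Zero-phase filtering preserves the
temporal alignment on which lagged decoding depends; its ringing can push
envelope samples slightly below zero, which is harmless for
correlation-based scoring.

Epoching drops the first 500 ms of each 60 s trial (stimulus-onset
response) and cuts consecutive 30 s epochs.  59.5 s does not divide evenly
into 30 s, so the second epoch of each trial is the residual 29.5 s
segment: this preserves the two-epochs-per-trial count while keeping the
audio and EEG epoch grids sample-identical (both modalities are cut by the
same function with the same parameters).  A trailing fragment is emitted
only if it is at least half an epoch long.

## Decoder

Conventions, fixed and documented:

* **Lag window.** Integer shifts from `floor(t_min·fs)` to
  `floor(t_max·fs)` inclusive.  For the canonical window −0.2…+0.35 s at
  64 Hz this gives −13…+22, i.e. 36 shifts including zero.  Flooring both
  bounds is the one rounding convention that reproduces that printed
  count; it is applied uniformly.
* **Design matrix.** Column (n, τ) at row t holds `d(t+τ, n)`;
  out-of-epoch samples are zero-filled (the TRF-toolbox convention; row
  trimming was rejected so that `ŝ` keeps the epoch length).  Columns are
  channel-major then lag.
* **Ridge solve.** `(DᵀD + λI) g = Dᵀ s` via a Cholesky-backed
  positive-definite solve, never an explicit inverse; `λ = 0` on a
  rank-deficient design falls back to the minimum-norm solution with a
  warning.
* **Standardization.** EEG channels and envelopes are z-scored per epoch
  before fitting.  Pearson scoring is invariant to this; it only
  conditions the ridge grid.
* **Nested LOO.** Outer LOO over epochs; inner LOO over the remaining
  epochs scores each λ in the grid (default 10⁻⁶…10⁶ by decades) by mean
  inner-fold Pearson r; ties break toward the larger λ (more
  regularization); the winning λ is refit on the *whole* training set
  (not averaged over inner folds) before reconstructing the held-out
  epoch.  Training epochs are stacked by summing their per-epoch Gram
  matrices, so lags never bridge epoch boundaries.  The inner loop reuses
  one eigendecomposition per fold across the whole λ grid.

Whether the original custom analysis z-scored, averaged inner-fold models,
or refit after selection is unreported; the choices above are flagged as
conventions, not facts about that analysis.

## Synthetic studies

No EEG from the experiment is deposited, so the generator defines the
study conditions under which every stage is validated by recovery:

* **Design.** 8 stimuli (first half designed familiar) × 2 presentations
  × 60 s trials per subject, 21 channels at 64 Hz, 30 s epochs (32 per
  subject); all counts configurable.
* **Envelopes.** Band-limited (1–9 Hz) Gaussian noise, offset/rectified
  to be nonnegative, re-band-limited and re-offset.  Real music envelopes
  share the band limits and nonnegativity but not, e.g., note-onset
  sparsity or metrical structure — tests passing on these envelopes show
  the machinery works, not that music-specific temporal structure is
  captured.
* **Forward model.** Each channel is the causal convolution of the
  envelope with a channel-specific kernel (damped 1–7 Hz oscillation,
  random phase/decay/topography, support 0–350 ms — matching the decoder's
  post-stimulus window) plus 1/f-amplitude noise scaled so the channel-wise
  RMS signal:noise ratio equals the trial's SNR.  With zero noise the
  multichannel system is generically exactly invertible over the lag
  window, which is what makes noise-free decoding a sharp test (r ≥ 0.99).
* **Condition effects.** Realized SNR = `snr_map[familiarity, mw_group] ×
  subject_effect × stimulus_effect` with log-normal multiplicative subject
  and stimulus effects — the multiplicative analogue of the crossed
  random-intercept structure fitted downstream.  The default map (0.25
  baseline, 0.35/0.20 familiar/unfamiliar in the high-mind-wandering
  group) plants the familiarity-by-mind-wandering dissociation; these
  values are calibration knobs of the generator, not empirical facts.
* **Questionnaire.** Familiarity answers follow the configured confusion
  probabilities (defaults: P(Yes | familiar) = 0.80,
  P(No or Not sure | unfamiliar) = 0.67, the reported agreement rates),
  with No/Not sure split evenly.  Mind-wandering answers come from a
  per-subject latent propensity on [0, 1] (designed low/high groups at
  0.32/0.68 ± 0.1) plus trial noise (SD 0.15), quantized into the four
  quartile bins.
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in a fixed order; identical configs reproduce a study
  bit-for-bit, including its serialized form.

`simulate_accuracy_study` is the scaled-down companion for inference
calibration: it plants effects directly on the per-epoch accuracy response
under the same crossed random-effects model (defaults: 12 subjects ×
8 stimuli × 2 presentations × 2 epochs, residual SD 0.05, subject SD 0.03,
stimulus SD 0.02, grand mean 0.06 — the scale of published reconstruction
accuracies).  Selection-consistency and type-I studies use it because
simulating EEG adds computation but no information about the inference
stage.  Planted effect sizes for the replicated power checks (0.03 for
selection consistency, 0.035 for the dissociation) were fixed a priori by
power arithmetic on this design.

## Behavioral coding

High familiarity ⇔ first-presentation answer Yes (No/Not sure → Low); the
code propagates to both presentations.  Mind wandering: bin midpoints
(12.5/37.5/62.5/87.5), subject mean over all trials, split at the grand
mean of subject means — a subject exactly at the grand mean codes Low
(deterministic, conservative toward the larger Low group).  The grand mean
is computed over subject means rather than pooled trials (a convention;
the two differ only in unbalanced data).  Missing answers are hard errors,
never imputed.

## Group inference

The mixed model `y = Xβ + Z_s b_s + Z_g b_g + ε` with crossed Subject and
Stimulus intercepts is fitted by profiled (RE)ML over the relative variance
ratios, using the Woodbury identity so each likelihood evaluation is
O(n·q²).  Three starts of L-BFGS-B on the log-ratio scale guard against
local optima; ratios below 1e−7 are pinned to zero with a singular-fit
warning.  The fit matches R's lmerTest to ~6 significant figures on shared
data (a subprocess oracle test), and its restricted likelihood is never
inferior to statsmodels MixedLM's on the same problem.

* **Satterthwaite dof.**  For a contrast c,
  `dof = 2·f² / (∇fᵀ A ∇f)` with `f(ν) = cᵀ Cov(β̂|ν) c` on the variance
  scale and `A = 2·H⁻¹`, H the finite-difference Hessian of the −2
  restricted log-likelihood at the estimates — the construction lmerTest
  uses.  Degenerate curvature falls back to the residual dof.
* **Elimination.**  Phase 1 tests each random intercept by REML
  likelihood ratio (retain if p < α_random = 0.1; boundary p-values are
  deliberately not halved, matching the convention of the elimination
  table this mirrors).  Phase 2 repeatedly drops the
  marginality-respecting fixed term with the largest Satterthwaite-F
  p ≥ α_fixed = 0.05, refitting after each drop.  The full trace is
  emitted.  **Known limitation:** backward elimination's *familywise*
  false-retention under a global null is ≈ 1−(1−α)^k for k candidate
  terms (~30% for the 7-term factorial), even though each individual
  term's test is correctly α-calibrated; the procedure's per-term
  calibration is what the test suite asserts quantitatively.  Fixed-effect
  LRT comparisons use ML fits; reported variance components use REML.
* **Effect scaling.**  Standardized coefficients come from refitting on
  the z-scored response with ±0.5-coded binary predictors, so a
  standardized β is the between-level difference in response SDs.
  Treatment coding makes every reported β an explicit High−Low (or
  Second−First) contrast: positive familiarity β ⇒ familiar stimuli
  reconstruct better.
* **R².**  Variance partition: marginal = var(Xβ̂)/total, conditional
  adds the random-intercept variances to the numerator.
* **Permutation null.**  The null accuracy of an epoch is its
  reconstruction scored against envelopes of *other* epochs of the same
  subject (self-pairs excluded), averaged over seeded random mismatches;
  per-subject observed and null means enter a paired t test with
  Cohen's d = mean(diff)/SD(diff).  The mismatched-pairing construction is
  a convention (standard in stimulus-reconstruction work); the original
  analysis does not document its null.

## Numerical and degenerate-input behaviour

Constant traces make Pearson r undefined and raise; single-epoch subjects
cannot be mismatched and raise; a rank-deficient fixed-effects design
raises with an explicit message instead of a solver error; factors with a
single observed level are dropped from the elimination with a warning.
Likelihood-ratio tests of identical models return (0, 0 dof, p = 1).

## Problem sizes

The shipped tests and the acceptance script run at desk scale as the
package's own verification conditions: 4–10 subjects and 2–8 channels for
decoding checks, 12 subjects × 384 epochs × 100 replicates for the
inference calibration studies, and an 8-subject, 8-channel full-design
study for the end-to-end acceptance run.  All scale linearly in subjects
and quadratically in (channels × lags); the full 41-subject, 21-channel
configuration runs unchanged, only longer.
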