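# Methods

`glombg` analyzes wide-field calcium-imaging recordings of olfactory-bulb
glomeruli during a go/no-go target-odor recognition task in background
odors, and ships a synthetic session generator so every analysis stage can
be validated against known ground truth.

## Trial structure and acquisition model

Each trial is acquired at 20 Hz, 13.2 µm/pixel: 7 s of clean air, onset of
a variable background odor (one of four), the fixed background
((s)-(−)-limonene) 750 ms later, the target odor another 750 ms later, and
3 s of the full mixture. Backgrounds are delivered at 0.1 % of saturated
vapor pressure, targets at 0.025 %. Eight mixtures (4 variable backgrounds
× go/no-go target) make up a session. Outcomes are hit / miss on go trials
and correct rejection / false alarm on no-go trials; the lick, when it
occurs, follows the target by ~1.2 s.

## Preprocessing

1. **Registration.** Each trial's temporal-mean frame is registered to a
   common reference by phase cross-correlation; the translation is
   corrected with an exact integer roll. Only translation is modeled: the
   generator drifts rigidly, and no downstream statistic uses affine
   structure.
2. **dF/F0.** Per pixel, F0 is the temporal mean of the 7-s air window
   preceding the first background onset; the movie becomes
   (F − F0)/F0. Non-positive F0 is an error naming the pixel.
3. **Spatial band-pass.** Per frame,
   `out = G(39 µm) ∗ (in − G(199 µm) ∗ in)`:
   the wide Gaussian estimate of the diffuse component (feedback axons,
   slow global signals) is subtracted, then pixel noise is smoothed with
   the narrow Gaussian. "Radius σ" is interpreted as the Gaussian standard
   deviation; kernels are truncated at 4σ and boundaries use reflect
   padding (the even-symmetric extension; numpy's "symmetric"). Filtering
   is purely spatial. The dF/F0 → filter order is fixed and asserted by
   tests; swapping is not equivalent.

   Useful closed forms (verified against a dense-convolution oracle): a
   Gaussian blob of scale σ_b passes with peak ratio
   σ_b²/(σ_b²+σ_h²) − σ_b²/(σ_b²+σ_l²+σ_h²); a 40-µm glomerulus passes at
   0.475 of its amplitude, a 600-µm diffuse structure at < 0.10 (on fields
   large enough to contain it; ≥ 192 px at 13.2 µm/px).

## ROI quantification

ROIs are an integer label mask (inputs, or generator ground truth). The
per-frame ROI value is the mean band-passed dF/F0 over the ROI's pixels;
the trace is z-scored per trial against its own 7-s air window
(population-SD convention, `sd_ddof` configurable; the pixel-level
z-then-average ordering is available behind `pixel_level=True`). Windowed
responses are arithmetic means over frames whose onset time falls in the
half-open window: `air` [−7, 0) s before the first background;
`background_pre` [−1, 0) s, `target_500ms` [0, 0.5) s and `target_1s`
[0, 1) s around target onset; plus 1-s sliding windows at chosen centers.
The long-format ResponseTable — one row per (trial, ROI, window) mean z,
with trial metadata merged in — is the single input to all statistics.

## Statistics

* **Discriminability.** Per mixture, the population vector is the
  per-glomerulus mean `target_500ms` z over correct trials, unit
  normalized. Glomeruli enter if any mixture's trial-averaged response
  exceeds 1 z in either condition (the set is computed jointly so vectors
  are comparable across conditions). Separability is the maximum dot
  product with the opposite-valence vectors; the naive→expert change is
  tested with an exact two-sided sign test (ties dropped).
* **Variability.** CV = SD/mean (sample SD by default) of `target_1s`
  responses over correct rejections, gated by: ≥ 20 correct rejections per
  session, at least one no-go mixture with trial-averaged response > 1 z
  per ROI, ≥ 6 repeats and mean ≥ 0.1 z per (ROI, mixture). The
  trial-matched control subsamples the condition with more repeats
  (without replacement, seeded; one draw by default, averaging optional).
  Conditions are compared by paired two-sided t test on per-animal means.
* **Background coupling.** Per (ROI, mixture), Pearson r across trials
  between the `target_1s` response and a 1-s sliding window at offsets
  spanning air and background periods; averaged over ROIs, then animals.
* **Trial split / coding improvement.** Per variable background odor,
  trials at or below the 25th / at or above the 75th percentile (linear
  interpolation) of mean background-period activity across included
  glomeruli form the low/high groups (thresholds over all trials; group
  vectors from correct trials). Coding improvement = similarity on high
  minus low trials; positive means low background activation improves
  separability. A mixture without a correct trial in a group drops out of
  that comparison.
* **Suppression.** Per (animal, background odor), the mean
  `background_pre` response of included glomeruli, naive vs expert;
  "suppressed" = expert < naive, tested with a one-sided exact binomial
  test (smaller tail). All trials enter these means by default — the
  background window closes at target onset, before any lick — with a
  correct-only switch. The same computation on `target_1s` over correct
  rejections is reported as a specificity check.
* **Sniffing.** Inhalations are negative airflow deflections crossing an
  adaptive threshold (2 × a robust MAD-based SD of the lightly smoothed
  trace, floored at 2 % of the peak so noise-free traces still threshold
  sensibly), with a 100 ms refractory period; detection is invariant to
  amplitude scale. Rates are counts per half-open window; the sniff CV is
  SD/mean of per-trial counts in `target_1s`; modulation is tested with
  paired t tests on per-animal rates (background − baseline,
  target − baseline).
* **Exact count tests.** Tail probabilities are integer/rational sums, so
  sign and binomial p-values are exact at any n used here. Two-sided =
  doubled smaller tail, capped at 1; one-sided = the tail in the observed
  direction. These conventions reproduce the published values
  (51/64 → 1.88×10⁻⁶, 26/32 → 5.35×10⁻⁴, 24/32 → 0.007, 29/31 → 2.31×10⁻⁷,
  7/16 → 0.40).

## The synthetic generator

Movies are a flat baseline (1000 counts) plus, in dF/F0 units: a
spatially uniform respiration sinusoid (3 Hz — whole cycles fit the air
window, so the noise-free air mean conserves the baseline); an
odor-locked diffuse Gaussian random field (σ = 600 µm, pointwise SD 0.01
dF/F0, normalized by the analytic stationary SD of the smoothed field);
glomerular responses; a lick-triggered ramp on lick trials starting 0.2 s
before the lick; and Gaussian shot noise (SD 40 counts).

Glomeruli are Gaussian footprints (σ = 40 µm) on a jittered grid with a
configurable center pitch (`glomerulus_spacing_sigma`, default 4 σ
≈ 160 µm). The validation and calibration studies use 10 σ (~400 µm):
those ROIs model the manually drawn, well-separated responsive glomeruli
of a real analysis rather than the full glomerular tiling, because at
dense packing the band-pass surround subtracts each ROI's neighborhood
average, which shrinks response means and inflates CV estimates. Tuning: each odor activates a Bernoulli subset
of glomeruli (targets 29.5 %, backgrounds 43.5 %), with lognormal
amplitudes (CV 0.4; background mean 1.0, target mean 0.6 in tuning
units). Calcium kinetics are a single-exponential rise (τ = 80 ms) and
decay (τ = 400 ms). `response_amplitude_dff = 0.012` converts tuning units
to dF/F0 and is calibrated so included-glomerulus background responses
sit near 1 z (the reported naive/expert anchors are 1.04 and 0.70) with
1-s target-window responses around 1.5-2 z.

**Gains.** Trial-to-trial variability is multiplicative and lognormal
(σ² = ln(1+CV²); mean 1). Background components carry a pre-target gain
g_bg and a post-target gain g_bg_post whose Pearson correlation is
exactly `gain_coupling_rho` (copula correlation
ln(1+ρ·CV²)/ln(1+CV²)); the target component carries an independent gain.
Half the gain log-variance is shared across glomeruli within a trial
(global excitability), half is private. The shared component is what lets
a selection on the trial's mean background response shift the whole
background pattern coherently — the first-order mechanism behind the
high/low-background coding-improvement effect; a single post-target gain
would fix each trial's pattern composition and null that effect. The
composite 1-s target-window gain (amplitude- and kinetics-weighted
mixture of g_bg_post and the target gain) is stored per (trial,
glomerulus) as the ground truth that variability analyses recover.

Condition defaults: naive — gain CV 1.5, ρ = 0.5, amplitude scales 1,
accuracy 0.6; expert — gain CV 1.05, ρ = 0.2, background amplitude × 0.7,
target amplitude × 1.3 (the trained condition's target-window means are
~1.3× larger while background responses shrink), accuracy 0.78.
Behavioral outcomes are Bernoulli with those accuracies; lick latencies
are normal (1.18 ± 0.3 s, floored at 0.55 s). Sniffing is a gamma-renewal
inhalation process (shape 4) with per-window rates — naive flat at 2 Hz;
expert 1.5 / 2.0 / 2.5 Hz over baseline / background / target — rendered
as biphasic airflow pulses at 100 Hz. The movie respiration sinusoid and
the airflow trace are separate processes and are not phase-locked.

## What the generator does and does not emulate

It reproduces the trial structure, activation fractions, response
magnitudes in z units, trial-to-trial gain statistics, background–target
coupling, condition contrasts, lick-locked premotor activity and
sniff-rate profiles. It does not model biophysical circuit dynamics,
photon-level camera noise, hemodynamics, photobleaching, within-trial
motion, behavioral learning across sessions, or sniff-locked fluorescence
oscillations. Passing recovery tests therefore shows the pipeline
correctly measures these statistical structures — not that real
recordings contain no other structure.

## Numerical choices and degenerate inputs

Half-open windows by frame-onset time everywhere; 0-based (row, column)
coordinates; seconds from acquisition start. Population SD for z-scoring
(air mean ≈ 0, SD ≈ 1 by construction), sample SD for CVs; both
configurable. Zero-variance inputs are errors (z-scoring, Pearson r) or
dropped with a reason (coupling rows); zero-norm population vectors are
errors unless a subgroup analysis explicitly tolerates missing mixtures.
Ties: exact similarity ties leave the sign test's n; degenerate trial
splits (P25 = P75) exclude the odor's trials. Percentiles interpolate
linearly between order statistics; "highest 75th percentile" is read as
the top quartile (≥ P75).

## Known estimator properties worth remembering

The sample CV of heavy-tailed lognormal gains is biased downward
(≈ −23 % at CV 1.5 with 30 repeats); recovery is therefore checked
against the CV of the stored ground-truth gains of the same trials, and
recovered CVs sit below the configured parameters at finite n. The sample
Pearson correlation of lognormal pairs is noisy (SD ≈ 0.11 at n = 200)
and slightly inflated at small n; the measured background–target r is
also attenuated a few percent by the independent target-component gain.
The high/low trial split retains a small positive improvement tendency
even at ρ = 0 (selection interacting with heavy-tailed shared gains);
the null check bounds |mean| by 2 SEM rather than asserting exact zero.

## Problem sizes

Validation cohorts run the full movie pipeline at reduced scale —
12–16 glomeruli at 400 µm spacing on ~1.1 × 1.5 mm fields of view,
40–96 trials per condition, 4–8 synthetic animals — chosen so the whole
suite completes in minutes while every recovery stays statistically
resolvable. The published values for the corresponding real-data
quantities (CV 1.49→1.06, coupling 0.46/0.53, background z 1.04→0.70,
expert/naive ratios 0.72 vs 1.10) are not reproducible without the
study's recordings; they serve as the generator's calibration defaults,
and the tests recover the generator's configured conditions instead.
The naive→expert increase in population-vector separability needs
study-scale trial counts (~150+ trials per condition) to emerge from the
attenuation noise of naive vectors; at the validation scale the tests
assert its ingredients (suppression, coupling, CV) rather than the
full-size sign test.
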