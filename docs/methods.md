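# Methods

## The synthetic study

The generator (`alkanir.simulate`) stands in for a feeding study whose raw
data (48 excreta spectra and GC alkane measurements) are not available as a
dataset.  It emulates exactly the features the downstream analysis relies
on, and nothing more.

**Design.**  48 hens in two diet groups of 24: a commercial feed with
minimal alkane content, and the same feed with a mass fraction
q = 0.01 of alfalfa replacing feed (`alfalfa_inclusion`; composing the
mixed diet as a convex combination (1−q)F + qA keeps the mixing equation's
premise exact — at q = 0.01 the difference from "1% on top", q = 1/101, is
below 1% relative and both are supported by setting the field accordingly).
Intakes and outputs are Normal(110, 5) and Normal(30, 1.2) g DM/day,
plausibly scaled for laying hens; non-positive draws are redrawn and never
emitted.

**Mass balance.**  True excreta concentrations satisfy
`output · E = intake · D · R` exactly, with group-level recovery fractions
R per alkane (defaults from the fecal-marker literature for this system:
0.297–0.479 depending on alkane and diet).  Because R is a group constant,
inverting the balance recovers it exactly, and the whole
recovery-adjustment → NNLS → proportion chain is an identity at zero
measurement noise.  This is the backbone of the end-to-end tests: with
`analytic_cv = 0` the estimated inclusion equals q to machine precision for
every animal and subset.

**Measurement noise.**  The "laboratory" table multiplies true
concentrations by a mean-one lognormal with per-alkane CV (`analytic_cv`).
This single term aggregates GC analytic error *and* residual animal-level
variation (individual recovery differences, digesta heterogeneity): the
exact group-level mass balance leaves no other per-alkane noise channel, so
the calibrated default CVs are larger than pure assay repeatability for the
low-concentration alkanes (C25 ≈ 5%, C27 ≈ 13%, C33 ≈ 15%) and 3% for the
alfalfa-dominated C29/C31.

**Calibration of the defaults.**  `default_design()` solves the feed and
alfalfa profiles and the analytic CVs in closed form so that the pooled
excreta concentrations (n = 48, both groups) have the target marginal
means/SDs of the emulated population — C25 1.98 ± 0.18, C27 2.46 ± 0.39,
C29 4.97 ± 2.21, C31 4.71 ± 2.87, C33 1.76 ± 0.33 mg/kg DM.  The pooled
variance splits into a within-group part (intake/output ratio CV ≈ 6%,
analytic CV) and a between-group separation δ.  For C29/C31 the separation
is solved from the SD budget (δ ≈ 2.2 and 2.8 mg/kg DM — the diet-group
bimodality), which places the alfalfa profile at ≈ 274 and ≈ 302 mg/kg DM;
these are deliberately solved from the excreta targets rather than fixed at
nominal literature values for alfalfa wax (≈ 290/360), which would
overshoot the pooled SDs by >10% given the recovery fractions.  For the
unimodal alkanes a small separation is imposed (0.08–0.17 mg/kg DM) and the
analytic CV absorbs the remainder.  A convergence test at n = 500 per group
verifies the moments to 5%.

**Spectra.**  Forward model on the 4000–10000 cm⁻¹ grid at 2 cm⁻¹:
per-alkane sums of three Gaussian bands in the C–H combination
(≈ 4250–4390 cm⁻¹) and first-overtone (≈ 5650–6060 cm⁻¹) regions, shifted
per alkane so the five signatures are linearly independent; a common
5-band matrix background; then per sample a log-normal multiplicative
scatter factor (SD 0.05), a random quadratic baseline (coefficient SDs
0.01/0.005/0.002 on a normalised axis), and white noise (SD 2·10⁻⁵ AU).
Band positions and amplitudes are free parameters chosen for physical
plausibility — they matter only through linear independence and
signal-to-artifact ratios.  No instrument physics (scan averaging,
resolution convolution) is simulated.  With all artifact SDs at zero the
spectra lie exactly in the span of the signatures plus background, so PLS
recovers concentrations to < 10⁻⁶ — the noise-free oracle used in tests.

What the generator does **not** emulate: nonlinear detector response,
wavelength-correlated noise, moisture/particle-size confounders, per-animal
recovery variation as a separate channel, or real GC error structure.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the *procedure*, not field performance on real excreta.

## Preprocessing

SNV centres and scales each spectrum (sample SD, divisor n−1).  MSC
regresses each spectrum on a reference learned from calibration samples
only (mean calibration spectrum) and corrects (s−a)/b; the context object
makes the train-only provenance explicit and is refit inside every CV fold.
The Savitzky–Golay second derivative uses polynomial order 2 — the minimum
supporting a second derivative, which makes the 3-point window coincide
with the exact central finite difference — and trims (w−1)/2 points per
edge rather than padding, so no fabricated values enter the regression.
Smoothing windows are the odd values 3–21.  The grid is
{none, SNV, MSC} × {no derivative, (2, w)} = 33 treatments.  Scatter
correction defaults to running before the derivative; both orders are
implemented (`TreatmentSpec.order`) since the composition is genuinely
ambiguous in practice, and they differ on scattered spectra.

## Calibration

The 40/8 split stratifies within each diet group by reference quartile
(stable sort, remainders to lower intervals, one uniformly drawn validation
sample per cell), guaranteeing four non-empty strata per group despite the
C29/C31 bimodality.  The split is computed per alkane.

PLS1 is NIPALS on mean-centred, unscaled data, with per-component
coefficient paths (rotations W(PᵀW)⁻¹ accumulated incrementally) so one fit
serves all component counts 1–10.  Degenerate residuals truncate the path;
beyond the effective rank the coefficients are constant.  At full rank the
coefficients equal OLS on centred data, and the first weight vector is
proportional to Xᵀy — both are test oracles, alongside an independent
cross-check against scikit-learn's PLS implementation.

Selection minimises LOOCV RMSECV over treatment × component count; ties
break toward fewer components, then grid order.  RMSE uses divisor n on all
three sets for comparability; R² is 1 − SSres/SStot with the mean from the
evaluation set (the squared-Pearson variant is available separately).
RMSECV is read as the selection criterion; the external set stays untouched
until final reporting, enforced by a leakage guard that errors on any
calibration/validation overlap.  Treatments without learnable parts (SNV,
plain derivative — per-spectrum operations) are transformed once before the
fold loop; this is exactly equivalent to per-fold refitting and is verified
against a brute-force fold loop to 10⁻¹².

## Agreement

Differences are predicted − reference (positive bias = overprediction),
plotted against predicted values.  Limits of agreement are bias ± 1.96·SD;
their confidence intervals use the classic approximation
SE = SD·√(1/n + 1.96²/(2(n−1))) with t quantiles (at n = 8 the t-based and
normal variants differ by < 5%; t is implemented).  The SSEP decomposition
regresses d on the predicted values: SSEP = n·d̄² + b̂²·S_PP + SSE is an
exact identity, so the bias/slope/residual shares sum to 100%.

## Diet estimation

Recovery R = (output·E)/(intake·D) per animal and alkane; adjustment
divides by the diet-group mean recovery (division, not multiplication, is
forced by the mass balance).  The group means are computed from the same
dataset being analysed — an accepted circularity in this design.  NNLS is
Lawson–Hanson (scipy); collinear source patterns are flagged.  The
proportion is p = x_a/(x_a + x_f); if both coefficients are zero
(degenerate inputs only) p is missing and excluded from summaries with a
logged count.  Summaries use the population variance (divisor n) so
RMSE² = bias² + var holds exactly; proportions are stored as fractions and
rendered in percent at 3 significant figures.  The combination search
covers all 26 subsets of sizes 2–5.

## Pipeline and reproducibility

`run_full_pipeline` composes the stages on one simulated study, producing
NIRS predictions for all 48 samples from each alkane's selected model,
agreement statistics on the 8 validation samples, and diet estimates from
both the laboratory and the NIRS tables (two report columns throughout).  A
master seed feeds independent substreams (simulation, per-alkane splits,
replicates) via spawn keys; identical configuration and seed give
byte-identical CSVs, recorded in a manifest with a config hash and package
versions.  Every model-selection decision is logged, and the exhaustive
candidate table (33 × 10 evaluations per alkane) is written as the audit
trail.

Problem sizes in the shipped drivers and checks — one 48-animal study with
full-grid calibration, 20-replicate concentration-only experiments, n = 500
per group for moment convergence — keep any single stage under about half a
minute on one CPU while leaving the statistical conclusions stable.

## Known limitations

* The NIRS predictions here are *better* than the simulated laboratory
  values for the diet-sensitive alkanes, because spectra derive from true
  concentrations while the lab table carries the analytic noise; on real
  data the ordering is typically reversed.  The package reports both
  sources precisely so this comparison is visible.
* The raw-vs-preprocessed advantage (scatter correction + derivative
  beating raw spectra in RMSECV) is asserted for the alkanes whose
  reference-noise floor is low (C25, C29, C31); for C27/C33 the ~13–15%
  reference CV dominates and masks the preprocessing effect.
* Only two dietary sources are supported, proportions only (no intake
  quantities), and no alkane-selection methods beyond the exhaustive
  2–5-subset search.
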