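# alkanir

Near-infrared spectroscopy (NIRS) calibration of n-alkane concentrations in
laying-hen excreta, and recovery-corrected estimation of the dietary alfalfa
proportion from those concentrations.

## The problem

Odd-chain plant-wax n-alkanes (C25, C27, C29, C31, C33) are indigestible
dietary markers: the alkane pattern in a hen's excreta reflects the mix of
feed sources it ate.  In free-range systems this allows estimating how much
of the diet came from plants such as alfalfa (*Medicago sativa*).  The
reference assay (GC after saponification and SPE clean-up) is slow and
expensive; NIRS on dried excreta is a cheap surrogate, if a calibration can
predict the alkane concentrations accurately enough to survive the
downstream mixing-model arithmetic.

This package implements that full chain as a tested, seedable analysis over
a synthetic study of 48 hens (24 on a commercial feed, 24 with a 1% alfalfa
inclusion), whose generator reproduces the statistical structure the
analysis needs — target marginal moments of the pooled excreta
concentrations, diet-group bimodality in C29/C31, an exact marker mass
balance, and NIR spectra with multiplicative scatter and baseline drift.

## The method

1. **Preprocessing** — window 4000–7500 cm⁻¹; scatter correction (SNV or
   MSC) and/or Savitzky–Golay second derivative (windows 3–21, polynomial
   order 2, edges trimmed); 33-cell treatment grid.
2. **Calibration** — per alkane: stratified 40/8 calibration/validation
   split (4 reference quartiles × 2 diet groups, one validation sample per
   cell); PLS1 regression (NIPALS, mean-centred, no scaling); exhaustive
   search over treatment × component count (1–10) by leave-one-out RMSECV
   with the learnable pipeline refit in every fold; external validation on
   the 8 untouched samples.
3. **Agreement** — Bland–Altman bias and 95% limits of agreement with
   t-based CIs, plus the decomposition of the sum of squared prediction
   errors, SSEP = n·d̄² + b̂²·S_PP + SSE, into bias/slope/residual shares.
4. **Diet estimation** — per-animal recovery rates
   R = (output·E)/(intake·D), adjustment E\* = E/R̄(group), non-negative
   least squares on x_f·F + x_a·A = E\*, proportion p = x_a/(x_a + x_f),
   and MSE = bias² + variance summaries over all 26 alkane subsets of sizes
   2–5.

## Worked example

The analysis is a sequence of numbered drivers; each prints what it found
and writes its tables under `results/`:

```sh
python analysis/01_simulate_study.py     # study bundle + spectra
python analysis/02_calibrate_models.py   # per-alkane PLS model selection
python analysis/03_agreement.py          # Bland–Altman + SSEP shares
python analysis/04_estimate_diet.py      # recovery-corrected NNLS estimates
python analysis/05_noise_replicates.py   # noise sensitivity, 20 replicates
```

With the default seed the simulation reproduces the target pooled excreta
statistics (`01`):

```
alkane     mean  target      sd  target
C25       1.977    1.98   0.175    0.18
C29       4.922    4.97   2.186    2.21
C31       4.623    4.71   2.818    2.87
```

calibration picks scatter-corrected treatments and calibrates the
diet-sensitive alkanes C29/C31 nearly perfectly while the low-variance
alkanes stay noise-limited (`02`):

```
C25: treatment 2,17,1+MSC   A=4  RMSEC=0.009 RMSECV=0.101 R2cv=0.69
C29: treatment 0,1,1+MSC    A=10 RMSEC=0.000 RMSECV=0.161 R2cv=0.99
C31: treatment 2,9,1+MSC    A=2  RMSEC=0.072 RMSECV=0.183 R2cv=1.00
```

and the diet estimation recovers the simulated 1% inclusion from both data
sources (`04`):

```
lab/alfalfa:  mean 1.010%  RMSE 0.142  bias +0.010
nirs/alfalfa: mean 1.005%  RMSE 0.097  bias +0.005
```

i.e. the mixed-diet group's estimated alfalfa share of dietary dry matter is
within ~0.01 percentage points of the true 1%, and the control group stays
near zero (mean 0.02%) — small positive values are the price of the
non-negativity constraint under noise.

Equivalently in one call:

```python
from alkanir import PipelineConfig, run_full_pipeline, write_outputs
result = run_full_pipeline(PipelineConfig(seed=1))
write_outputs(result, "results/full_run")
```

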