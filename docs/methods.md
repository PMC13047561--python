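# Methods

## The problem

Mango is a climacteric fruit: ripening continues after picking, so the
harvest date controls both eating quality and shelf life, and skin
colour is a poor cue.  The workflow implemented here couples a
non-destructive measurement (650–950 nm absorbance of intact fruit from
a portable spectrometer) to four destructive quality indicators —
firmness (N/mm²), pH, soluble solid content (SSC, °Brix) and dry matter
content (DMC, always stored in percent) — in two stages: per-indicator
PLS calibrations that predict the indicators from spectra, and a
composite decision index F over the standardised indicators that maps a
fruit to a maturity grade.

## Synthetic orchard generator

Real paired spectra/quality datasets of this design are not publicly
deposited, so `mangonir.simulate` generates data with the statistical
structure the analysis assumes.  The defaults are the study conditions
themselves:

* **Design** — varieties 'Tainong'/'Guifei'/'Jinhuang', 11/10/10
  batches of 25 fruit at 4-day intervals (775 fruit).  Day 0 (the first
  batch) is taken as the commercial-harvest reference; `day0_offset`
  can shift it.
* **Quality trajectories** — each indicator interpolates linearly
  between its published 40-day endpoints (e.g. Tainong firmness
  13 → 9.3 N/mm², pH 2.78 → 3.15, SSC 4.2 → 6.8 °Brix, DMC 14 → 19 %).
  Endpoints-only is the simplest shape consistent with the printed
  start/end values; the mid-window bumps of real seasons are covered by
  the fluctuation term.
* **Weather fluctuation** — a lag-1 autocorrelated (ρ = 0.6) deviation
  shared by every fruit of a batch, stationary amplitude 5 % of each
  indicator's range by default.  This emulates rainy-spell rebounds in
  firmness and stalled SSC/DMC accumulation without modelling weather
  itself.
* **Measurement noise** — independent per-fruit Gaussian noise, default
  2 % of each indicator's range, a typical repeatability figure for
  penetrometer/refractometer/pH measurements at this scale.
* **Spectra** — clean spectrum = Gaussian-trough baseline (centre
  805 nm, width 60 nm, level 0.80, depth 0.35) minus 0.04 absorbance
  per maturity-grade unit, plus 0.004 absorbance per % DMC on a linear
  ramp above 900 nm.  This reproduces the three qualitative features
  the analysis exploits: mean absorbance decreasing with maturity, a
  trough at 805 nm, and a DMC-linked rise above 900 nm.  Observed
  spectra add per-fruit multiplicative slope (sd 0.05 around 1),
  additive offset (sd 0.02) and white noise (sd 0.005) — the scatter
  effects MSC/SNV exist to remove.  Grid: 650–950 nm at 1 nm
  (301 points); the instrument's true sampling step is not published,
  so a 1-nm grid was chosen and is configurable.
* **Determinism** — all sub-streams derive from one
  `numpy.random.SeedSequence`; identical seeds give bit-identical data.

What the generator does **not** emulate: absolute absorbance levels of
real fruit tissue (no radiative-transfer model), variety-specific
spectral shape differences beyond the DMC/grade couplings, nonlinear
indicator kinetics, and instrument drift.  Tests passing on these data
therefore demonstrate that the *pipeline* is correct and recovers known
structure — not that a real orchard would achieve the same Rp or
grading accuracy.  In particular the near-100 % synthetic grading
accuracies exceed what field data can deliver.

## Spectral pretreatments

Six standard transforms plus the identity, all shape-preserving:

* **MSC** — per-spectrum OLS against a reference; the reference is the
  mean of the *correction set only* and is reused unchanged for
  prediction samples (prevents information leakage).
* **SNV** — per-spectrum centring/scaling, sample sd (n−1).
* **Savitzky–Golay** — `scipy.signal.savgol_filter`; defaults window 11
  points, polynomial order 2, derivative order 1 (common chemometric
  defaults at 1-nm sampling).  Edges are handled by refitting the
  polynomial on the one-sided end window so the grid is preserved;
  derivatives are divided by Δλᵏ so units are absorbance·nm⁻ᵏ and
  results are grid-independent.
* **Vector / min–max normalisation** — per spectrum (row-wise).

## Outlier screen

PCA of mean-centred spectra (components to ≥ 95 % variance, capped at
10); a sample is flagged when Hotelling T² (F-distribution limit) *or*
the Q residual (moment-matched scaled-χ² limit) exceeds its 99 % limit.
The method is the standard chemometric screen; the flag-if-either rule
and limits are stated here because no single convention dominates.

## Sample-set partitioning

Kennard–Stone greedy max–min Euclidean selection on mean-centred *raw*
spectra, so that one split per indicator is reused across all candidate
pretreatments and model comparisons stay paired.  Ties (equal
distances) break to the lowest row index, making selection fully
deterministic.  Correction-set size = round(0.75·n) with rounding half
away from zero (this reproduces 162/54 at n = 216 and 149/50 at
n = 199).  Splits are computed per indicator after dropping that
indicator's missing values, so per-indicator sample counts may differ.

## PLS calibration

PLS1 by NIPALS: centre X and y (X is centred, not autoscaled —
autoscaling single-block spectral data inflates noise wavelengths); per
component w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then
deflate.  The regression vector is b = W(PᵀW)⁻¹q with an intercept
restoring the raw scale.  Degenerate components (‖Xᵀy‖ or ‖t‖ at
rounding level) stop extraction early with the achieved count.

Latent-variable count: venetian-blind k-fold cross-validation (ordered,
deterministic; default 10 folds, cap 15), choosing the smallest count
within one standard error of the minimum CV-RMSE.  The original
workflow's software does not expose its validation scheme; this CV
design is a stated substitute.

Diagnostics: Rc/Rp are Pearson correlations of measured vs predicted on
the correction/prediction set; RMSEC/RMSEP use denominator n (the usual
chemometric convention).  Constant predictions report r = 0 with a
warning flag.  The best pretreatment per indicator maximises Rp, with
ties (< 0.005) broken by lower RMSEP, then lower RMSEC, then fewer
latent variables — prediction-set performance is the generalisation
surface this workflow emphasises.

## Composite harvesting index

Indicators are z-scored (calibration means/sds; sample sd).
Correlation-matrix PCA gives eigenvalues (summing to 4), loadings
(eigenvector·√eigenvalue) and the score-coefficient matrix
(loadings/eigenvalue), whose scores have unit variance by construction.
Eigenvector signs are fixed so the SSC loading is ≥ 0 on every
component — an arbitrary but reproducible convention across
eigensolvers.  Components with eigenvalue ≥ 1 (Kaiser rule) are
retained by default ("first2" and explicit counts are available), and
the F coefficients (a, b, c, d) are the explained-variance-weighted
combination of the retained score-coefficient rows.  With the study
trajectories this yields a negative firmness coefficient and positive
pH/SSC/DMC coefficients.

Grades: 6.5 + 0.5·floor(days/8), clamped to [6.5, 9]; negative days are
"pre-commercial".  Two 4-day batches share each 0.5 grade, so 11
batches span the six grades 6.5–9.  Grade boundaries on F are midpoints
between adjacent per-grade calibration means — the simplest monotone
rule; the boundary rule is deliberately isolated
(`calibrate_thresholds`) so alternatives can be swapped in.  If grade
means are non-monotone (heavy noise), they are pool-adjacent-violators
adjusted with a warning.  PCA/coefficients are fitted pooled across
varieties; thresholds are calibrated per variety (configurable), since
varieties traverse different F ranges.

## Correlation reports

Pairwise-complete Pearson r with two-tailed p from the t transform
(n−2 df), flagged at 0.05/0.01.  The default correlates *batch means*
(the trajectory is a batch-level phenomenon and the batch is the
replication unit, ~10 points per variety); per-fruit correlation is
available.  |r| = 1 reports p = 0.

## Problem sizes and numerical choices

The test suite runs the full 775-fruit design where structure matters
(sign patterns, index behaviour) and 44–275-fruit single-variety
designs elsewhere; the acceptance script runs the complete
three-variety analysis (full pretreatment grid, 84 fitted calibration
models) in well under a minute.  Tolerances: exact contracts at 1e-8 to
1e-12; cross-implementation PLS agreement at 1e-6; Monte-Carlo checks
at 3σ.  Seeded throughout; no test depends on platform RNG state.

## Known limitations

* Synthetic-data performance overstates field performance (see above).
* The generator's spectrum–indicator link is low-rank and nearly
  linear, so PLS needs few latent variables; real spectra would demand
  more and stress the CV selection harder.
* The midpoint grade rule assumes roughly symmetric within-grade F
  spread; strongly skewed noise would favour quantile-based cuts.
* Batch-mean correlations at n ≈ 10 have wide confidence intervals;
  sign assertions are stable but magnitudes are not.
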