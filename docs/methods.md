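# Methods

This note documents the models, numerical choices, defaults and known
limitations of `fltpet`. Empirical statements below are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## SUV quantification

Static uptake is measured on the *summed image*: the duration-weighted mean
concentration over frames whose mid-time falls in a configurable window,
default [50, 60] min. The clinical convention "SUV at 60 min" names a time
point, not a window; a late 10-minute window is the standard operational
reading and the window is an explicit argument everywhere. SUV uses
body-weight normalization, SUV = C[kBq/mL] / (injected activity[kBq] /
body weight[g]), giving the dimensionless g/mL convention. Volumes are
assumed decay-corrected to injection time during reconstruction, as is
universal for clinical PET; the package performs no decay arithmetic.
Masks live on the image voxel grid (0-based indices); no world-coordinate
resampling or registration is in scope.

## Input function

Clinically the input function is image-derived: voxels of a blood-pool ROI
are ranked by their early (first 2 min) time-integral and the mean TAC of
the hottest 20% (configurable) is taken as the whole-blood curve, which
limits partial-volume dilution without registration machinery. Metabolite
correction multiplies the whole-blood curve by a constant plasma-to-blood
ratio (default 1.0) and a sigmoid parent fraction

p(t) = floor + (1 − floor) / (1 + (t/half_time)^steepness),

defaults half_time 60 min, steepness 1.5, floor 0.7. FLT is metabolized
slowly (glucuronidation), so a gentle decline is physiologic; the exact
shape is a configurable simulation choice, not a measured claim, because no
assayed parent-fraction data accompany the fixtures. A constant rather than
time-varying plasma-to-blood ratio keeps the correction identifiable.

For simulation the plasma curve is the standard tri-exponential bolus
(Feng model 2), Cp(t′) = (A₁t′ − A₂ − A₃)e^(−λ₁t′) + A₂e^(−λ₂t′) +
A₃e^(−λ₃t′), t′ = t − delay; defaults (A₁ = 800 kBq/mL/min, A₂ = 22,
A₃ = 21 kBq/mL, λ = 4.1, 0.12, 0.01 min⁻¹, delay 0.5 min) give a ~100
kBq/mL peak appropriate to a 370 MBq injection.

## Two-tissue-compartment kinetics

The reversible model (k₄ free) is the default because the fitted cohort
shows nonzero k₄; an irreversible variant is the `k4_free=False` switch.
V_b is treated as a dimensionless volume fraction: the mixing equation
C_T = (1−V_b)(C₁+C₂) + V_b·C_b requires a fraction, and the fixture values
(0.015–0.10) are fraction-scaled regardless of the table's printed unit.

**Forward solution.** The tissue impulse response is
K₁/(α₂−α₁)[(k₃+k₄−α₁)e^(−α₁t) + (α₂−k₃−k₄)e^(−α₂t)] with eigenrates
α₁,₂ = [(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]/2. Convolution with the
input, interpolated to a uniform 0.05-min grid, is computed *exactly* per
grid interval for a piecewise-linear input via a first-order recursive
filter (`scipy.signal.lfilter`), with series expansions of the segment
integrals when αΔt < 1e−8 so the k₄ → 0 (Patlak-like) and fully degenerate
limits are seamless; a 1e−9 floor on the eigenrate gap guards the
measure-zero repeated-eigenvalue case (relative error ~ε/(Δα·t), far below
the 0.1% oracle tolerance). The tests pin agreement with an adaptive LSODA
integration of the ODEs to < 0.1% of the curve maximum over 100 random
parameter draws. Model curves are matched to data by exact per-frame time
averages (cumulative trapezoid, differenced at frame edges).

**Fitting.** Bounded least squares (`scipy.optimize.least_squares`, TRF)
over (K₁, k₂, k₃, k₄, V_b) with box bounds [0,2]×[0,2]×[0,1]×[0,0.5]×
[0,0.5], multistart from a seeded Latin-hypercube (default 20 starts, seed
20200101); the best restart by weighted cost is returned, with approximate
standard errors from the local Jacobian. Weights default to frame duration
— the standard count-statistics proxy; `uniform` and `duration-over-value`
(inverse-variance under the simulator's noise model) are config options.
A minimum of 8 frames is enforced as an identifiability floor.

## Kinetic spatial filtering

Templates are per-class mean TACs normalized to unit area (trapezoid), so
classification compares curve *shape*, independent of amplitude — the point
of the method, since liver and tumor differ in kinetics (washout versus
accumulation) more reliably than in late intensity. Distance is L2 between
normalized curves by default; one-minus-correlation and unit-peak
normalization are config switches. Ties break toward the earlier template
in the class order (liver first), i.e. toward suppression — conservative
for the filter's purpose. All-zero TACs (air) get class "other". The class
map is then regularized by a neighborhood-majority filter (cubic radius 1
by default) before voxels of the exclusion classes (default: liver) are
zeroed in the summed image. Majority relabeling erodes one-voxel-thick
tumor rims; small lesions can be filtered out entirely. That mirrors the
clinical observation that sub-30-mm lesions tend to vanish under this kind
of filter and is accepted behavior, pinned by a phantom regression test
rather than "fixed".

Metrics: percent signal reduction per ROI, 100·(1 − mean_filtered /
mean_unfiltered), and the post-filter tumor-to-liver ratio, reported as
+inf with a flag when the filtered liver mean is zero.

## Response statistics

PET response is an SUV60_mean reduction of at least 20%, *inclusive*
(change ≤ −20 responds): boundary inclusivity is the common radiology
convention and reproduces the fixture's 15/25 split. mRECIST collapses to
CR/PR = responder, SD/PD = nonresponder; NE propagates and is excluded
column-wise from all aggregates (adding an NE record changes nothing — a
tested invariant). Concordance is computed over lesions evaluable on both
systems (24 of 26 in the fixture). Cohen κ comes from the 2×2 table with
the large-sample CI SE √(p_o(1−p_o)/n)/(1−p_e) and the Fleiss null SE for
the p-value; the κ value is cross-checked against scikit-learn in tests.
Wilcoxon tests use exact small-sample nulls where the data permit
(scipy); the χ² test is Pearson without continuity correction by default.
The fixture's overall SUV60_mean change, printed as a "median" of
−29.5 ± 31.4 in the source table's narrative, is arithmetically the *mean*
of the 25 evaluable changes (the median is −33.9); the summary reports
both.

Fixture oddities are preserved verbatim with quality flags rather than
corrected: one subject's V_b prints as "5.0E−0" (≥ 1, impossible as a
fraction) and one kinetic-table subject has no lesion-table counterpart.
Three printed K_i values differ from K₁k₃/(k₂+k₃) by one unit in the second
decimal (rounded from unrounded fits upstream); the identity is therefore
asserted at ±0.01.

## Synthetic phantom

Defaults: 40×40×20 grid at 4 mm; frame schedule 6×10 s, 8×15 s, 6×60 s,
5×120 s, 8×300 s (59 min, 33 frames — a typical dynamic liver protocol,
chosen here as no acquisition protocol accompanies the fixtures); liver
ellipsoid with high-delivery/low-trapping kinetics (K₁ 0.25, k₂ 0.9,
k₃ 0.02, k₄ 0.01, V_b 0.10) so the physiologic background is strong; a
blood-pool cylinder following the bolus; one 30-mm spherical lesion with
mid-range observed tumor kinetics (K₁ 0.31, k₂ 0.40, k₃ 0.24, k₄ 0.04,
V_b 0.019). Frame noise is zero-mean Gaussian with SD = noise_coeff ·
√(value/duration), clipped at zero; the default noise_coeff 0.5 yields
≈9% relative noise on late-frame liver voxels, mid-range for voxel-level
dynamic PET. Noise applies per voxel; ROI-mean TACs — the only objects the
fitter consumes — carry that SD shrunk by √N_voxels. The replicate bias
study in the acceptance tests therefore draws TAC noise at the default
lesion's ROI level (N = 251). Post-treatment scans rescale lesion K₁
(default ×0.34, the responder-like two-thirds delivery cut) and k₃
(default ×0.7) with the liver untouched, reusing the same seed so a unit
effect reproduces the baseline bit-for-bit.

What the phantom does *not* emulate: partial-volume blur, scatter and
attenuation, reconstruction correlations between voxels, respiratory
motion, heterogeneous or necrotic lesions, and inter-subject input-function
variability. Passing phantom tests therefore demonstrates correctness of
the estimators under the stated noise model, not clinical performance; in
particular the published per-patient filter numbers (81%/98% signal
reductions, post-filter ratio 11.1 ± 17.7) require the original scans and
are represented only by qualitative phantom properties (liver suppression
> 90%, 30-mm tumor retention > 50%).

The cohort generator samples baseline rate constants log-normally around
the fixture means (CV 0.45), converts them to late-window SUVs through the
same forward model, applies a multiplicative K₁ reduction of mean 0.66
(responders) or 0.50 (nonresponders, SD 0.10) plus a k₃ reduction for
responders, adds 5% measurement noise, and draws the conventional-imaging
label to disagree with truth with probability 1/6 (the disagreement rate
observed in the fixture cross-tab). A deterministic
`cohort_from_crosstab(a, b, c, d)` constructor exists for exact-agreement
checks.

## Known limitations

* No delay/dispersion fitting beyond the bolus delay parameter; no
  Patlak/Logan graphical analyses; no voxelwise parametric imaging (single
  voxels at realistic noise do not support stable five-parameter fits —
  the package fits ROI-mean TACs only).
* The kappa CI method is the large-sample approximation; exact small-n
  intervals are out of scope.
* The image-derived input function assumes a user-supplied blood-pool mask;
  vessel segmentation is not provided.
* Problem sizes in the tests (phantom grid, 200 fit replicates, 100 oracle
  draws) are chosen as desk-scale defaults that still exercise every code
  path; all are configurable upward.
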