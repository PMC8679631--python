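# fltpet

Dynamic ¹⁸F-FLT PET analysis of hepatocellular carcinoma (HCC) response to
transarterial chemoembolization (TACE), built for imaging scientists who
want the whole quantification chain — SUV measurement, image-derived input
function, compartmental kinetics, hepatic-background filtering, and
response/concordance statistics — as tested, composable Python.

HCC develops inside cirrhotic liver whose own ¹⁸F-FLT uptake is high, so
static images show poor tumor-to-liver contrast. The package implements the
two quantitative routes around that problem:

1. **Kinetics.** Each lesion's time–activity curve (TAC) is fit with the
   reversible two-tissue-compartment model driven by a metabolite-corrected
   arterial input function Cp(t):

   dC₁/dt = K₁·Cp − (k₂+k₃)·C₁ + k₄·C₂,  dC₂/dt = k₃·C₁ − k₄·C₂,
   C_T(t) = (1−V_b)(C₁+C₂) + V_b·C_b(t)

   with delivery K₁ (mL/min/g), efflux k₂, phosphorylation k₃, release k₄
   (1/min) and fractional blood volume V_b. The net influx constant is
   **K_i = K₁k₃/(k₂+k₃)**. The forward model is the analytic bi-exponential
   convolution (eigenrates α₁,₂ = [(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]/2);
   fitting is bounded weighted least squares with a seeded Latin-hypercube
   multistart, exposed as the scikit-learn estimator `TwoTissueFitter`.

2. **Kinetic spatial filtering (KSF).** Voxel TACs are classified against
   tissue-class template curves (liver / tumor / blood) by shape (unit-area
   normalized, nearest-template), the class map is regularized with a
   neighborhood-majority filter, and liver-like voxels are zeroed in the
   summed image to suppress physiologic hepatic uptake.

Treatment response is graded from the percentage change in SUV60_mean
(inclusive −20% threshold) and compared against mRECIST with Cohen κ.
A seeded synthetic 4D liver phantom (`fltpet.simulate`) provides ground
truth for every stage; the published per-lesion and per-subject tables ship
as fixture CSVs in `fltpet/data/`.

## Worked example

Library use — fit one simulated lesion and classify its response:

```python
from dataclasses import replace
from fltpet import (PhantomConfig, TaceEffect, generate_phantom,
                    simulate_post_tace, extract_tac, fit_2tcm, percent_change,
                    pet_response, compute_suv, summed_image, suv_stats)

cfg = replace(PhantomConfig(), noise_coeff=0.0)
base, truth = generate_phantom(cfg)
post, _ = simulate_post_tace(cfg, TaceEffect(k1_factor=0.34, k3_factor=0.7))

lesion = truth.masks["lesion_1"]
fit = fit_2tcm(extract_tac(base, lesion), truth.aif, cfg.schedule)
print(f"K1={fit.params.K1:.3f}  k3={fit.params.k3:.3f}  Ki={fit.ki:.4f}")

pre = suv_stats(compute_suv(summed_image(base, (50, 59)), cfg.subject), lesion)
after = suv_stats(compute_suv(summed_image(post, (50, 59)), cfg.subject), lesion)
change = percent_change(pre["suv_mean"], after["suv_mean"])
print(f"SUV60_mean {pre['suv_mean']:.2f} -> {after['suv_mean']:.2f} "
      f"({change:+.1f}%): {pet_response(change).value}")
```

```
K1=0.310  k3=0.240  Ki=0.1163
SUV60_mean 12.10 -> 3.19 (-73.7%): responder
```

The fitted K₁ = 0.310 and K_i = 0.116 recover the phantom's ground-truth
lesion kinetics exactly (noise-free inverse crime), and a two-thirds cut in
delivery with reduced trapping drops the late SUV by ~74%, well past the
−20% response threshold.

Shell use — every clinical-table aggregate the package computes:

```console
$ fltpet reproduce-tables
lesions: 26
baseline SUV60_mean: 6.48 +/- 1.85
baseline SUV60_max:  9.68 +/- 3.02
pct change SUV60_mean: -29.5 (median -33.9, n=25)
pct change SUV60_max:  -18.6
PET responders: 15/25
mRECIST responders: 14/24
kappa: 0.657 (95% CI 0.35-0.96, p=0.0013, counts (12, 2, 2, 8))
kinetics: n=14, mean K1=0.303, mean Ki=0.089
```

15/25 lesions respond on PET versus 14/24 on conventional imaging, with
good chance-corrected agreement (κ = 0.66). Other subcommands: `suv`,
`fit-kinetics`, `ksf`, `respond`, `simulate-phantom`, `simulate-cohort`
(see `fltpet --help`).

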