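# hepatopat

Simulation and analysis pipeline for volumetric photoacoustic (PA) liver
angiography.  The package targets the computational questions behind
non-invasive fatty-liver assessment: given raw channel data from a rotating
hemispherical ultrasound detector, how do you reconstruct a hepatic
angiogram through two media with different sound speeds, remove
breathing-motion artifacts without external gating hardware, and reduce the
angiogram to a handful of quantitative markers that separate lean from
fatty livers?

Because no public raw dataset exists for this modality, the package ships a
first-class synthetic generator — seeded liver phantoms with exact
ground-truth vessel masks, parametric respiration, and a two-zone
straight-ray forward model — so every stage of the chain is testable
against known truth.  It is intended for researchers prototyping PA
reconstruction and gating algorithms, and for anyone who needs a
reproducible end-to-end benchmark of hepatic-angiogram feature extraction.

## What it computes

* **Dual speed-of-sound universal back-projection (UBP).**  Each voxel `r`
  accumulates the temporal back-projection term of every detector trace
  `p_d(t)`,

      b_d(t) = 2 p_d(t) − 2 t p_d′(t),   evaluated at  t = τ(r, d),

  where the delay τ splits the straight ray at its closed-form intersection
  with a half-elliptic-cylinder tissue boundary:
  `τ = ℓ_tissue/c_tissue + ℓ_water/c_water`.  Post-processing: exponential
  depth compensation, 3D Gaussian high-pass, Frangi vesselness, composite.

* **Respiratory time gating.**  The first-arrival time of the surface
  signal per shot forms a respiration trace; shots near its extrema are
  removed, two sweeps are merged into full-scan data (motion-free mode), or
  shots are binned into phases of the breath cycle (dynamic mode).

* **Quantitative features.**  Liver volume; vessel volume occupancy
  `VVO = V_vessel/V_liver`; vessel number density `VND = N_vessel/V_liver`
  from a junction-broken 3D skeleton; angiographic irregularity
  `AI = M_VDD ⊙ A`, the voxelwise product of a sliding-window histogram
  entropy map (`E = −Σ P_i log₂ P_i`, 256 bins, 1.2 mm window) and a
  rotational SVD-anisotropy map
  (`A = exp(−(max_θ Σ₁₁ − min_θ Σ₁₁))`, Σ₁₁ = σ₁/Σσᵢ, 3 mm window, 10°
  steps, averaged over the three slicing axes); and an autofocus tissue
  speed-of-sound estimate (sharpness = mean |3D FFT| of a deep ROI,
  maximised over a 1400–1700 m/s grid).

* **Group statistics.**  One-tailed Welch t-tests on the five per-subject
  features between cohorts.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Run the default cohort study — six lean and six obese synthetic subjects,
per-subject features, and the five Welch tests:

```python
from hepatopat import run_pipeline

result = run_pipeline(seed=1)
print(result.feature_table.groupby("group")[
    ["v_liver_mm3", "vvo", "vnd_per_mm3", "mean_ai", "sos_est_mps"]].mean())
for t in result.tests:
    print(f"{t.feature}: t={t.t_statistic:.2f}  p={t.p_one_tailed:.2e} ({t.alternative})")
```

which prints

```
       v_liver_mm3       vvo  vnd_per_mm3   mean_ai  sos_est_mps
group
lean     70.147687  0.076323     0.090286  4.328250  1570.000000
obese   104.720062  0.030134     0.028648  4.965325  1538.333333
v_liver_mm3: t=-1056.12  p=6.73e-15 (less)
vvo: t=15.22  p=1.58e-08 (greater)
vnd_per_mm3: t=20.51  p=2.55e-06 (greater)
mean_ai: t=-41.33  p=1.60e-12 (less)
sos_est_mps: t=6.64  p=6.09e-05 (greater)
```

The obese preset has a larger liver, fewer and more tortuous vessels, a
more heterogeneous parenchyma and a lower tissue sound speed, so all five
markers separate the groups in the stated directions: obese livers are
larger and slower, with lower vessel occupancy and density and higher
angiographic irregularity.  Alternatives are configuration, not code; the
same machinery run with identical presets gives null results at the
nominal rate.

The same pipeline is available from the shell, along with the individual
stages:

```bash
hepatopat run --seed 1 --out results/
hepatopat phantom --preset obese --seed 2 --out obese.nii.gz
hepatopat simulate --volume obese.nii.gz --out raw.h5
hepatopat gate --raw raw.h5
hepatopat recon --raw raw.h5 --out volume.nii.gz
hepatopat sos --raw raw.h5 --out curve.csv
```

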