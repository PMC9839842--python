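# Methods

`hepatopat` re-creates, at desk scale and on fully synthetic data, the
computational chain of volumetric photoacoustic (PA) liver imaging: raw
channel data from a rotating hemispherical detector, two-zone
back-projection reconstruction, respiratory time gating, quantitative
hepatic-angiogram features, and group statistics.  This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic studies do and do not demonstrate.

## Imaging model

**Geometry.** World coordinates are millimetres with z vertical.  Detectors
sit on the lower half of a sphere centred at the origin (radius
`hemisphere_radius_mm`, default 30 mm at desk scale).  Four arc arrays,
evenly spaced in azimuth with elements spread over polar angles 12–80°,
rotate about the vertical axis by one step per laser shot so a one-way
sweep covers the 90° inter-arc gap.  The full-scale schedule (4 × 256
elements, 500 shots at 50 Hz, 40 MHz sampling) is configurable; desk-scale
defaults (4 × 64 elements, 100 shots) keep a full simulation and
reconstruction in minutes on one CPU.  The total rotation span per sweep is
not uniquely determined by the hardware description; 90°, the inter-arc gap
of four evenly spaced arcs, is adopted and exposed in the geometry config.

**Two-zone medium.** The body cross-section is a half ellipse in the (x, z)
plane — the interior of an axis-aligned ellipse cut by the flat cap plane
`z = cap_plane_z_mm` — extruded along the body axis (y).  Tissue occupies
the region above the cap; everything else is coupling water.  Each zone has
a uniform speed of sound (defaults: water 1498 m/s, tissue 1540 m/s, both
restricted to 1300–1800 m/s) and refraction at the interface is neglected,
so rays are straight and the delay between a field point and a detector is
the tissue chord over `c_tissue` plus the water remainder over `c_water`.
The chord is computed in closed form (quadratic root interval of the line
against the elliptic cylinder, intersected with the cap half-space); tests
compare it against brute-force midpoint slowness integration with 10⁴
sub-segments, whose own chord quantisation (~1/n per boundary crossing)
bounds the achievable agreement.

**Forward model.** A detector trace is the superposition over absorbing
voxels of `a/(4πr)·p(t − τ)` with τ the two-zone delay and `p` a
derivative-of-Gaussian ("N-shaped") pulse whose spectral peak sits at the
2.25 MHz detector centre frequency (σ = 1/(2π·f_c)).  The element impulse
response, directivity, finite aperture, attenuation and refraction are not
modelled.  The forward and inverse operators deliberately share the same
delay model, so simulation studies probe noise, motion and sound-speed
mismatch rather than ray-model error; consequently these studies cannot
detect biases that a shared incorrect ray model would introduce on real
data.

**Reconstruction.** Universal back-projection: every voxel sums
`b(t) = 2p(t) − 2t·p′(t)` of each retained trace at its delay, with uniform
per-element weights (the calibrated solid-angle weights of the real array
are not published; uniform weighting preserves linearity and permutation
invariance, which the tests assert).  The temporal derivative is a centred
finite difference; trace values at fractional delays are linearly
interpolated, adequate at 40 MHz sampling against a 2.25 MHz band.  The
voxel loops run in a compiled kernel; detectors are processed in tiles of
512 so each tile's traces stay cache-resident (the sum over tiles is
exact).  Post-processing follows the standard angiographic chain:
exponential depth-gain compensation `exp(μ_eff·depth)` capped at 10×
(μ_eff default 1 cm⁻¹; the compensation form is this package's choice),
Gaussian high-pass (kernel σ = cutoff/2, so wavelengths at the cutoff are
retained ≥ 99%), 3D Frangi vesselness (α = β = 0.5, scales 0.15–0.9 mm,
bright ridges, max over scales, self-normalised to [0, 1]), and
compositing of the self-normalised enhanced image back onto the base image.

**Boundary fitting.** From the central body-axis slice of a single-SoS
reconstruction, the farthest above-threshold voxel per lateral column gives
a surface point cloud (the flat cap is interior to the conic and would bias
the fit); an axis-aligned conic `Ax² + Cz² + Dx + Ez + 1 = 0` is fitted by
linear least squares and converted to centre and semi-axes.  The fit is
deterministic and recovers a constructed half-elliptic cylinder within a
voxel.

## Synthetic phantoms

A phantom is an ellipsoidal liver of parenchyma (level 1, multiplied by
1 + 0.15·smoothed-noise texture) containing `n_vessels` mutually
non-touching tubular trees at 5:1 vessel:parenchyma contrast.  Centerlines
are seeded random walks started in the liver core with an inward initial
heading, with angular jitter set by `tortuosity` and linearly tapering
radii (root radius drawn from `radius_range_mm`, tapering to half);
candidates shorter than 12 samples or 30 voxels are re-drawn, and a
26-connected one-voxel guard keeps trees from touching even diagonally so
skeleton counting has exact ground truth.  Placement retries are bounded;
the preset geometries were validated over 60 seeds each with zero
placement failures.

Cohort presets emulate the expected lean/fatty-liver contrasts on a 56³
grid at 0.15 mm pitch: lean — liver semi-axes (2.6, 2.8, 2.3) mm, 6
vessels, tortuosity 0.25; obese — larger liver (3.0, 3.2, 2.6) mm, 3 more
tortuous vessels (0.5), higher parenchymal texture amplitude (0.30 vs
0.15, emulating steatotic heterogeneity), and a lower true tissue sound
speed (1540 vs 1570 m/s, fatty livers being slower).  The texture contrast
is what gives the obese group a higher angiographic irregularity: with
texture equal, the two AI factors oppose each other (more vessels raise the
windowed entropy but lower the rotational isotropy) and AI separates only
weakly.  Per-subject seeds derive from (master seed, group, index) only, so
enlarging a cohort reuses its existing subjects.

**Respiration.** Motion is an axial displacement field
`Δz = A·s(φ)·tanh((z − z_pivot)/w)` — antisymmetric about a diaphragm-like
pivot plane (width w = 1.5 mm) — plus a caliber modulation of one
designated vessel, radius scaled by `1 + d·s(φ)` and rebuilt analytically
from its centerline distance field.  The default waveform is a sin²
inspiratory burst occupying 20% of a 1 s cycle with a quiescent pause,
matching breathing under anesthesia; a sinusoid is available for
phase-resolved studies that need distinct deformation at (almost) every
phase.  Deformation is applied by trilinear pull-back resampling, which
conserves total absorbed energy under near-rigid shifts to within 1%.
Breath period under anesthesia is not pinned by the source system
description; 1.0 s is the modelling default and is exposed in config.

## Time gating

The first-arrival sample of the surface signal is tracked per shot on a
reference element (the element with maximal mean RMS), thresholding at
`mean(|background|) + 3·std(background)` over a pre-signal window, with two
consecutive supra-threshold samples required so an isolated noise spike
cannot fake an arrival.  The arrival trace is median-filtered (5 shots),
smoothed by a Gaussian-weighted moving average (9 shots), and
differentiated; peaks and troughs are found with prominence ≥ 2× the
residual noise level in two passes, the second enforcing a minimum
separation of half the estimated half cycle.  Shots within ±10% of a cycle
around any extremum are removed.  Forward and backward sweeps are merged
per angular position (mean where both survive, the survivor where one
does, linear interpolation along angle where neither does).  For dynamic
imaging the cycle is divided into `round(cycle/20 ms)` phases and each shot
is labelled by its offset from the preceding trough; the gate widths and
smoothing windows are not given by the source description and were fixed
once on simulation, all configurable.

Because the band-limited reconstruction differs from the raw absorption
lattice far more than motion ghosting does at a 0.5 mm excursion, gating
efficacy is measured against the reconstruction of an identical motion-free
acquisition: the gated+merged image is ~19× closer to it (normalised RMSE)
than the ungated image in the default moving-phantom study.

## Segmentation and features

Liver: 3σ threshold with background sampled from a 5-voxel lateral shell at
the grid faces (the "periphery of the field of view"; its extent is this
package's choice), followed by largest-26-connected-component cleanup.
Vessels: the 3σ rule applied repeatedly within the ROI — a first pass on
the Frangi volume yields specific seeds, a second pass on the intensity
volume (background = ROI parenchyma away from the seeds) grows them to the
full lumen, keeping only components containing a seed.  The literal
single-pass variant (used when no intensity volume is supplied)
under-covers the lumen roughly two-fold because vesselness peaks on
centerlines; the seeded refinement recovers vessel volume fractions within
a few percent of truth.  Counting thins the vessel mask to centerlines
(3D skeletonization), deletes voxels with ≥ 3 skeleton neighbours in the
26-neighbourhood to break the network at junctions, removes branches
shorter than 5 voxels (0.75 mm; the "small vessel" size is unstated
upstream), and counts surviving components.  Branch breaking by junction
voxel deletion (rather than edge labelling) is the adopted reading; on
tubes and Y-junctions the two coincide.

**VDD** (vessel distribution diversity): Shannon entropy (bits) of the
256-bin histogram in a 1.2 mm sliding cube, assigned to the window centre;
bins are equal-width over the global min–max of the volume (window-local
ranges would erase contrast information), stride 1, edges NaN.

**MI** (morphological irregularity): for each 3 mm 2D window of each slice
along each axis, the window is rotated 0–170° in 10° steps (bilinear
interpolation on the inscribed-circle support, corners zeroed, which makes
a constant window exactly rotation-invariant), the normalised SVD dominancy
Σ₁₁(θ) = σ₁/Σσᵢ is computed (σ₁/‖σ‖₂ available by flag), and
`A = exp(−(max_θ Σ₁₁ − min_θ Σ₁₁))`; the three per-axis maps are averaged.
Singular values come from the symmetric eigendecomposition of the window
Gram matrix, batched over all windows of an axis.  In-plane stride is
configurable (default 2; the cohort pipeline uses 4) with stride 1
available for verification.

**AI** = voxelwise product of the VDD and MI maps ("dot product" read as
the Hadamard product — the only reading that yields a map), averaged over
liver voxels where both maps are defined; edge windows are excluded rather
than padded.  CNR is `(mean_signal − mean_bg)/std_bg`; FWHM is measured by
linear interpolation at half maximum about the profile peak.

## Speed-of-sound estimation

The ROI (default a cube ~4.5 mm on a side starting ≈3 mm below the liver
surface, measured vertically) is reconstructed with candidate tissue
speeds 1400–1700 m/s in 10 m/s steps, water speed fixed.  Sharpness is the
mean absolute amplitude of the ROI's 3D Fourier spectrum; the DC term is
excluded by default because it is focus-independent (a flag restores it).
The arg-max is the estimate, ties breaking toward the lower speed, with a
warning when the maximum sits at a grid edge.  Under ±100 m/s mismatch the
point-spread function shears as well as blurs, so a single-axis FWHM is not
monotone in the mismatch; the geometric mean of the three axis FWHMs is
the defocus metric (0.27 mm at the true speed vs ~0.43 mm at ±100 m/s in
the reference study).

## Hemodynamics

The motion-contrast map is the per-voxel Pearson correlation (Spearman by
flag) between the across-phase value sequence and the respiration pattern
(the smoothed first-arrival trace resampled to phase bins, or any supplied
pattern); zero-variance voxels are flagged undefined.  Vessel
cross-sectional areas use the two-step threshold: a fixed coarse region
isolates the vessel, then per frame the 3σ rule on the peripheral square of
the cropped cross-sectional image (the crop margin makes the periphery
sample the surrounding parenchyma) segments the lumen; areas are
normalised to the first phase, with SEM across cycles when per-cycle data
are supplied.  A prescribed 10% radius modulation yields a peak normalised
area within a few percent of the analytic (1.1)² = 1.21.

## Statistics and pipeline

Group comparisons use the one-tailed Welch (unequal-variances) t-test with
Welch–Satterthwaite degrees of freedom, against a textbook-formula oracle
to 1e-10 in the tests.  No multiple-testing correction is applied by
default, matching the per-feature reporting convention upstream.  The
pipeline is a pure function of (config, master seed): cohort → per-subject
feature volume → masks → five features (V_liver, VVO, VND, mean AI, SoS
estimate) → five Welch tests with config-stated alternative directions
(liver volume: obese larger; VVO, VND, SoS: lean larger; mean AI: obese
larger, by the preset construction above).  The per-subject feature volume
comes either from the full acoustic chain (`image.mode: "acoustic"`) or
directly from the noisy phantom volume (`"direct"`, the default for cohort
statistics, where the acoustic operator would add cost but no group
contrast).  The SoS feature is always measured acoustically: a small deep
calibration absorber is simulated through the two-zone model at the
subject's true tissue speed (group mean ± 8 m/s between-subject SD) and
the autofocus search is run on it.  Under identical presets the five tests
reject at the nominal level across master seeds (binomial envelope);
under the default effect presets all five reject at p < 0.01 with n = 6
per group.

## Problem sizes

Default studies are sized for a single CPU: phantoms 32³–96³ voxels at
0.15 mm pitch, 4 × 16–64 elements, 16–150 shots per sweep, SoS grids of
21–31 candidates, cohorts of 6 + 6 with 20-seed null replications at 32³.
Full-scale parameters remain available in config.

## Known limitations

No fluence modelling, acoustic attenuation, dispersion, element
directivity or refraction; the phantom anatomy is an ellipsoid with tubes,
not a liver; the inverse crime (shared forward/inverse delay model) means
simulated accuracy does not bound accuracy on real data; skeleton counting
reports branches between junctions, not anatomical vessel trees; phase
labels are defined relative to the detected trough, so absolute phase has
an arbitrary circular offset; heartbeat-scale gating is available only by
shrinking the event-separation parameter, not as a separate detector.
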