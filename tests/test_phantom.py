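"""Phantom generation, truth-mask consistency, and respiration deformation."""


import numpy as np
import pytest

from hepatopat.phantom import (MotionModel, PhantomSpec, apply_respiration,
                               generate_phantom, lean_spec, make_cohort,
                               obese_spec, _displacement_profile)

SMALL = dict(grid_shape=(36, 36, 36), liver_semiaxes_mm=(2.0, 2.2, 1.7),
             liver_center_mm=(0.0, 0.0, 0.3), radius_range_mm=(0.3, 0.4))


def test_single_straight_tube():
    spec = PhantomSpec(**SMALL, n_vessels=1, tortuosity=0.0, seed=5)
    volume, truth = generate_phantom(spec)
    assert truth.n_vessels_true == 1
    assert truth.vessel_mask_true.any()
    # a zero-tortuosity centerline is a straight segment
    pts, _ = truth.centerlines[0]
    d = np.diff(pts, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    assert np.allclose(d, d[0], atol=1e-9)


def test_determinism_bit_identical():
    spec = PhantomSpec(**SMALL, n_vessels=3, seed=9)
    v1, t1 = generate_phantom(spec)
    v2, t2 = generate_phantom(spec)
    assert np.array_equal(v1.values, v2.values)
    assert np.array_equal(t1.vessel_mask_true, t2.vessel_mask_true)


def test_vessel_fraction_matches_mask_counting():
    spec = PhantomSpec(grid_shape=(48, 48, 48), liver_semiaxes_mm=(2.6, 2.8, 2.3),
                       n_vessels=6, radius_range_mm=(0.3, 0.5),
                       liver_center_mm=(0.0, 0.0, 0.3), seed=2)
    _, truth = generate_phantom(spec)
    expected = truth.vessel_mask_true.sum() / truth.liver_mask_true.sum()
    assert truth.vessel_fraction_true == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_truth_masks_nested(seed):
    spec = PhantomSpec(**SMALL, n_vessels=2 + seed % 3, tortuosity=0.1 * (seed % 5),
                       seed=seed)
    _, truth = generate_phantom(spec)
    assert not np.any(truth.vessel_mask_true & ~truth.liver_mask_true)
    assert truth.n_vessels_true == spec.n_vessels


def test_spec_invariants_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(**{**SMALL, "radius_range_mm": (0.1, 0.4)})
    with pytest.raises(ValueError):
        PhantomSpec(grid_shape=(36, 36, 36), liver_semiaxes_mm=(4.0, 4.0, 4.0))
    assert lean_spec().n_vessels > obese_spec().n_vessels


def test_vessel_amplitude_and_nonnegativity():
    spec = PhantomSpec(**SMALL, n_vessels=2, seed=4, texture_amp=0.1)
    volume, truth = generate_phantom(spec)
    assert volume.values.min() >= 0
    assert np.allclose(volume.values[truth.vessel_mask_true],
                       spec.vessel_contrast * spec.background_level)


def test_cohort_sizes_and_labels():
    lean = PhantomSpec(**SMALL, n_vessels=4, seed=0)
    obese = PhantomSpec(**SMALL, n_vessels=2, seed=0, preset="obese")
    cohort = make_cohort(lean, obese, n_per_group=3, seed=11)
    labels = [c[2] for c in cohort]
    assert len(cohort) == 6 and labels.count("lean") == 3


def test_cohort_richness_ordering_and_prefix_stability():
    lean = PhantomSpec(**SMALL, n_vessels=4, seed=0)
    obese = PhantomSpec(**SMALL, n_vessels=2, seed=0, preset="obese")
    cohort3 = make_cohort(lean, obese, n_per_group=3, seed=11)
    lean_frac = np.mean([t.vessel_fraction_true for _, t, g in cohort3
                         if g == "lean"])
    obese_frac = np.mean([t.vessel_fraction_true for _, t, g in cohort3
                          if g == "obese"])
    assert lean_frac > obese_frac
    # shared subject indices reuse identical phantoms across cohort sizes
    cohort2 = make_cohort(lean, obese, n_per_group=2, seed=11)
    assert np.array_equal(cohort2[0][0].values, cohort3[0][0].values)
    assert np.array_equal(cohort2[1][0].values, cohort3[1][0].values)


def test_cohort_requires_two_per_group():
    lean = PhantomSpec(**SMALL, n_vessels=2)
    with pytest.raises(ValueError):
        make_cohort(lean, lean, n_per_group=1, seed=0)


def test_respiration_phase_zero_is_identity(small_phantom):
    _, volume, truth = small_phantom
    motion = MotionModel(displacement_amp_mm=0.6, dilation_amp=0.1)
    out = apply_respiration(volume, truth, motion, 0)
    assert np.allclose(out.values, volume.values, atol=1e-9)
    with pytest.raises(ValueError):
        apply_respiration(volume, truth, motion, motion.phase_count)


def test_respiration_dilation_scales_vessel_volume(small_phantom):
    _, volume, truth = small_phantom
    motion = MotionModel(displacement_amp_mm=0.0, dilation_amp=0.1,
                         phase_count=20, waveform_kind="sine")
    out = apply_respiration(volume, truth, motion, 5)  # s = 1 at quarter cycle
    amp = volume.values[truth.vessel_mask_true].max()
    base = (truth.designated_ratio <= 1.0) & truth.liver_mask_true
    dil = (out.values >= amp - 1e-9) & ~(truth.vessel_mask_true & ~base)
    grown = (truth.designated_ratio <= 1.1) & truth.liver_mask_true
    # tube volume scales as radius^2: ~21% growth for a 10% dilation
    ratio = grown.sum() / base.sum()
    assert ratio == pytest.approx(1.21, rel=0.08)
    assert np.count_nonzero(out.values >= amp - 1e-9) > \
        np.count_nonzero(volume.values >= amp - 1e-9)


def test_displacement_profile_antisymmetric():
    motion = MotionModel(pivot_plane_z_mm=1.0)
    z = np.array([1.4, 0.6])  # straddling the pivot symmetrically
    d = _displacement_profile(z, motion)
    assert d[0] == pytest.approx(-d[1], rel=1e-12)


def test_rigid_translation_conserves_energy(small_phantom):
    _, volume, truth = small_phantom
    # pivot far below the grid: the tanh profile is ~1 everywhere -> rigid shift
    motion = MotionModel(pivot_plane_z_mm=-50.0, displacement_amp_mm=0.4,
                         phase_count=20, waveform_kind="sine")
    out = apply_respiration(volume, truth, motion, 5)
    assert out.values.sum() == pytest.approx(volume.values.sum(), rel=0.01)


def test_waveform_starts_at_zero():
    for kind in ("burst", "sine"):
        m = MotionModel(waveform_kind=kind)
        assert m.waveform(0) == 0.0
        assert m.phase_count == 50  # 1 s breath / 20 ms laser period
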