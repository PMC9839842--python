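"""Phase-resolved motion-contrast maps and vessel cross-section series."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from hepatopat.hemodynamics import (motion_contrast_map,
                                    vessel_cross_section_series)
from hepatopat.phantom import MotionModel, apply_respiration


def test_correlation_identities():
    pat = np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False))
    pv = np.zeros((12, 3, 3, 3))
    pv[:, 0, 0, 0] = pat
    pv[:, 1, 1, 1] = -pat
    pv[:, 2, 2, 2] = 5.0  # constant voxel: undefined
    mc = motion_contrast_map(pv, pat)
    assert mc.values[0, 0, 0] == pytest.approx(1.0)
    assert mc.values[1, 1, 1] == pytest.approx(-1.0)
    assert mc.undefined[2, 2, 2] and np.isnan(mc.values[2, 2, 2])
    with pytest.raises(ValueError):
        motion_contrast_map(pv[:2], pat[:2])


def test_noise_voxels_uncorrelated():
    rng = np.random.default_rng(0)
    pat = np.sin(np.linspace(0, 2 * np.pi, 50, endpoint=False))
    pv = rng.normal(size=(50, 12, 12, 12))
    mc = motion_contrast_map(pv, pat)
    frac_small = np.mean(np.abs(mc.values) < 0.5)
    assert frac_small > 0.95


def test_spearman_mode_matches_on_monotone_data():
    pat = np.linspace(0, 1, 10)
    pv = np.zeros((10, 2, 2, 2))
    pv[:, 0, 0, 0] = np.exp(pat)  # monotone transform
    mc = motion_contrast_map(pv, pat, method="spearman")
    assert mc.values[0, 0, 0] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def dilation_series(small_phantom):
    _, volume, truth = small_phantom
    motion = MotionModel(period_s=0.2, phase_count=10, displacement_amp_mm=0.0,
                         dilation_amp=0.1, waveform_kind="sine")
    pv = np.stack([apply_respiration(volume, truth, motion, p).values
                   for p in range(10)])
    pts, _ = truth.centerlines[0]
    mid = pts[len(pts) // 2]
    idx = np.round((mid - np.array(volume.origin_mm))
                   / volume.voxel_pitch_mm).astype(int)
    designated = (truth.designated_ratio <= 1.0) & truth.liver_mask_true
    coarse = np.take(binary_dilation(designated, iterations=4), idx[1], axis=1)
    return volume, truth, pv, (1, int(idx[1])), coarse


def test_dilated_vessel_area_series(dilation_series):
    volume, truth, pv, slice_spec, coarse = dilation_series
    series = vessel_cross_section_series(pv, slice_spec, coarse,
                                         volume.voxel_pitch_mm)
    assert series.value_mean[0] == 1.0
    # 10% radius modulation -> (1.1)^2 = 1.21 peak area
    assert series.value_mean.max() == pytest.approx(1.21, rel=0.2)


def test_static_vessel_series_flat(dilation_series):
    volume, truth, pv, slice_spec, coarse = dilation_series
    static = np.repeat(pv[:1], 10, axis=0)
    series = vessel_cross_section_series(static, slice_spec, coarse,
                                         volume.voxel_pitch_mm)
    assert np.all(np.abs(series.value_mean - 1.0) <= 0.05)


def test_series_amplitude_invariance(dilation_series):
    volume, truth, pv, slice_spec, coarse = dilation_series
    s1 = vessel_cross_section_series(pv, slice_spec, coarse,
                                     volume.voxel_pitch_mm)
    s2 = vessel_cross_section_series(10.0 * pv, slice_spec, coarse,
                                     volume.voxel_pitch_mm)
    assert np.allclose(s1.value_mean, s2.value_mean)


def test_disk_area_matches_circle():
    """Two-step threshold on a synthetic disk recovers pi r^2."""
    r = 10
    n = 48
    jj, kk = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = ((jj - 24) ** 2 + (kk - 24) ** 2 <= r ** 2).astype(float) * 5.0
    disk += np.random.default_rng(0).normal(0, 0.05, disk.shape)
    pv = np.repeat(disk[None, :, None, :], 3, axis=0)
    coarse = np.zeros((n, n), bool)
    coarse[24 - 16:24 + 16, 24 - 16:24 + 16] = True
    series = vessel_cross_section_series(pv, (1, 0), coarse, 1.0)
    from hepatopat.hemodynamics import _crop_bounds, _frame_area
    area = _frame_area(disk, coarse, 1.0, 3, _crop_bounds(coarse, 6))
    assert area == pytest.approx(np.pi * r ** 2, rel=0.04)
    assert np.allclose(series.value_mean, 1.0)


def test_cycles_give_sem(dilation_series):
    volume, truth, pv, slice_spec, coarse = dilation_series
    rng = np.random.default_rng(5)
    cycles = np.stack([pv + rng.normal(0, 0.01, pv.shape) for _ in range(3)])
    series = vessel_cross_section_series(cycles, slice_spec, coarse,
                                         volume.voxel_pitch_mm)
    assert np.all(series.value_sem >= 0)
    assert series.value_mean[0] == 1.0


def test_pivot_sign_contrast(small_phantom):
    """Tissue above vs below the diaphragm pivot moves in antiphase."""
    _, volume, truth = small_phantom
    motion = MotionModel(period_s=0.2, phase_count=10, displacement_amp_mm=0.6,
                         pivot_plane_z_mm=0.4, waveform_kind="sine")
    pv = np.stack([apply_respiration(volume, truth, motion, p).values
                   for p in range(10)])
    pattern = np.array([motion.waveform(p) for p in range(10)])
    mc = motion_contrast_map(pv, pattern)
    gz = np.gradient(volume.values, axis=2)
    zs = volume.origin_mm[2] + np.arange(volume.shape[2]) * volume.voxel_pitch_mm
    strong_edge = gz < -0.5  # matched gradient sign on both sides
    above = strong_edge & (zs[None, None, :] > 0.4 + 0.6)
    below = strong_edge & (zs[None, None, :] < 0.4 - 0.6)
    assert above.sum() > 5 and below.sum() > 5
    assert np.nanmean(mc.values[above]) > 0.3
    assert np.nanmean(mc.values[below]) < -0.3


def test_static_simulation_has_no_motion_contrast(small_phantom):
    _, volume, truth = small_phantom
    rng = np.random.default_rng(2)
    pv = np.stack([volume.values + rng.normal(0, 0.02, volume.values.shape)
                   for _ in range(20)])
    pattern = np.sin(np.linspace(0, 2 * np.pi, 20, endpoint=False))
    mc = motion_contrast_map(pv, pattern)
    signal = volume.values > 0.5
    vals = np.abs(mc.values[signal])
    assert np.nanpercentile(vals, 95) < 0.6
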