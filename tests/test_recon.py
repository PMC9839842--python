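"""Back-projection, boundary fitting, and the post-processing chain."""

import numpy as np
import pytest

from conftest import make_point_volume
from hepatopat.forward import ScanGeometry, simulate_signals
from hepatopat.recon import (ReconGrid, ReconVolume, compose_display,
                             depth_compensate, fit_half_ellipse,
                             frangi_enhance, highpass_3d, ubp_reconstruct)


@pytest.fixture(scope="module")
def point_recon(uniform_boundary):
    vol, idx = make_point_volume(shape=(32, 32, 32), index=(13, 18, 20))
    geom = ScanGeometry(hemisphere_radius_mm=20.0, elements_per_arc=16,
                        shots_per_sweep=30)
    raw = simulate_signals(vol, geom, uniform_boundary)
    grid = ReconGrid(vol.shape, vol.voxel_pitch_mm, vol.origin_mm)
    rec = ubp_reconstruct(raw, uniform_boundary, grid)
    return vol, idx, raw, grid, rec


def test_point_source_recovered(point_recon, uniform_boundary):
    _, idx, _, _, rec = point_recon
    am = np.unravel_index(np.argmax(rec.values), rec.values.shape)
    assert np.all(np.abs(np.array(am) - np.array(idx)) <= 1)


def test_reconstruction_linear_in_traces(point_recon, uniform_boundary):
    _, _, raw, grid, rec = point_recon
    rec2 = ubp_reconstruct(raw.scaled(2.0), uniform_boundary, grid)
    assert np.allclose(rec2.values, 2.0 * rec.values, rtol=1e-5, atol=1e-10)


def test_shot_permutation_invariance(point_recon, uniform_boundary):
    vol, _, raw, grid, rec = point_recon
    # removing disjoint halves and averaging equals the full reconstruction
    n = raw.n_shots
    first = np.zeros(n, bool)
    first[: n // 2] = True
    rec_a = ubp_reconstruct(raw, uniform_boundary, grid, frame_mask=first)
    rec_b = ubp_reconstruct(raw, uniform_boundary, grid, frame_mask=~first)
    combined = (rec_a.values * (~first).sum() + rec_b.values * first.sum()) / n
    assert np.allclose(combined, rec.values, rtol=1e-5, atol=1e-12)


def test_all_frames_masked_is_error(point_recon, uniform_boundary):
    _, _, raw, grid, _ = point_recon
    with pytest.raises(ValueError, match="empty detection"):
        ubp_reconstruct(raw, uniform_boundary, grid,
                        frame_mask=np.ones(raw.n_shots, bool))


def test_recon_truth_correlation(small_phantom, uniform_boundary):
    """Forward-then-invert consistency on a vessel-rich phantom."""
    _, volume, _ = small_phantom
    geom = ScanGeometry(hemisphere_radius_mm=20.0, elements_per_arc=24,
                        shots_per_sweep=60)
    raw = simulate_signals(volume, geom, uniform_boundary)
    grid = ReconGrid(volume.shape, volume.voxel_pitch_mm, volume.origin_mm)
    rec = ubp_reconstruct(raw, uniform_boundary, grid)
    r = np.corrcoef(rec.values.ravel(), volume.values.ravel())[0, 1]
    assert r > 0.8


def _half_cylinder_volume(a=15.0, b=10.0, pitch=0.3, shape=(120, 20, 80)):
    origin = (-(shape[0] - 1) * pitch / 2, 0.0, -(shape[2] - 1) * pitch / 2)
    xs = origin[0] + np.arange(shape[0]) * pitch
    zs = origin[2] + np.arange(shape[2]) * pitch
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    inside = ((X / a) ** 2 + (Z / b) ** 2 <= 1.0) & (Z >= 0.0)
    vals = np.repeat(inside[:, None, :], shape[1], axis=1).astype(float)
    grid = ReconGrid(shape, pitch, origin)
    return ReconVolume(vals, grid)


def test_fit_half_ellipse_recovers_construction():
    vol = _half_cylinder_volume(a=15.0, b=10.0)
    fit = fit_half_ellipse(vol, surface_threshold=0.5)
    assert fit.semi_axes_mm[0] == pytest.approx(15.0, abs=0.3)
    assert fit.semi_axes_mm[1] == pytest.approx(10.0, abs=0.3)
    assert fit.ellipse_center_mm[0] == pytest.approx(0.0, abs=0.3)
    # deterministic fit
    fit2 = fit_half_ellipse(vol, surface_threshold=0.5)
    assert fit2.semi_axes_mm == fit.semi_axes_mm


def test_fit_half_ellipse_circular_section():
    vol = _half_cylinder_volume(a=8.0, b=8.0, shape=(80, 10, 60))
    fit = fit_half_ellipse(vol, surface_threshold=0.5)
    assert fit.semi_axes_mm[0] == pytest.approx(fit.semi_axes_mm[1], rel=0.05)


def test_fit_half_ellipse_needs_points():
    vol = _half_cylinder_volume(shape=(12, 4, 12), a=1.0, b=1.0)
    with pytest.raises(ValueError, match="surface points"):
        fit_half_ellipse(vol, surface_threshold=2.0)


def test_depth_compensation_closed_form():
    grid = ReconGrid.centered((8, 8, 40), voxel_pitch_mm=0.5)
    vol = ReconVolume(np.ones(grid.shape), grid)
    out = depth_compensate(vol, mu_eff_per_cm=0.0)
    assert np.array_equal(out.values, vol.values)
    z0 = grid.axes_mm()[2][0]
    out = depth_compensate(vol, mu_eff_per_cm=1.0, surface_z_mm=z0,
                           max_gain=1e9)
    k = int(round(10.0 / 0.5))  # 1 cm above the surface plane
    assert out.values[0, 0, k] == pytest.approx(np.e, rel=1e-6)
    capped = depth_compensate(vol, mu_eff_per_cm=5.0, surface_z_mm=z0,
                              max_gain=10.0)
    assert capped.values.max() <= 10.0 + 1e-12


def _tube_volume(shape=(40, 40, 40), pitch=0.15, radius_mm=0.4, axis=0):
    grid = ReconGrid.centered(shape, pitch)
    ax = grid.axes_mm()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    if axis == 0:
        r2 = Y ** 2 + Z ** 2
    else:
        r2 = ((Y - Z) ** 2 / 2.0) + X ** 2  # tube along the (0,1,1) diagonal
    vals = (r2 <= radius_mm ** 2).astype(float)
    return ReconVolume(vals, grid)


def test_frangi_highlights_tubes():
    tube = _tube_volume()
    enh = frangi_enhance(tube, scales_mm=(0.3, 0.45, 0.6))
    center = enh.values[18:22, 20, 20].max()
    bg = enh.values[5:10, 5:10, 5:10].max()
    assert center > 5 * max(bg, 1e-12)
    assert 0.0 <= enh.values.min() and enh.values.max() == pytest.approx(1.0)


def test_frangi_constant_volume_zero():
    grid = ReconGrid.centered((20, 20, 20))
    flat = ReconVolume(np.full(grid.shape, 3.0), grid)
    enh = frangi_enhance(flat, scales_mm=(0.3, 0.6))
    assert np.allclose(enh.values, 0.0)


def test_frangi_rotation_robustness():
    axis_resp = frangi_enhance(_tube_volume(axis=0), scales_mm=(0.3, 0.45, 0.6))
    diag_resp = frangi_enhance(_tube_volume(axis=1), scales_mm=(0.3, 0.45, 0.6))
    a = axis_resp.values[20, 20, 20]
    d = diag_resp.values[20, 20, 20]
    assert d == pytest.approx(a, rel=0.10)


def test_frangi_scale_below_pitch_rejected():
    with pytest.raises(ValueError):
        frangi_enhance(_tube_volume(), scales_mm=(0.05,))


def test_highpass_and_compose():
    grid = ReconGrid.centered((40, 40, 40), voxel_pitch_mm=0.15)
    flat = ReconVolume(np.full(grid.shape, 2.0), grid)
    assert np.allclose(highpass_3d(flat, cutoff_mm=1.0).values, 0.0, atol=1e-9)
    with pytest.raises(ValueError):
        highpass_3d(flat, cutoff_mm=0.2)
    # stripe with wavelength below the cutoff is retained almost in full
    lam = 0.9
    xs = grid.axes_mm()[0]
    stripe = ReconVolume(np.sin(2 * np.pi * xs / lam)[:, None, None]
                         * np.ones(grid.shape), grid)
    hp = highpass_3d(stripe, cutoff_mm=1.0)
    sigma = 0.5  # cutoff/2, the documented kernel width
    expected = 1.0 - np.exp(-2 * np.pi ** 2 * sigma ** 2 / lam ** 2)
    core = (slice(10, 30),) * 3
    retained = np.abs(hp.values[core]).max() / np.abs(stripe.values[core]).max()
    assert retained >= 0.9
    assert retained == pytest.approx(expected, abs=0.05)
    assert np.array_equal(compose_display(stripe, hp, 0.0).values,
                          stripe.values)
    composed = compose_display(flat, hp, 0.5)
    assert composed.values.shape == flat.values.shape
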