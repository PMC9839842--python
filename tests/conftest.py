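"""Shared fixtures: phantoms, simulated acquisitions, and study bundles.

Heavy simulations are session-scoped so that unit tests and the
property-based acceptance tests share one computation.
"""

from dataclasses import replace

import numpy as np
import pytest

from hepatopat.acoustics import TissueBoundary
from hepatopat.forward import ScanGeometry, add_noise, simulate_signals
from hepatopat.gating import gate_sweep, merge_round_trip
from hepatopat.phantom import (AbsorptionVolume, MotionModel, PhantomSpec,
                               apply_respiration, generate_phantom)
from hepatopat.recon import ReconGrid, ubp_reconstruct


def make_point_volume(shape=(48, 48, 48), pitch=0.15, index=None, value=1.0):
    vals = np.zeros(shape)
    index = tuple(n // 2 for n in shape) if index is None else tuple(index)
    vals[index] = value
    origin = tuple(-(n - 1) * pitch / 2 for n in shape)
    return AbsorptionVolume(vals, pitch, origin), index


@pytest.fixture(scope="session")
def uniform_boundary():
    """Degenerate two-zone medium: both speeds 1500 m/s."""
    return TissueBoundary(ellipse_center_mm=(0.0, 0.0), semi_axes_mm=(5.0, 4.2),
                          c_water_mps=1500.0, c_tissue_mps=1500.0,
                          cap_plane_z_mm=-3.2)


@pytest.fixture(scope="session")
def two_zone_boundary():
    return TissueBoundary(ellipse_center_mm=(0.5, -0.4), semi_axes_mm=(6.0, 5.0),
                          c_water_mps=1498.0, c_tissue_mps=1560.0,
                          cap_plane_z_mm=-4.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Vessel-rich 40^3 phantom with exact truth, reused across modules."""
    spec = PhantomSpec(grid_shape=(40, 40, 40),
                       liver_semiaxes_mm=(2.2, 2.4, 1.8), n_vessels=4,
                       radius_range_mm=(0.3, 0.4),
                       liver_center_mm=(0.0, 0.0, 0.4), seed=3)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def gating_study(small_phantom, uniform_boundary):
    """Moving-phantom round-trip acquisition: 1 s breath, 0.5 mm excursion.

    Bundles the forward/backward sweeps, per-sweep gating, the merged
    motion-free reconstruction, the ungated reconstruction, and the
    reference reconstruction of the identical motion-free acquisition.
    """
    spec, volume, truth = small_phantom
    motion = MotionModel(period_s=1.0, pivot_plane_z_mm=0.4,
                         displacement_amp_mm=0.5, phase_count=50)
    geom_f = ScanGeometry(hemisphere_radius_mm=20.0, elements_per_arc=24,
                          shots_per_sweep=150)
    geom_b = replace(geom_f, sweep_direction="backward")
    bnd = uniform_boundary
    raw_f = add_noise(simulate_signals(volume, geom_f, bnd, motion=motion,
                                       truth=truth), 35.0, 7)
    raw_b = add_noise(simulate_signals(volume, geom_b, bnd, motion=motion,
                                       truth=truth), 35.0, 8)
    bg_win = (0, 200)
    gate_f = gate_sweep(raw_f, bg_win)
    gate_b = gate_sweep(raw_b, bg_win)
    n = geom_f.shots_per_sweep
    merged = merge_round_trip(raw_f, raw_b, gate_f.removed_mask,
                              gate_b.removed_mask)
    ungated = merge_round_trip(raw_f, raw_b, np.zeros(n, bool),
                               np.zeros(n, bool))
    grid = ReconGrid(volume.shape, volume.voxel_pitch_mm, volume.origin_mm)
    rec_gated = ubp_reconstruct(merged, bnd, grid)
    rec_ungated = ubp_reconstruct(ungated, bnd, grid)
    static_f = add_noise(simulate_signals(volume, geom_f, bnd), 35.0, 7)
    static_b = add_noise(simulate_signals(volume, geom_b, bnd), 35.0, 8)
    rec_static = ubp_reconstruct(
        merge_round_trip(static_f, static_b, np.zeros(n, bool),
                         np.zeros(n, bool)), bnd, grid)
    return {
        "spec": spec, "volume": volume, "truth": truth, "motion": motion,
        "geom_f": geom_f, "raw_f": raw_f, "raw_b": raw_b,
        "gate_f": gate_f, "gate_b": gate_b, "background_window": bg_win,
        "rec_gated": rec_gated, "rec_ungated": rec_ungated,
        "rec_static": rec_static, "boundary": bnd, "grid": grid,
    }


@pytest.fixture(scope="session")
def phase_study(small_phantom, uniform_boundary):
    """Sinusoidal-motion acquisition binned into 10 respiratory phases."""
    spec, volume, truth = small_phantom
    motion = MotionModel(period_s=0.2, pivot_plane_z_mm=0.4,
                         displacement_amp_mm=0.8, phase_count=10,
                         waveform_kind="sine")
    geom = ScanGeometry(hemisphere_radius_mm=20.0, elements_per_arc=24,
                        shots_per_sweep=100)
    raw = add_noise(simulate_signals(volume, geom, uniform_boundary,
                                     motion=motion, truth=truth), 40.0, 5)
    grid = ReconGrid(volume.shape, volume.voxel_pitch_mm, volume.origin_mm)
    truth_phase_volumes = np.stack(
        [apply_respiration(volume, truth, motion, p).values for p in range(10)])
    phase_recons = []
    for p in range(10):
        mask = raw.phase_truth != p
        phase_recons.append(
            ubp_reconstruct(raw, uniform_boundary, grid, frame_mask=mask).values)
    return {"motion": motion, "raw": raw, "truth_volumes": truth_phase_volumes,
            "recons": np.stack(phase_recons), "volume": volume, "truth": truth}


@pytest.fixture(scope="session")
def sos_study(two_zone_boundary):
    """Deep point absorber imaged through the two-zone medium at 1540 m/s."""
    from hepatopat.sos import SosSearchSpec, estimate_sos

    boundary = two_zone_boundary.with_tissue_sos(1540.0)
    pitch = 0.15
    shape = (13, 13, 13)
    vals = np.zeros(shape)
    vals[6, 6, 6] = 1.0
    center = (0.5, 0.0, 0.6)
    origin = tuple(c - (n - 1) * pitch / 2 for c, n in zip(center, shape))
    volume = AbsorptionVolume(vals, pitch, origin)
    geom = ScanGeometry(hemisphere_radius_mm=25.0, elements_per_arc=24,
                        shots_per_sweep=40)
    raw = simulate_signals(volume, geom, boundary)
    roi = ReconGrid.centered((21, 21, 21), pitch, center_mm=center)
    spec = SosSearchSpec(grid_mps=np.arange(1400.0, 1700.0 + 1, 10.0), roi=roi)
    est, curve = estimate_sos(raw, boundary, spec)
    return {"boundary": boundary, "raw": raw, "roi": roi, "spec": spec,
            "estimate": est, "curve": curve, "true_sos": 1540.0,
            "center": center}


@pytest.fixture(scope="session")
def effect_pipeline():
    """Default effect-cohort pipeline run (6 lean vs 6 obese)."""
    from hepatopat.pipeline import run_pipeline

    return run_pipeline(seed=1)
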