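"""End-to-end cohort pipeline: phantoms -> images -> features -> statistics.

``run_pipeline`` generates a two-group phantom cohort, derives a feature
volume per subject (either through the full acoustic chain — simulate,
back-project, depth-compensate, high-pass, Frangi-enhance, composite — or
directly from the noisy phantom volume for cheap statistical studies),
segments liver and vessels, computes the five per-subject features
(V_liver, VVO, VND, mean AI, SoS estimate), and runs one-tailed Welch
tests between the groups with configurable alternative directions.

Every stage is a pure function of (config, master seed); the per-subject
speed-of-sound measurement simulates a deep calibration absorber through
the two-zone forward model with the subject's true tissue sound speed and
runs the autofocus search on it.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .acoustics import TissueBoundary
from .features import ai_map, mean_ai, mi_map, vdd_map, vnd, vvo
from .forward import ScanGeometry, add_noise, simulate_signals
from .phantom import (AbsorptionVolume, PhantomSpec, generate_phantom,
                      lean_spec, obese_spec, subject_seed)
from .recon import (ReconGrid, ReconVolume, compose_display, depth_compensate,
                    frangi_enhance, highpass_3d, ubp_reconstruct)
from .segmentation import liver_mask, skeletonize_and_count, vessel_mask
from .sos import SosSearchSpec, estimate_sos
from .stats import TestResult, welch_one_tailed

log = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "orthogonal_maps", "PipelineResult"]

FEATURES = ["v_liver_mm3", "vvo", "vnd_per_mm3", "mean_ai", "sos_est_mps"]


def default_config() -> dict:
    """The default desk-scale study configuration.

    The obese preset has a larger liver with fewer, more tortuous vessels
    and a lower true tissue sound speed than the lean preset, mirroring the
    expected fatty-liver contrasts; alternative directions state lean-group
    expectations relative to obese.
    """
    return {
        "cohort": {
            "n_per_group": 6,
            "grid_shape": [56, 56, 56],
            "voxel_pitch_mm": 0.15,
            "lean": {"liver_semiaxes_mm": [2.6, 2.8, 2.3], "n_vessels": 6,
                     "tortuosity": 0.25, "radius_range_mm": [0.3, 0.38],
                     "liver_center_mm": [0.0, 0.0, 0.3]},
            "obese": {"liver_semiaxes_mm": [3.0, 3.2, 2.6], "n_vessels": 3,
                      "tortuosity": 0.5, "radius_range_mm": [0.3, 0.42],
                      "liver_center_mm": [0.0, 0.0, 0.3],
                      "texture_amp": 0.3},
        },
        "image": {
            "mode": "direct",          # "direct" or "acoustic"
            "snr_db": 25.0,
            "geometry": {"hemisphere_radius_mm": 22.0, "elements_per_arc": 32,
                         "shots_per_sweep": 40},
            "boundary": {"ellipse_center_mm": [0.0, 0.0],
                         "semi_axes_mm": [5.5, 4.5],
                         "cap_plane_z_mm": -3.4,
                         "c_water_mps": 1498.0},
            "mu_eff_per_cm": 1.0,
            "highpass_cutoff_mm": 2.0,
            "frangi_scales_mm": [0.3, 0.45, 0.6],
            "compose_weight": 1.0,
        },
        "features": {"vdd_window_mm": 1.2, "mi_window_mm": 3.0,
                     "mi_stride": 4, "min_branch_voxels": 5},
        "sos": {"true_mps": {"lean": 1570.0, "obese": 1540.0},
                "between_subject_sd_mps": 8.0,
                "grid": [1450.0, 10.0, 1650.0],
                "snr_db": 30.0},
        "stats": {"alternatives": {"v_liver_mm3": "less", "vvo": "greater",
                                   "vnd_per_mm3": "greater",
                                   "mean_ai": "less",
                                   "sos_est_mps": "greater"}},
    }


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    tests: list[TestResult]
    manifest: dict
    maps: dict = field(default_factory=dict)


def orthogonal_maps(values: np.ndarray) -> dict[str, np.ndarray]:
    """Maximum amplitude projections along the three axes.

    Returned raw (the projection maximum equals the volume maximum);
    normalise downstream for display.
    """
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError("empty volume")
    return {"axial": v.max(axis=2), "coronal": v.max(axis=1),
            "sagittal": v.max(axis=0)}


def _phantom_spec(cfg: dict, group: str, seed: int) -> PhantomSpec:
    base = dict(grid_shape=tuple(cfg["cohort"]["grid_shape"]),
                voxel_pitch_mm=cfg["cohort"]["voxel_pitch_mm"], seed=seed)
    over = {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg["cohort"][group].items()}
    maker = lean_spec if group == "lean" else obese_spec
    return maker(**base, **over)


def _boundary(cfg: dict, c_tissue: float) -> TissueBoundary:
    b = cfg["image"]["boundary"]
    return TissueBoundary(ellipse_center_mm=tuple(b["ellipse_center_mm"]),
                          semi_axes_mm=tuple(b["semi_axes_mm"]),
                          cap_plane_z_mm=b.get("cap_plane_z_mm"),
                          c_water_mps=b["c_water_mps"],
                          c_tissue_mps=c_tissue)


def _direct_volume(volume: AbsorptionVolume, snr_db: float, rng) -> np.ndarray:
    v = volume.values.astype(float)
    rms = np.sqrt(np.mean(v ** 2))
    noise = rng.normal(0.0, rms * 10 ** (-snr_db / 20.0), v.shape)
    return v + noise


def _acoustic_volume(volume: AbsorptionVolume, cfg: dict, c_tissue: float,
                     seed: int) -> tuple[np.ndarray, ReconGrid]:
    geom = ScanGeometry(**cfg["image"]["geometry"])
    boundary = _boundary(cfg, c_tissue)
    raw = simulate_signals(volume, geom, boundary)
    raw = add_noise(raw, cfg["image"]["snr_db"], seed)
    grid = ReconGrid(volume.shape, volume.voxel_pitch_mm, volume.origin_mm)
    rec = ubp_reconstruct(raw, boundary, grid)
    rec = depth_compensate(rec, cfg["image"]["mu_eff_per_cm"],
                           surface_z_mm=cfg["image"]["boundary"]["cap_plane_z_mm"])
    hp = highpass_3d(rec, cfg["image"]["highpass_cutoff_mm"])
    enh = frangi_enhance(hp, scales_mm=cfg["image"]["frangi_scales_mm"])
    comp = compose_display(rec, enh, cfg["image"]["compose_weight"])
    return comp.values, grid


def _measure_subject_sos(cfg: dict, true_c: float, seed: int) -> float:
    """Autofocus SoS estimate from a simulated deep calibration absorber."""
    pitch = 0.3
    shape = (9, 9, 9)
    vals = np.zeros(shape)
    vals[4, 4, 4] = 1.0
    vals[3, 4, 4] = vals[5, 4, 4] = vals[4, 3, 4] = vals[4, 5, 4] = 0.6
    center = (0.0, 0.0, 1.5)
    origin = tuple(c - (n - 1) * pitch / 2 for c, n in zip(center, shape))
    vol = AbsorptionVolume(vals, pitch, origin)
    geom = ScanGeometry(hemisphere_radius_mm=20.0, elements_per_arc=16,
                        shots_per_sweep=16)
    boundary = _boundary(cfg, true_c)
    raw = simulate_signals(vol, geom, boundary)
    raw = add_noise(raw, cfg["sos"]["snr_db"], seed)
    lo, step, hi = cfg["sos"]["grid"]
    roi = ReconGrid.centered((9, 9, 9), 0.3, center_mm=center)
    spec = SosSearchSpec(grid_mps=np.arange(lo, hi + step / 2, step), roi=roi)
    est, _ = estimate_sos(raw, boundary, spec)
    return est


def _subject_features(cfg: dict, group: str, index: int, master_seed: int
                      ) -> dict:
    seed = subject_seed(master_seed, group, index)
    rng = np.random.default_rng(seed + 1)
    spec = _phantom_spec(cfg, group, seed)
    volume, truth = generate_phantom(spec)

    sos_cfg = cfg["sos"]
    true_c = float(sos_cfg["true_mps"][group]
                   + rng.normal(0.0, sos_cfg["between_subject_sd_mps"]))
    true_c = float(np.clip(true_c, 1400.0, 1700.0))

    mode = cfg["image"]["mode"]
    if mode == "acoustic":
        feat_vol, grid = _acoustic_volume(volume, cfg, true_c, seed + 2)
    elif mode == "direct":
        feat_vol = _direct_volume(volume, cfg["image"]["snr_db"], rng)
        grid = ReconGrid(volume.shape, volume.voxel_pitch_mm, volume.origin_mm)
    else:
        raise ValueError(f"unknown image mode {mode!r}")

    pitch = grid.voxel_pitch_mm
    thr, lmask = liver_mask(feat_vol, pitch)
    enh = frangi_enhance(ReconVolume(np.clip(feat_vol, 0, None), grid),
                         scales_mm=cfg["image"]["frangi_scales_mm"])
    vthr, vmask = vessel_mask(enh.values, lmask, intensity_volume=feat_vol)
    graph = skeletonize_and_count(vmask, cfg["features"]["min_branch_voxels"])

    fcfg = cfg["features"]
    m_vdd = vdd_map(feat_vol, pitch, window_mm=fcfg["vdd_window_mm"])
    _, _, _, a = mi_map(feat_vol, pitch, window_mm=fcfg["mi_window_mm"],
                        stride=fcfg["mi_stride"])
    ai = ai_map(m_vdd, a)

    sos_est = _measure_subject_sos(cfg, true_c, seed + 3)

    return {
        "subject": f"{group}-{index}",
        "group": group,
        "v_liver_mm3": lmask.volume_mm3,
        "vvo": vvo(vmask.volume_mm3, lmask.volume_mm3),
        "vnd_per_mm3": vnd(graph.n_vessels, lmask.volume_mm3),
        "mean_ai": mean_ai(ai, lmask),
        "sos_est_mps": sos_est,
        "n_vessels": graph.n_vessels,
        "true_sos_mps": true_c,
        "n_vessels_true": truth.n_vessels_true,
        "vessel_fraction_true": truth.vessel_fraction_true,
    }


def run_pipeline(config: dict | None = None, seed: int = 0,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full cohort study; deterministic in (config, seed).

    Stage failures are re-raised with the subject and stage attached; when
    ``outdir`` is given, the feature table, test results, orthogonal
    projections of the first subject of each group, and a JSON manifest are
    written there (partial outputs are kept on failure).
    """
    cfg = copy.deepcopy(default_config())
    _deep_update(cfg, config or {})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for group in ("lean", "obese"):
        for i in range(cfg["cohort"]["n_per_group"]):
            try:
                rows.append(_subject_features(cfg, group, i, seed))
            except Exception as e:
                if outdir is not None and rows:
                    pd.DataFrame(rows).to_csv(outdir / "features_partial.csv",
                                              index=False)
                raise RuntimeError(
                    f"pipeline stage 'features' failed for {group}[{i}]: {e}"
                ) from e
    table = pd.DataFrame(rows)

    tests = []
    alts = cfg["stats"]["alternatives"]
    lean_rows = table[table.group == "lean"]
    obese_rows = table[table.group == "obese"]
    for feat in FEATURES:
        tests.append(welch_one_tailed(lean_rows[feat], obese_rows[feat],
                                      alternative=alts[feat], feature=feat))

    manifest = {"seed": seed, "config": cfg,
                "n_subjects": len(table),
                "features": FEATURES}
    result = PipelineResult(feature_table=table, tests=tests, manifest=manifest)

    if outdir is not None:
        hio.save_feature_table(table, outdir / "features.csv")
        pd.DataFrame([t.__dict__ for t in tests]).to_csv(
            outdir / "welch_tests.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _write_figures(cfg, seed, outdir, table)
    return result


def _write_figures(cfg, seed, outdir, table):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for group in ("lean", "obese"):
        spec = _phantom_spec(cfg, group, subject_seed(seed, group, 0))
        volume, _ = generate_phantom(spec)
        maps = orthogonal_maps(volume.values)
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for ax, (name, img) in zip(axes, maps.items()):
            peak = img.max()
            ax.imshow((img / peak if peak > 0 else img).T, origin="lower",
                      cmap="magma")
            ax.set_title(f"{group} {name}")
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(outdir / f"map_{group}.png", dpi=120)
        plt.close(fig)

    fig, axes = plt.subplots(1, len(FEATURES), figsize=(3 * len(FEATURES), 3))
    for ax, feat in zip(axes, FEATURES):
        data = [table[table.group == g][feat] for g in ("lean", "obese")]
        ax.boxplot(data, tick_labels=["lean", "obese"])
        ax.set_title(feat)
    fig.tight_layout()
    fig.savefig(outdir / "feature_boxplots.png", dpi=120)
    plt.close(fig)


def _deep_update(base: dict, update: dict):
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
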