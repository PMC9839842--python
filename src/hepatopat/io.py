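"""File I/O: NIfTI/TIFF volumes, HDF5 raw channel data, masks, and tables.

Volumes carry their voxel pitch in the NIfTI header zooms.  Raw channel
data uses a simple HDF5 dialect: /traces (shots x elements x samples),
/time_axis, geometry attributes under /geometry, optional /phase_truth and
/gating/* datasets, with a ``format_version`` attribute for stability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .forward import RawSignalSet, ScanGeometry
from .gating import GatingResult
from .phantom import PhantomSpec
from .recon import ReconVolume
from .segmentation import BinaryMask, SkeletonGraph

FORMAT_VERSION = "1.0"

__all__ = ["save_nifti", "load_nifti", "save_tiff", "save_mask",
           "save_raw_h5", "load_raw_h5", "save_gating_h5",
           "spec_to_yaml", "spec_from_yaml", "save_feature_table",
           "skeleton_to_edge_list", "save_recon"]


def save_nifti(values: np.ndarray, voxel_pitch_mm: float, path) -> Path:
    path = Path(path)
    affine = np.diag([voxel_pitch_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms((voxel_pitch_mm,) * 3 + (() if values.ndim == 3 else (1.0,)))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), pitch


def save_recon(volume: ReconVolume, path) -> Path:
    """NIfTI payload plus a JSON sidecar holding the provenance."""
    path = save_nifti(volume.values, volume.voxel_pitch_mm, path)
    side = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    side.write_text(json.dumps(
        {"provenance": _jsonable(volume.provenance),
         "shape": list(volume.values.shape),
         "voxel_pitch_mm": volume.voxel_pitch_mm,
         "origin_mm": list(volume.grid.origin_mm)}, indent=2))
    return path


def save_tiff(values: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))
    return path


def save_mask(mask: BinaryMask, path) -> Path:
    affine = np.diag([mask.voxel_pitch_mm] * 3 + [1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    nib.save(img, str(path))
    return Path(path)


def save_raw_h5(raw: RawSignalSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("traces", data=raw.traces.astype(np.float32))
        f.create_dataset("time_axis", data=raw.time_axis_s)
        g = f.create_group("geometry")
        for k, v in dataclasses.asdict(raw.geometry).items():
            g.attrs[k] = v
        if raw.phase_truth is not None:
            f.create_dataset("phase_truth", data=np.asarray(raw.phase_truth))
        for k, v in raw.meta.items():
            f.attrs[f"meta_{k}"] = v
    return path


def load_raw_h5(path) -> RawSignalSet:
    with h5py.File(path, "r") as f:
        gattrs = dict(f["geometry"].attrs)
        for key in ("grid_shape", "polar_range_deg"):
            if key in gattrs:
                gattrs[key] = tuple(gattrs[key])
        gattrs = {k: (v.item() if isinstance(v, np.generic) else v)
                  for k, v in gattrs.items()}
        if "polar_range_deg" in gattrs:
            gattrs["polar_range_deg"] = tuple(float(x) for x in gattrs["polar_range_deg"])
        geom = ScanGeometry(**{k: v for k, v in gattrs.items()
                               if k in ScanGeometry.__dataclass_fields__})
        phase = f["phase_truth"][()] if "phase_truth" in f else None
        meta = {k[5:]: v for k, v in f.attrs.items() if k.startswith("meta_")}
        return RawSignalSet(traces=f["traces"][()],
                            time_axis_s=f["time_axis"][()], geometry=geom,
                            phase_truth=phase, meta=meta)


def save_gating_h5(result: GatingResult, path) -> Path:
    """Append the gating summary under /gating in an existing raw file."""
    path = Path(path)
    with h5py.File(path, "a") as f:
        if "gating" in f:
            del f["gating"]
        g = f.create_group("gating")
        g.create_dataset("first_arrival", data=result.first_arrival)
        g.create_dataset("smoothed", data=result.smoothed)
        g.create_dataset("diff", data=result.diff)
        g.create_dataset("peaks", data=result.peaks)
        g.create_dataset("troughs", data=result.troughs)
        g.create_dataset("removed_mask", data=result.removed_mask)
        g.attrs["half_cycle_shots"] = result.half_cycle_shots
        if result.phase_labels is not None:
            g.create_dataset("phase_labels", data=result.phase_labels)
    return path


def spec_to_yaml(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(spec)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def spec_from_yaml(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return PhantomSpec(**d)


def save_feature_table(table: pd.DataFrame, path) -> Path:
    """One row per subject; columns in the documented order."""
    order = ["subject", "group", "v_liver_mm3", "vvo", "vnd_per_mm3",
             "mean_ai", "sos_est_mps"]
    cols = [c for c in order if c in table.columns] + \
        [c for c in table.columns if c not in order]
    table[cols].to_csv(path, index=False)
    return Path(path)


def skeleton_to_edge_list(graph: SkeletonGraph, path) -> Path:
    """Plain-text skeleton edges: one 'i1 j1 k1 i2 j2 k2' line per 26-edge."""
    path = Path(path)
    lines = [f"# branches={graph.n_vessels} pitch_mm={graph.voxel_pitch_mm}"]
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)
               if tuple(o) != (1, 1, 1)]
    vox = np.argwhere(graph.branch_labels > 0)
    labels = graph.branch_labels
    voxset = {tuple(v): labels[tuple(v)] for v in vox}
    for v in vox:
        for off in offsets:
            nb = tuple(v + off - 1)
            if nb in voxset and voxset[nb] == labels[tuple(v)] and tuple(v) < nb:
                lines.append(" ".join(map(str, (*v, *nb))))
    path.write_text("\n".join(lines) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
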