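"""Phase-resolved hemodynamics: motion-contrast maps and vessel area series.

Given a stack of phase-gated volumes spanning one respiratory cycle, two
analyses mirror the dynamic-imaging readouts: (1) the per-voxel Pearson
correlation between the voxel's phase sequence and the respiration pattern
(a motion-contrast map whose sign separates tissue moving with vs against
the diaphragm), and (2) the cross-sectional area of a chosen vessel tracked
across phases with a two-step threshold (a fixed coarse region, then a
per-frame 3-sigma threshold from the slice periphery), normalised to the
first phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["PhaseSeries", "MotionContrastVolume", "motion_contrast_map",
           "vessel_cross_section_series"]


@dataclass
class PhaseSeries:
    """Per-phase normalised values (first phase = 1) with across-cycle SEM."""

    phase_index: np.ndarray
    value_mean: np.ndarray
    value_sem: np.ndarray

    def __post_init__(self):
        if np.any(self.value_sem < 0):
            raise ValueError("SEM must be non-negative")


@dataclass
class MotionContrastVolume:
    """Per-voxel correlation with the respiration pattern, in [-1, 1]."""

    values: np.ndarray
    undefined: np.ndarray  # zero-variance voxels, excluded from rendering


def motion_contrast_map(phase_volumes: np.ndarray,
                        respiration_pattern: np.ndarray,
                        method: str = "pearson") -> MotionContrastVolume:
    """Correlate every voxel's phase sequence with the respiration pattern.

    ``phase_volumes`` has shape (phases, nx, ny, nz).  Zero-variance voxels
    are flagged undefined (NaN).  ``method`` is "pearson" (default) or
    "spearman" (rank-transformed Pearson).
    """
    pv = np.asarray(phase_volumes, dtype=float)
    pat = np.asarray(respiration_pattern, dtype=float)
    if pv.ndim != 4 or pv.shape[0] < 3:
        raise ValueError("need at least 3 phase volumes")
    if len(pat) != pv.shape[0]:
        raise ValueError("pattern length must equal the phase count")
    if method == "spearman":
        pv = np.argsort(np.argsort(pv, axis=0), axis=0).astype(float)
        pat = np.argsort(np.argsort(pat)).astype(float)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    pvc = pv - pv.mean(axis=0)
    patc = pat - pat.mean()
    num = np.tensordot(patc, pvc, axes=(0, 0))
    den = np.sqrt((pvc ** 2).sum(axis=0) * (patc ** 2).sum())
    undefined = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(undefined, np.nan, num / np.where(den == 0, 1.0, den))
    r = np.clip(r, -1.0, 1.0)
    return MotionContrastVolume(values=r, undefined=undefined)


def _slice_2d(volume: np.ndarray, axis: int, index: int) -> np.ndarray:
    return np.take(volume, index, axis=axis)


def _crop_bounds(coarse: np.ndarray, margin_px: int) -> tuple[slice, slice]:
    idx = np.argwhere(coarse)
    lo = np.maximum(idx.min(axis=0) - margin_px, 0)
    hi = np.minimum(idx.max(axis=0) + margin_px + 1, coarse.shape)
    return slice(lo[0], hi[0]), slice(lo[1], hi[1])


def _frame_area(img: np.ndarray, coarse: np.ndarray, pixel_area: float,
                border_px: int, crop: tuple[slice, slice]) -> float:
    # the "cross-sectional image" is the crop around the vessel, so the
    # peripheral square samples the immediately surrounding tissue
    img = img[crop]
    coarse = coarse[crop]
    b = border_px
    frame = np.zeros(img.shape, dtype=bool)
    frame[:b, :] = True
    frame[-b:, :] = True
    frame[:, :b] = True
    frame[:, -b:] = True
    bg = img[frame & ~coarse]
    thr = np.mean(np.abs(bg)) + 3.0 * np.std(bg)
    seg = (np.abs(img) > thr) & coarse
    return float(seg.sum()) * pixel_area


def vessel_cross_section_series(phase_volumes: np.ndarray,
                                slice_spec: tuple[int, int],
                                coarse_mask: np.ndarray,
                                voxel_pitch_mm: float,
                                border_px: int = 3,
                                margin_px: int = 6) -> PhaseSeries:
    """Two-step-threshold cross-sectional area of one vessel across phases.

    ``phase_volumes`` is (phases, nx, ny, nz) for a single averaged cycle or
    (cycles, phases, nx, ny, nz) for per-cycle data (then the SEM across
    cycles is reported).  ``slice_spec`` = (axis, index) picks the
    cross-sectional plane; ``coarse_mask`` is the fixed step-1 region that
    isolates the vessel in that plane.  Areas (mm^2) are normalised to the
    first phase; an empty per-frame segmentation yields area 0 and is
    flagged in the log.
    """
    pv = np.asarray(phase_volumes, dtype=float)
    if pv.ndim == 4:
        pv = pv[None]
    if pv.ndim != 5:
        raise ValueError("phase_volumes must be 4D or 5D")
    axis, index = slice_spec
    n_cycles, n_phases = pv.shape[:2]
    pixel_area = voxel_pitch_mm ** 2
    if not coarse_mask.any():
        raise ValueError("coarse mask is empty")
    crop = _crop_bounds(coarse_mask, margin_px)
    areas = np.empty((n_cycles, n_phases))
    for c in range(n_cycles):
        for p in range(n_phases):
            img = _slice_2d(pv[c, p], axis, index)
            if coarse_mask.shape != img.shape:
                raise ValueError("coarse mask must match the slice shape")
            areas[c, p] = _frame_area(img, coarse_mask, pixel_area, border_px,
                                      crop)
    if np.any(areas == 0):
        log.warning("empty vessel segmentation in %d frame(s)",
                    int((areas == 0).sum()))
    ref = areas[:, 0].copy()
    if np.any(ref == 0):
        raise ValueError("vessel segmentation empty at the reference phase")
    norm = areas / ref[:, None]
    mean = norm.mean(axis=0)
    sem = (norm.std(axis=0, ddof=1) / np.sqrt(n_cycles)) if n_cycles > 1 \
        else np.zeros(n_phases)
    return PhaseSeries(phase_index=np.arange(n_phases), value_mean=mean,
                       value_sem=sem)
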