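"""Quantitative angiographic features of the hepatic volume.

Five per-subject quantities are derived from the reconstructed, enhanced
volume and its masks:

* liver volume ``V_liver`` (mm^3) and vessel volume occupancy
  ``VVO = V_vessel / V_liver``;
* vessel number density ``VND = N_vessel / V_liver`` (mm^-3);
* vessel distribution diversity (VDD): the Shannon entropy (bits) of the
  256-bin value histogram inside a 1.2 mm sliding cube, mapped to the window
  centre;
* morphological irregularity (MI): for a 3 mm sliding 2D window rotated in
  10-degree steps over 180 degrees, the normalised SVD dominancy
  Sigma11(theta) = sigma_1 / sum(sigma_i) is tracked and
  A = exp(-(max_theta Sigma11 - min_theta Sigma11)); maps from the three
  slicing axes are averaged;
* angiographic irregularity AI: the voxelwise product of the VDD and MI
  maps, averaged inside the liver mask.

CNR and profile-FWHM helpers quantify vessel visibility and apparent size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import window_entropy
from .segmentation import BinaryMask

log = logging.getLogger(__name__)

__all__ = ["vvo", "vnd", "vdd_map", "mi_map", "ai_map", "mean_ai",
           "cnr", "profile_fwhm", "FeatureMaps"]


@dataclass
class FeatureMaps:
    """The texture maps entering the AI feature."""

    m_vdd: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    a_z: np.ndarray
    a: np.ndarray
    ai: np.ndarray


def vvo(v_vessel_mm3: float, v_liver_mm3: float) -> float:
    """Vessel volume occupancy: vessel-mask volume over liver-mask volume."""
    if v_liver_mm3 <= 0:
        raise ValueError("liver volume must be positive")
    return float(v_vessel_mm3) / float(v_liver_mm3)


def vnd(n_vessels: int, v_liver_mm3: float) -> float:
    """Vessel number density: counted vessels per mm^3 of liver."""
    if v_liver_mm3 <= 0:
        raise ValueError("liver volume must be positive")
    return float(n_vessels) / float(v_liver_mm3)


def vdd_map(volume: np.ndarray, voxel_pitch_mm: float,
            window_mm: float = 1.2, n_bins: int = 256) -> np.ndarray:
    """Sliding-window histogram-entropy (VDD) map in bits.

    Values are binned into ``n_bins`` equal-width bins spanning the global
    min-max of the volume (a shared scale, so windows with different local
    contrast remain comparable), then each fully interior window's histogram
    entropy E = -sum P_i log2 P_i is assigned to its centre voxel.  Edge
    voxels are NaN.
    """
    v = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("volume must be finite")
    w = max(int(round(window_mm / voxel_pitch_mm)), 3)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        binned = np.zeros(v.shape, dtype=np.int64)
    else:
        binned = np.clip(((v - lo) / (hi - lo) * n_bins).astype(np.int64),
                         0, n_bins - 1)
    return window_entropy(binned, w, n_bins)


def _rotation_samplers(w: int, angles_deg: np.ndarray):
    """Precompute bilinear gather indices/weights for each rotation angle.

    Sampling is restricted to the inscribed circle (corners masked to zero),
    which makes a constant window exactly rotation invariant.
    """
    c = (w - 1) / 2.0
    jj, kk = np.meshgrid(np.arange(w), np.arange(w), indexing="ij")
    u = jj - c
    vv = kk - c
    # inscribed circle: every support pixel stays inside the source box
    # under any rotation, so a constant window is exactly invariant
    circle = (u ** 2 + vv ** 2) <= ((w - 1) / 2.0) ** 2
    samplers = []
    for th in np.deg2rad(angles_deg):
        ur = np.cos(th) * u - np.sin(th) * vv + c
        vr = np.sin(th) * u + np.cos(th) * vv + c
        i0 = np.clip(np.floor(ur).astype(int), 0, w - 2)
        j0 = np.clip(np.floor(vr).astype(int), 0, w - 2)
        fu = np.clip(ur - i0, 0.0, 1.0)
        fv = np.clip(vr - j0, 0.0, 1.0)
        inside = (ur >= 0) & (ur <= w - 1) & (vr >= 0) & (vr <= w - 1) & circle
        wts = np.stack([(1 - fu) * (1 - fv), (1 - fu) * fv,
                        fu * (1 - fv), fu * fv]) * inside
        samplers.append((i0, j0, wts.astype(np.float64)))
    return samplers


def _window_anisotropy(windows: np.ndarray, samplers, s11_mode: str) -> np.ndarray:
    """A = exp(-(max - min) of Sigma11 over the rotation schedule).

    ``windows`` is (n, w, w).  All-zero windows (no structure) get A = 1.
    """
    n, w, _ = windows.shape
    s11_min = np.full(n, np.inf)
    s11_max = np.full(n, -np.inf)
    zero = ~np.any(windows != 0, axis=(1, 2))
    for i0, j0, wts in samplers:
        rot = (wts[0] * windows[:, i0, j0]
               + wts[1] * windows[:, i0, j0 + 1]
               + wts[2] * windows[:, i0 + 1, j0]
               + wts[3] * windows[:, i0 + 1, j0 + 1])
        # singular values via the symmetric Gram spectrum (faster batched)
        gram = rot @ np.swapaxes(rot, 1, 2)
        sv = np.sqrt(np.clip(np.linalg.eigvalsh(gram)[:, ::-1], 0.0, None))
        denom = sv.sum(axis=1) if s11_mode == "sum" else np.linalg.norm(sv, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s11 = np.where(denom > 0, sv[:, 0] / denom, 1.0)
        s11_min = np.minimum(s11_min, s11)
        s11_max = np.maximum(s11_max, s11)
    a = np.exp(-(s11_max - s11_min))
    a[zero] = 1.0
    if zero.any():
        log.debug("%d all-zero MI windows set to A=1", int(zero.sum()))
    return a


def mi_map(volume: np.ndarray, voxel_pitch_mm: float, window_mm: float = 3.0,
           dtheta_deg: float = 10.0, stride: int = 2,
           s11_mode: str = "sum") -> FeatureMaps | tuple:
    """Morphological-irregularity maps along the three slicing axes.

    Returns (A_x, A_y, A_z, A) where each per-axis map holds
    exp(-(range over theta of Sigma11)) at evaluated window centres (NaN
    elsewhere) and A is their voxelwise mean.  ``stride`` subsamples window
    centres in-plane for speed; stride 1 evaluates every centre.
    ``s11_mode`` selects the dominancy normalisation: dominant singular
    value over the sum of singular values ("sum") or over their Euclidean
    norm ("l2").
    """
    v = np.asarray(volume, dtype=float)
    w = int(round(window_mm / voxel_pitch_mm))
    if w < 5:
        raise ValueError("MI window must be at least 5 pixels per side")
    if s11_mode not in ("sum", "l2"):
        raise ValueError("s11_mode must be 'sum' or 'l2'")
    angles = np.arange(0.0, 180.0, dtheta_deg)
    samplers = _rotation_samplers(w, angles)
    half = w // 2

    maps = []
    chunk = 8192
    for axis in range(3):
        vol = np.moveaxis(v, axis, 0)  # slices along this axis
        ns, n1, n2 = vol.shape
        amap = np.full(vol.shape, np.nan)
        c1 = np.arange(half, n1 - (w - half) + 1, stride)
        c2 = np.arange(half, n2 - (w - half) + 1, stride)
        if len(c1) == 0 or len(c2) == 0:
            maps.append(np.moveaxis(amap, 0, axis))
            continue
        # gather every window of every slice into one batch (chunked), so
        # the rotation + SVD work runs as a few large vectorised calls
        view = np.lib.stride_tricks.sliding_window_view(vol, (w, w), axis=(1, 2))
        wins = view[:, c1 - half][:, :, c2 - half].reshape(-1, w, w)
        a_all = np.empty(wins.shape[0])
        for lo in range(0, wins.shape[0], chunk):
            a_all[lo:lo + chunk] = _window_anisotropy(
                np.ascontiguousarray(wins[lo:lo + chunk]), samplers, s11_mode)
        a_all = a_all.reshape(ns, len(c1), len(c2))
        for s in range(ns):
            amap[s][np.ix_(c1, c2)] = a_all[s]
        maps.append(np.moveaxis(amap, 0, axis))

    a_x, a_y, a_z = maps
    with np.errstate(invalid="ignore"):
        a = (a_x + a_y + a_z) / 3.0
    return a_x, a_y, a_z, a


def ai_map(m_vdd: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Angiographic irregularity: voxelwise product of the VDD and MI maps."""
    if m_vdd.shape != a.shape:
        raise ValueError("maps must be co-registered (same shape)")
    return m_vdd * a


def mean_ai(ai: np.ndarray, liver: BinaryMask) -> float:
    """Mean AI over liver voxels where both maps are defined."""
    sel = liver.values & np.isfinite(ai)
    if not sel.any():
        raise ValueError("no defined AI voxels inside the liver mask")
    return float(ai[sel].mean())


def cnr(volume: np.ndarray, signal_roi: np.ndarray,
        background_roi: np.ndarray) -> float:
    """Contrast-to-noise ratio: (mean_signal - mean_bg) / std_bg."""
    s = volume[signal_roi]
    b = volume[background_roi]
    if s.size == 0 or b.size == 0:
        raise ValueError("signal and background ROIs must be non-empty")
    if np.any(signal_roi & background_roi):
        raise ValueError("signal and background ROIs must be disjoint")
    sd = b.std()
    if sd == 0:
        raise ValueError("background has zero variance")
    return float((s.mean() - b.mean()) / sd)


def profile_fwhm(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum of a single-peaked 1D profile (mm).

    The half-maximum crossings on either side of the global peak are found
    by linear interpolation between samples.
    """
    p = np.asarray(profile, dtype=float)
    if p.max() <= p.min():
        raise ValueError("flat profile has no peak")
    i_pk = int(np.argmax(p))
    half = p.min() + (p.max() - p.min()) / 2.0

    def cross(idx_range):
        prev = i_pk
        for i in idx_range:
            if p[i] < half:
                # linear interpolation between i and prev
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + (i - prev) * frac
            prev = i
        return idx_range[-1] if len(idx_range) else i_pk

    left = cross(range(i_pk - 1, -1, -1))
    right = cross(range(i_pk + 1, len(p)))
    return float((right - left) * spacing_mm)
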