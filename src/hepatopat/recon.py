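"""Dual speed-of-sound universal back-projection and image post-processing.

Reconstruction follows the delay-and-sum universal back-projection (UBP)
scheme: each voxel accumulates the temporal term b(t) = 2 p(t) - 2 t p'(t)
of every retained detector trace, evaluated at the straight-ray two-zone
travel time, with uniform per-element weights.  Post-processing mirrors the
standard hepatic-angiogram chain: exponential depth-gain compensation, 3D
Gaussian high-pass filtering, Hessian-based Frangi vessel enhancement, and
compositing of the self-normalised enhanced image back onto the base image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import frangi as _skimage_frangi

from . import _kernels
from .acoustics import TissueBoundary, travel_time  # noqa: F401  (re-export)
from .forward import RawSignalSet

log = logging.getLogger(__name__)

__all__ = ["ReconGrid", "ReconVolume", "fit_half_ellipse", "travel_time",
           "ubp_reconstruct", "depth_compensate", "frangi_enhance",
           "highpass_3d", "compose_display"]


@dataclass(frozen=True)
class ReconGrid:
    """Axis-aligned reconstruction lattice (voxel centres in world mm)."""

    shape: tuple[int, int, int]
    voxel_pitch_mm: float = 0.15
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel_pitch_mm <= 0:
            raise ValueError("voxel pitch must be positive")

    @classmethod
    def centered(cls, shape, voxel_pitch_mm=0.15, center_mm=(0.0, 0.0, 0.0)):
        origin = tuple(c - (n - 1) * voxel_pitch_mm / 2.0
                       for c, n in zip(center_mm, shape))
        return cls(tuple(shape), voxel_pitch_mm, origin)

    def axes_mm(self):
        return tuple(self.origin_mm[i] + np.arange(self.shape[i]) * self.voxel_pitch_mm
                     for i in range(3))


@dataclass
class ReconVolume:
    """Reconstructed scalar volume plus the parameters that produced it."""

    values: np.ndarray
    grid: ReconGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed values must be finite")

    @property
    def voxel_pitch_mm(self) -> float:
        return self.grid.voxel_pitch_mm

    def with_values(self, values, **extra) -> "ReconVolume":
        return ReconVolume(values, self.grid, {**self.provenance, **extra})


def fit_half_ellipse(volume: ReconVolume, surface_threshold: float,
                     c_water_mps: float = 1498.0,
                     c_tissue_mps: float = 1540.0) -> TissueBoundary:
    """Least-squares half-ellipse fit to the detected skin surface.

    From the central body-axis slice, the lowest above-threshold voxel of
    each x column gives a surface point cloud; an axis-aligned conic
    A x^2 + C z^2 + D x + E z + 1 = 0 is fitted in the least-squares sense
    and converted to centre + semi-axes.  The fitted boundary is extruded
    along the body axis.  Residual RMS (mm) is logged and returned in the
    boundary via the fit metadata on the module logger.
    """
    vals = np.abs(volume.values)
    xs, ys, zs = volume.grid.axes_mm()
    j = vals.shape[1] // 2
    sl = vals[:, j, :]
    pts = []
    for i in range(sl.shape[0]):
        above = np.nonzero(sl[i] > surface_threshold)[0]
        if above.size:
            # per column, the surface voxel on the curved (far) side of the
            # cap plane; the flat cap itself is interior to the conic
            pts.append((xs[i], zs[above[-1]]))
    if len(pts) < 20:
        raise ValueError(f"only {len(pts)} surface points found (need >= 20)")
    pts = np.asarray(pts)
    x, z = pts[:, 0], pts[:, 1]
    # axis-aligned conic A x^2 + C z^2 + D x + E z + 1 = 0 in least squares;
    # a real ellipse requires A and C of equal sign and positive a^2, b^2
    Mdes = np.column_stack([x ** 2, z ** 2, x, z])
    coef, *_ = np.linalg.lstsq(Mdes, -np.ones_like(x), rcond=None)
    A, C, D, E = coef
    if A * C <= 0:
        raise ValueError("surface points do not fit an ellipse")
    cx = -D / (2 * A)
    cz = -E / (2 * C)
    rhs = A * cx ** 2 + C * cz ** 2 - 1.0
    if rhs / A <= 0 or rhs / C <= 0:
        raise ValueError("degenerate ellipse fit")
    a = float(np.sqrt(rhs / A))
    b = float(np.sqrt(rhs / C))
    resid = A * x ** 2 + C * z ** 2 + D * x + E * z + 1.0
    rms = float(np.sqrt(np.mean(resid ** 2)))
    log.info("half-ellipse fit: center=(%.2f, %.2f) mm, semi-axes=(%.2f, %.2f) "
             "mm, algebraic residual RMS %.3g", cx, cz, a, b, rms)
    return TissueBoundary(ellipse_center_mm=(float(cx), float(cz)),
                          semi_axes_mm=(a, b), c_water_mps=c_water_mps,
                          c_tissue_mps=c_tissue_mps)


def _backprojection_term(raw: RawSignalSet) -> np.ndarray:
    """b(t) = 2 p(t) - 2 t p'(t), derivative by centred finite differences."""
    p = raw.traces.astype(np.float64)
    fs = raw.sampling_rate_hz
    dp = np.gradient(p, axis=-1) * fs
    t = raw.time_axis_s[None, None, :]
    return 2.0 * p - 2.0 * t * dp


def ubp_reconstruct(raw: RawSignalSet, boundary: TissueBoundary | None,
                    grid: ReconGrid,
                    frame_mask: np.ndarray | None = None,
                    c_mps: float | None = None) -> ReconVolume:
    """Universal back-projection onto a voxel grid, dual or single SoS.

    ``frame_mask`` marks shots to REMOVE (True = dropped); with all shots
    removed an "empty detection" error is raised.  Passing ``boundary=None``
    with ``c_mps`` performs single-SoS UBP.  Linear in the traces and
    invariant to shot ordering.
    """
    if boundary is None:
        if c_mps is None:
            raise ValueError("either a boundary or a uniform c_mps is required")
        boundary = TissueBoundary(ellipse_center_mm=(0.0, 0.0),
                                  semi_axes_mm=(1.0, 1.0),
                                  c_water_mps=c_mps, c_tissue_mps=c_mps)
    geom = raw.geometry
    n_shots = raw.n_shots
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if frame_mask.shape != (n_shots,):
            raise ValueError("frame_mask length must equal the shot count")
        keep = ~frame_mask
    else:
        keep = np.ones(n_shots, dtype=bool)
    if not keep.any():
        raise ValueError("empty detection: all frames masked")

    btr = _backprojection_term(raw)[keep]
    det = geom.all_positions()[keep]
    n_det = det.shape[0] * det.shape[1]
    btr = np.ascontiguousarray(btr.reshape(n_det, -1).astype(np.float32))
    det = np.ascontiguousarray(det.reshape(n_det, 3).astype(np.float64))

    xs, ys, zs = (np.ascontiguousarray(a) for a in grid.axes_mm())
    uniform = boundary.c_water_mps == boundary.c_tissue_mps
    # tile detectors so each tile's traces stay cache-resident while the
    # voxel loops sweep the grid; the sum over tiles is exact
    tile = 512
    out = np.zeros(grid.shape, dtype=np.float64)
    for lo in range(0, n_det, tile):
        part = _kernels.ubp_backproject(
            btr[lo:lo + tile], det[lo:lo + tile], xs, ys, zs,
            geom.sampling_rate_hz, float(raw.time_axis_s[0]),
            1.0 / boundary.c_water_mps, 1.0 / boundary.c_tissue_mps,
            not uniform,
            boundary.ellipse_center_mm[0], boundary.ellipse_center_mm[1],
            boundary.semi_axes_mm[0], boundary.semi_axes_mm[1],
            boundary.cap_plane_z_mm)
        out += part * (min(lo + tile, n_det) - lo)
    out /= n_det
    prov = {
        "c_water_mps": boundary.c_water_mps,
        "c_tissue_mps": boundary.c_tissue_mps,
        "boundary_center_mm": tuple(boundary.ellipse_center_mm),
        "boundary_semi_axes_mm": tuple(boundary.semi_axes_mm),
        "retained_shots": int(keep.sum()),
        "total_shots": int(n_shots),
    }
    return ReconVolume(values=out, grid=grid, provenance=prov)


def depth_compensate(volume: ReconVolume, mu_eff_per_cm: float,
                     surface_z_mm: float | np.ndarray | None = None,
                     max_gain: float = 10.0) -> ReconVolume:
    """Exponential depth-gain compensation for optical fluence decay.

    Gain exp(mu_eff * depth) with depth measured upward from the
    illuminated tissue surface (scalar plane or per-(x, y) surface map),
    capped at ``max_gain``.  mu_eff = 0 is the identity.
    """
    if mu_eff_per_cm < 0:
        raise ValueError("mu_eff must be >= 0")
    if mu_eff_per_cm == 0:
        return volume.with_values(volume.values.copy(), depth_mu_eff=0.0)
    zs = volume.grid.axes_mm()[2]
    if surface_z_mm is None:
        surface_z_mm = float(zs[0])
    surface = np.asarray(surface_z_mm, dtype=float)
    if surface.ndim == 2:
        depth_cm = np.clip(zs[None, None, :] - surface[:, :, None], 0.0, None) / 10.0
    else:
        depth_cm = np.clip(zs - surface, 0.0, None)[None, None, :] / 10.0
    gain = np.minimum(np.exp(mu_eff_per_cm * depth_cm), max_gain)
    return volume.with_values(volume.values * gain,
                              depth_mu_eff=mu_eff_per_cm, depth_max_gain=max_gain)


def highpass_3d(volume: ReconVolume, cutoff_mm: float) -> ReconVolume:
    """Gaussian high-pass: volume minus its Gaussian low-pass.

    The low-pass kernel width is sigma = cutoff_mm / 2, so structure with
    wavelength at or below the cutoff is retained essentially in full
    (transfer 1 - exp(-2 pi^2 sigma^2 / lambda^2)).
    """
    pitch = volume.voxel_pitch_mm
    if cutoff_mm <= 2.0 * pitch:
        raise ValueError("cutoff must exceed twice the voxel pitch")
    sigma_vox = (cutoff_mm / 2.0) / pitch
    low = gaussian_filter(volume.values.astype(float), sigma_vox)
    return volume.with_values(volume.values - low, highpass_cutoff_mm=cutoff_mm)


def frangi_enhance(volume: ReconVolume,
                   scales_mm=(0.15, 0.3, 0.45, 0.6, 0.9),
                   alpha: float = 0.5, beta: float = 0.5,
                   c: float | None = None) -> ReconVolume:
    """3D Frangi vesselness (bright tubes), max over scales, in [0, 1]."""
    pitch = volume.voxel_pitch_mm
    scales_mm = np.atleast_1d(np.asarray(scales_mm, dtype=float))
    if scales_mm.min() < pitch:
        raise ValueError(
            f"smallest Frangi scale {scales_mm.min()} mm is below the voxel "
            f"pitch {pitch} mm")
    sigmas = scales_mm / pitch
    v = _skimage_frangi(volume.values.astype(float), sigmas=sigmas,
                        alpha=alpha, beta=beta, gamma=c,
                        black_ridges=False)
    peak = v.max()
    if peak > 0:
        v = v / peak
    return volume.with_values(v, frangi_scales_mm=tuple(scales_mm),
                              frangi_alpha=alpha, frangi_beta=beta)


def compose_display(base: ReconVolume, enhanced: ReconVolume,
                    weight: float) -> ReconVolume:
    """Add the self-normalised enhanced image back onto the base image."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight == 0:
        return base.with_values(base.values.copy())
    e = enhanced.values
    peak = np.abs(e).max()
    if peak > 0:
        e = e / peak
    scale = np.abs(base.values).max()
    return base.with_values(base.values + weight * scale * e,
                            compose_weight=weight)
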