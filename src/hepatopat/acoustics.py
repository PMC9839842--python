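"""Two-zone acoustic geometry: the water/tissue interface and travel times.

The imaged body rests above the coupling-fluid bath.  Its axial cross-section
is approximated by a half ellipse in the (x, z) plane — the interior of an
axis-aligned ellipse cut by the flat plane z = cap_plane_z_mm — extruded
along the body axis (y) into a half-elliptic cylinder.  Sound speed is
uniform within each zone and refraction at the interface is neglected, so a
ray travels straight from a field point to a detector and its delay is the
path length in each zone divided by that zone's speed of sound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import seg_tissue_fraction

_MM_TO_M = 1.0e-3

__all__ = ["TissueBoundary", "travel_time", "segment_tissue_fraction",
           "points_in_tissue"]


@dataclass(frozen=True)
class TissueBoundary:
    """Half-elliptic-cylinder tissue zone immersed in coupling water.

    Parameters
    ----------
    ellipse_center_mm : (x, z) centre of the cross-sectional ellipse.
    semi_axes_mm : (a, b) semi-axes along x and z.
    cap_plane_z_mm : flat plane closing the half ellipse; tissue occupies
        z >= cap_plane_z_mm.  Defaults to the ellipse centre height.
    c_water_mps, c_tissue_mps : zone speeds of sound in m/s.
    """

    ellipse_center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    c_water_mps: float = 1498.0
    c_tissue_mps: float = 1540.0
    cap_plane_z_mm: float | None = None
    cylinder_axis: str = "y"

    def __post_init__(self):
        a, b = self.semi_axes_mm
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        for c in (self.c_water_mps, self.c_tissue_mps):
            if not 1300.0 <= c <= 1800.0:
                raise ValueError(f"speed of sound {c} m/s outside [1300, 1800]")
        if self.cylinder_axis != "y":
            raise ValueError("only a y-aligned body axis is supported")
        if self.cap_plane_z_mm is None:
            object.__setattr__(self, "cap_plane_z_mm",
                               float(self.ellipse_center_mm[1]))

    def with_tissue_sos(self, c_tissue_mps: float) -> "TissueBoundary":
        return replace(self, c_tissue_mps=float(c_tissue_mps))


def points_in_tissue(points_mm: np.ndarray, boundary: TissueBoundary) -> np.ndarray:
    """Boolean tissue membership for points of shape (..., 3)."""
    p = np.asarray(points_mm, dtype=float)
    cx, cz = boundary.ellipse_center_mm
    a, b = boundary.semi_axes_mm
    ell = ((p[..., 0] - cx) / a) ** 2 + ((p[..., 2] - cz) / b) ** 2 <= 1.0
    return ell & (p[..., 2] >= boundary.cap_plane_z_mm)


def segment_tissue_fraction(a_mm: np.ndarray, b_mm: np.ndarray,
                            boundary: TissueBoundary) -> np.ndarray:
    """Fraction of each straight segment a->b lying inside the tissue zone.

    Closed-form: the line's intersection with the elliptic cylinder is a
    quadratic root interval in the segment parameter, the cap plane adds a
    half-line, and the tissue chord is their intersection with [0, 1].
    """
    A = np.asarray(a_mm, dtype=float)
    B = np.asarray(b_mm, dtype=float)
    A, B = np.broadcast_arrays(A, B)
    cx, cz = boundary.ellipse_center_mm
    ea, eb = boundary.semi_axes_mm
    zcap = boundary.cap_plane_z_mm

    d = B - A
    ex = (A[..., 0] - cx) / ea
    ez = (A[..., 2] - cz) / eb
    fx = d[..., 0] / ea
    fz = d[..., 2] / eb
    qa = fx ** 2 + fz ** 2
    qb = 2.0 * (ex * fx + ez * fz)
    qc = ex ** 2 + ez ** 2 - 1.0

    degenerate = qa < 1.0e-18
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = qb ** 2 - 4.0 * qa * qc
        sq = np.sqrt(np.maximum(disc, 0.0))
        t0e = np.where(degenerate, np.where(qc <= 0, 0.0, 1.0),
                       (-qb - sq) / (2.0 * qa))
        t1e = np.where(degenerate, np.where(qc <= 0, 1.0, 0.0),
                       (-qb + sq) / (2.0 * qa))
        miss = (~degenerate) & (disc <= 0.0)
        t0e = np.where(miss, 1.0, t0e)
        t1e = np.where(miss, 0.0, t1e)

        dz = d[..., 2]
        az = A[..., 2]
        tcap = (zcap - az) / np.where(dz == 0.0, np.inf, dz)
        t0c = np.where(dz > 0, tcap, -1.0e30)
        t1c = np.where(dz < 0, tcap, 1.0e30)
        flat_out = (np.abs(dz) < 1.0e-18) & (az < zcap)
        t0c = np.where(flat_out, 1.0e30, t0c)

    lo = np.maximum(0.0, np.maximum(t0e, t0c))
    hi = np.minimum(1.0, np.minimum(t1e, t1c))
    return np.maximum(hi - lo, 0.0)


def travel_time(voxel_mm: np.ndarray, detector_mm: np.ndarray,
                boundary: TissueBoundary) -> np.ndarray:
    """Straight-ray acoustic delay (seconds) between field points and detectors.

    The segment is split at its closed-form intersection with the
    half-elliptic cylinder and each part is divided by its zone's speed of
    sound.  Reduces exactly to Euclidean distance over c when the two zone
    speeds coincide; a zero-length segment has zero delay.
    """
    A = np.asarray(voxel_mm, dtype=float)
    B = np.asarray(detector_mm, dtype=float)
    A, B = np.broadcast_arrays(A, B)
    length_m = np.linalg.norm(B - A, axis=-1) * _MM_TO_M
    if boundary.c_water_mps == boundary.c_tissue_mps:
        return length_m / boundary.c_water_mps
    frac = segment_tissue_fraction(A, B, boundary)
    l_tissue = length_m * frac
    return l_tissue / boundary.c_tissue_mps + (length_m - l_tissue) / boundary.c_water_mps


def travel_time_scalar(a_mm, b_mm, boundary: TissueBoundary) -> float:
    """Scalar convenience wrapper over the numba segment kernel (self-check)."""
    ax, ay, az = (float(v) for v in a_mm)
    bx, by, bz = (float(v) for v in b_mm)
    r = float(np.hypot(np.hypot(bx - ax, by - ay), bz - az))
    f = seg_tissue_fraction(ax, ay, az, bx, by, bz,
                            boundary.ellipse_center_mm[0],
                            boundary.ellipse_center_mm[1],
                            boundary.semi_axes_mm[0],
                            boundary.semi_axes_mm[1],
                            boundary.cap_plane_z_mm)
    lm = r * _MM_TO_M
    return lm * f / boundary.c_tissue_mps + lm * (1 - f) / boundary.c_water_mps
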