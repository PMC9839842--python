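"""Numba-compiled inner loops for the forward projector and back-projector.

All kernels are pure functions of scalars and contiguous arrays so that they
can be cached and reused across the simulation and reconstruction paths.
Lengths are in millimetres, times in seconds, speeds in metres per second.
"""

import numpy as np
from numba import njit

_MM_TO_M = 1.0e-3


@njit(cache=True, fastmath=True)
def seg_tissue_fraction(ax, ay, az, bx, by, bz, ecx, ecz, ea, eb, zcap):
    """Fraction of the straight segment A->B lying inside the tissue zone.

    The tissue zone is the half-elliptic cylinder
    {((x-ecx)/ea)^2 + ((z-ecz)/eb)^2 <= 1  and  z >= zcap}
    extruded along y. Returns a value in [0, 1]; 0 for a degenerate segment.
    """
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    # parametrise p(t) = A + t*d, t in [0,1]; tissue membership only depends
    # on (x, z), so the ellipse test reduces to a quadratic in t
    ex = (ax - ecx) / ea
    ez = (az - ecz) / eb
    fx = dx / ea
    fz = dz / eb
    qa = fx * fx + fz * fz
    qb = 2.0 * (ex * fx + ez * fz)
    qc = ex * ex + ez * ez - 1.0

    if qa < 1.0e-18:
        if qc <= 0.0:
            t0e, t1e = 0.0, 1.0
        else:
            return 0.0
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc <= 0.0:
            return 0.0
        sq = np.sqrt(disc)
        t0e = (-qb - sq) / (2.0 * qa)
        t1e = (-qb + sq) / (2.0 * qa)

    # half-space z >= zcap
    if dz > 1.0e-18:
        t0c = (zcap - az) / dz
        t1c = 1.0e30
    elif dz < -1.0e-18:
        t0c = -1.0e30
        t1c = (zcap - az) / dz
    else:
        if az >= zcap:
            t0c, t1c = -1.0e30, 1.0e30
        else:
            return 0.0

    lo = max(0.0, max(t0e, t0c))
    hi = min(1.0, min(t1e, t1c))
    if hi <= lo:
        return 0.0
    return hi - lo


@njit(cache=True, fastmath=True)
def forward_splat(src_xyz, src_amp, det_xyz, fs, t0, n_samples,
                  inv_cw, inv_ct, use_boundary, ecx, ecz, ea, eb, zcap):
    """Accumulate delta-arrivals from point sources onto detector time grids.

    Each source voxel contributes amp/(4*pi*r) at its travel-time delay,
    split linearly between the two nearest samples.  The caller convolves
    the result with the excitation pulse.
    """
    n_det = det_xyz.shape[0]
    n_src = src_xyz.shape[0]
    out = np.zeros((n_det, n_samples), dtype=np.float64)
    for d in range(n_det):
        px = det_xyz[d, 0]
        py = det_xyz[d, 1]
        pz = det_xyz[d, 2]
        for s in range(n_src):
            sx = src_xyz[s, 0]
            sy = src_xyz[s, 1]
            sz = src_xyz[s, 2]
            dx = px - sx
            dy = py - sy
            dz = pz - sz
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1.0e-9:
                continue
            if use_boundary:
                f = seg_tissue_fraction(sx, sy, sz, px, py, pz,
                                        ecx, ecz, ea, eb, zcap)
                tau = r * _MM_TO_M * (f * inv_ct + (1.0 - f) * inv_cw)
            else:
                tau = r * _MM_TO_M * inv_cw
            pos = (tau - t0) * fs
            i0 = int(np.floor(pos))
            if i0 < 0 or i0 >= n_samples - 1:
                continue
            w1 = pos - i0
            a = src_amp[s] / (4.0 * np.pi * r)
            out[d, i0] += a * (1.0 - w1)
            out[d, i0 + 1] += a * w1
    return out


@njit(cache=True, fastmath=True)
def ubp_backproject(btr, det_xyz, xs, ys, zs, fs, t0,
                    inv_cw, inv_ct, use_boundary, ecx, ecz, ea, eb, zcap):
    """Universal back-projection sum over detectors for every grid voxel.

    btr holds the per-detector back-projection term b(t) = 2 p(t) - 2 t p'(t)
    sampled on the acquisition time axis; trace values at fractional delays
    are obtained by linear interpolation.
    """
    n_det = det_xyz.shape[0]
    ns = btr.shape[1]
    nx = xs.shape[0]
    ny = ys.shape[0]
    nz = zs.shape[0]
    out = np.zeros((nx, ny, nz), dtype=np.float64)
    for i in range(nx):
        vx = xs[i]
        for j in range(ny):
            vy = ys[j]
            for k in range(nz):
                vz = zs[k]
                acc = 0.0
                for d in range(n_det):
                    dx = det_xyz[d, 0] - vx
                    dy = det_xyz[d, 1] - vy
                    dz = det_xyz[d, 2] - vz
                    r = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if use_boundary:
                        f = seg_tissue_fraction(
                            vx, vy, vz,
                            det_xyz[d, 0], det_xyz[d, 1], det_xyz[d, 2],
                            ecx, ecz, ea, eb, zcap)
                        tau = r * _MM_TO_M * (f * inv_ct + (1.0 - f) * inv_cw)
                    else:
                        tau = r * _MM_TO_M * inv_cw
                    pos = (tau - t0) * fs
                    i0 = int(np.floor(pos))
                    if i0 < 0 or i0 >= ns - 1:
                        continue
                    w1 = pos - i0
                    acc += btr[d, i0] * (1.0 - w1) + btr[d, i0 + 1] * w1
                out[i, j, k] = acc / n_det
    return out


@njit(cache=True)
def window_entropy(bin_volume, window, n_bins):
    """Sliding-window Shannon entropy (bits) of a pre-binned volume.

    bin_volume holds integer bin labels in [0, n_bins).  The entropy of the
    window's label histogram is written at the window centre; voxels whose
    window does not fit entirely inside the volume are NaN.
    """
    nx, ny, nz = bin_volume.shape
    half = window // 2
    out = np.full((nx, ny, nz), np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_win = window * window * window
    for i in range(half, nx - (window - half) + 1):
        for j in range(half, ny - (window - half) + 1):
            for k in range(half, nz - (window - half) + 1):
                for b in range(n_bins):
                    counts[b] = 0
                for ii in range(i - half, i - half + window):
                    for jj in range(j - half, j - half + window):
                        for kk in range(k - half, k - half + window):
                            counts[bin_volume[ii, jj, kk]] += 1
                ent = 0.0
                for b in range(n_bins):
                    c = counts[b]
                    if c > 0:
                        p = c / n_win
                        ent -= p * np.log2(p)
                out[i, j, k] = ent
    return out
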