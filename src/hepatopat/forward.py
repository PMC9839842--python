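"""Forward acoustic simulation under the rotating hemispherical scan.

Four arc-shaped detector arrays sit on a hemispherical bowl below the
sample; each laser shot rotates the arcs about the vertical axis by one
angular step so that a one-way sweep fills the inter-arc gap.  A detector
trace is the superposition of spherical-wave arrivals from every absorbing
voxel, delayed by the two-zone straight-ray travel time and convolved with
an N-shaped (derivative-of-Gaussian) excitation pulse.  The forward model
deliberately shares its delay operator with the reconstruction, so
simulation studies probe noise, motion, and sound-speed mismatch rather
than ray-model discrepancies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import _kernels
from .acoustics import TissueBoundary
from .phantom import AbsorptionVolume, MotionModel, PhantomTruth, apply_respiration

log = logging.getLogger(__name__)

__all__ = ["ScanGeometry", "PulseSpec", "RawSignalSet", "build_scan_geometry",
           "simulate_signals", "add_noise"]


@dataclass(frozen=True)
class ScanGeometry:
    """Rotating hemispherical detection schedule.

    Elements are spread along the polar angle of each arc; the arcs are
    evenly spaced in azimuth and rotate by ``rotation_step_deg`` per shot.
    The default full-scale schedule is 4 arcs x 256 elements at a 50 Hz
    repetition rate with 500 shots covering the 90 degree inter-arc gap.
    """

    hemisphere_radius_mm: float = 30.0
    n_arcs: int = 4
    elements_per_arc: int = 64
    shots_per_sweep: int = 100
    rotation_span_deg: float = 90.0
    sampling_rate_hz: float = 40.0e6
    laser_rep_period_s: float = 0.02
    sweep_direction: str = "forward"
    polar_range_deg: tuple[float, float] = (12.0, 80.0)

    def __post_init__(self):
        if self.n_arcs < 1 or self.elements_per_arc < 1:
            raise ValueError("arc and element counts must be >= 1")
        if self.shots_per_sweep < 1:
            raise ValueError("shots_per_sweep must be >= 1")
        if self.sweep_direction not in ("forward", "backward"):
            raise ValueError("sweep_direction must be 'forward' or 'backward'")

    @property
    def rotation_step_deg(self) -> float:
        return self.rotation_span_deg / self.shots_per_sweep

    @property
    def n_elements(self) -> int:
        return self.n_arcs * self.elements_per_arc

    @property
    def sweep_duration_s(self) -> float:
        return self.shots_per_sweep * self.laser_rep_period_s

    def shot_angle_deg(self, step: int) -> float:
        if self.sweep_direction == "backward":
            step = self.shots_per_sweep - 1 - step
        return step * self.rotation_step_deg

    def element_positions(self, step: int) -> np.ndarray:
        """World positions (n_elements, 3) of every detector at one shot.

        Detectors lie on the lower hemisphere: z = -R cos(theta) <= 0 with
        theta the polar angle from the downward pole.
        """
        R = self.hemisphere_radius_mm
        th = np.deg2rad(np.linspace(*self.polar_range_deg, self.elements_per_arc))
        base_az = np.arange(self.n_arcs) * (360.0 / self.n_arcs)
        az = np.deg2rad(base_az + self.shot_angle_deg(step))
        sin_t = np.sin(th)
        pos = np.empty((self.n_arcs, self.elements_per_arc, 3))
        pos[..., 0] = R * sin_t[None, :] * np.cos(az)[:, None]
        pos[..., 1] = R * sin_t[None, :] * np.sin(az)[:, None]
        pos[..., 2] = -R * np.cos(th)[None, :]
        return pos.reshape(self.n_elements, 3)

    def all_positions(self) -> np.ndarray:
        """(shots, n_elements, 3) stack of detector positions."""
        return np.stack([self.element_positions(k)
                         for k in range(self.shots_per_sweep)])


def build_scan_geometry(config: dict | None = None, **kwargs) -> ScanGeometry:
    """Build a ScanGeometry from a config mapping (unknown keys rejected)."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    return ScanGeometry(**cfg)


@dataclass(frozen=True)
class PulseSpec:
    """Derivative-of-Gaussian ('N-shape'-like) excitation pulse."""

    center_freq_hz: float = 2.25e6
    amplitude: float = 1.0

    @property
    def sigma_s(self) -> float:
        # spectral peak of a DoG pulse sits at 1/(2 pi sigma)
        return 1.0 / (2.0 * np.pi * self.center_freq_hz)

    def sampled(self, fs: float) -> tuple[np.ndarray, int]:
        """Pulse samples over +-5 sigma and the index of t = 0."""
        if self.center_freq_hz > fs / 2.0:
            raise ValueError(
                f"pulse center frequency {self.center_freq_hz:g} Hz exceeds "
                f"the Nyquist rate of the {fs:g} Hz sampling")
        sig = self.sigma_s
        half = max(int(np.ceil(5.0 * sig * fs)), 2)
        t = (np.arange(-half, half + 1)) / fs
        p = -t / sig * np.exp(-(t ** 2) / (2.0 * sig ** 2))
        peak = np.abs(p).max()
        if peak > 0:
            p = p / peak * self.amplitude
        return p, half


@dataclass
class RawSignalSet:
    """Per-shot, per-element pressure traces with their time axis."""

    traces: np.ndarray               # (shots, elements, samples)
    time_axis_s: np.ndarray
    geometry: ScanGeometry
    phase_truth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        tr = np.asarray(self.traces)
        if tr.ndim != 3:
            raise ValueError("traces must be (shots, elements, samples)")
        if tr.shape[2] != len(self.time_axis_s):
            raise ValueError("time axis length does not match sample count")
        if not np.all(np.isfinite(tr)):
            raise ValueError("traces must be finite")
        self.traces = tr

    @property
    def n_shots(self) -> int:
        return self.traces.shape[0]

    @property
    def sampling_rate_hz(self) -> float:
        return self.geometry.sampling_rate_hz

    def scaled(self, factor: float) -> "RawSignalSet":
        return RawSignalSet(self.traces * factor, self.time_axis_s,
                            self.geometry, self.phase_truth, dict(self.meta))


def _time_axis(volume: AbsorptionVolume, geom: ScanGeometry,
               boundary: TissueBoundary, pulse: PulseSpec) -> np.ndarray:
    axes = volume.axes_mm()
    corners = np.array([[axes[0][i], axes[1][j], axes[2][k]]
                        for i in (0, -1) for j in (0, -1) for k in (0, -1)])
    r_max = np.linalg.norm(corners, axis=1).max() + geom.hemisphere_radius_mm
    c_min = min(boundary.c_water_mps, boundary.c_tissue_mps)
    t_max = r_max * 1e-3 / c_min + 8.0 * pulse.sigma_s
    n = int(np.ceil(t_max * geom.sampling_rate_hz)) + 2
    return np.arange(n) / geom.sampling_rate_hz


def _check_inside(volume: AbsorptionVolume, geom: ScanGeometry):
    axes = volume.axes_mm()
    diag = max(np.linalg.norm([axes[0][i], axes[1][j], axes[2][k]])
               for i in (0, -1) for j in (0, -1) for k in (0, -1))
    if geom.hemisphere_radius_mm <= diag:
        raise ValueError(
            f"hemisphere radius {geom.hemisphere_radius_mm} mm does not "
            f"enclose the grid (extent {diag:.1f} mm from origin)")


def simulate_signals(volume: AbsorptionVolume, geom: ScanGeometry,
                     boundary: TissueBoundary, pulse: PulseSpec | None = None,
                     motion: MotionModel | None = None,
                     truth: PhantomTruth | None = None,
                     amplitude_threshold: float = 0.0) -> RawSignalSet:
    """Simulate raw detector traces for one sweep.

    With a motion model, shot k sees the phantom deformed to breath phase
    k mod phase_count (forward sweep) and the true phase of every shot is
    recorded in ``phase_truth``.  An empty volume yields all-zero traces.
    """
    pulse = pulse or PulseSpec()
    _check_inside(volume, geom)
    time_axis = _time_axis(volume, geom, boundary, pulse)
    ns = len(time_axis)
    fs = geom.sampling_rate_hz
    kernel, k_half = pulse.sampled(fs)

    uniform = boundary.c_water_mps == boundary.c_tissue_mps
    b_args = (1.0 / boundary.c_water_mps, 1.0 / boundary.c_tissue_mps,
              not uniform,
              boundary.ellipse_center_mm[0], boundary.ellipse_center_mm[1],
              boundary.semi_axes_mm[0], boundary.semi_axes_mm[1],
              boundary.cap_plane_z_mm)

    phase_truth = None
    if motion is not None:
        n_per_cycle = motion.phase_count
        phase_truth = np.arange(geom.shots_per_sweep) % n_per_cycle
        if geom.sweep_direction == "backward":
            # time keeps running forward in the second sweep
            phase_truth = (phase_truth + geom.shots_per_sweep) % n_per_cycle
        if truth is None:
            raise ValueError("motion simulation requires the phantom truth")

    def sources_at(phase):
        vol = volume
        if motion is not None:
            vol = apply_respiration(volume, truth, motion, int(phase))
        v = vol.values
        idx = np.argwhere(v > amplitude_threshold)
        if idx.size == 0:
            return np.zeros((0, 3)), np.zeros(0)
        coords = vol.voxel_coords_mm(idx)
        return np.ascontiguousarray(coords), \
            np.ascontiguousarray(v[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float))

    traces = np.zeros((geom.shots_per_sweep, geom.n_elements, ns), dtype=np.float32)
    cache: dict[int, tuple] = {}
    for k in range(geom.shots_per_sweep):
        ph = 0 if phase_truth is None else int(phase_truth[k])
        if ph not in cache:
            cache[ph] = sources_at(ph)
            if phase_truth is None:
                cache = {0: cache[0]}
        src, amp = cache[ph]
        if src.shape[0] == 0:
            continue
        det = np.ascontiguousarray(geom.element_positions(k))
        splat = _kernels.forward_splat(src, amp, det, fs, 0.0, ns, *b_args)
        conv = fftconvolve(splat, kernel[None, :], mode="full")
        traces[k] = conv[:, k_half:k_half + ns].astype(np.float32)

    return RawSignalSet(traces=traces, time_axis_s=time_axis, geometry=geom,
                        phase_truth=phase_truth,
                        meta={"pulse_center_freq_hz": pulse.center_freq_hz})


def add_noise(raw: RawSignalSet, snr_db: float, seed: int) -> RawSignalSet:
    """Add white Gaussian noise at the requested SNR relative to signal RMS."""
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return RawSignalSet(raw.traces.copy(), raw.time_axis_s,
                                raw.geometry, raw.phase_truth, dict(raw.meta))
        raise ValueError("snr_db must be finite or +inf")
    sig_rms = float(np.sqrt(np.mean(raw.traces.astype(np.float64) ** 2)))
    noise_rms = sig_rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = raw.traces + rng.normal(0.0, noise_rms, raw.traces.shape).astype(
        raw.traces.dtype)
    meta = dict(raw.meta, snr_db=snr_db, noise_seed=seed)
    return RawSignalSet(noisy, raw.time_axis_s, raw.geometry, raw.phase_truth, meta)
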