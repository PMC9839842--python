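"""Respiratory time gating from the raw channel data.

Breathing shifts the tissue surface, which shifts the first-arrival time of
the surface signal on a reference detector element.  Tracking that
first-arrival index across laser shots (azimuthal angles) gives a
respiration trace; its extrema mark the inspiration/expiration turnarounds
where motion is fastest.  Shots near the extrema are discarded, two
sequential sweeps (forward + backward) are merged into a full-scan set, and
the retained shots can instead be binned into respiratory phases for
dynamic imaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from scipy.signal.windows import gaussian as gaussian_window

from .forward import RawSignalSet

log = logging.getLogger(__name__)

__all__ = ["GatingResult", "first_arrival", "smooth_and_diff",
           "find_breath_events", "motion_frame_mask", "merge_round_trip",
           "assign_phases", "gate_sweep"]

NO_ARRIVAL = -1


@dataclass
class GatingResult:
    """Per-sweep gating summary."""

    first_arrival: np.ndarray
    smoothed: np.ndarray
    diff: np.ndarray
    peaks: np.ndarray
    troughs: np.ndarray
    removed_mask: np.ndarray
    half_cycle_shots: float
    phase_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _reference_element(raw: RawSignalSet) -> int:
    """Calibration pass: the element with the largest mean RMS across shots."""
    rms = np.sqrt(np.mean(raw.traces.astype(np.float64) ** 2, axis=(0, 2)))
    return int(np.argmax(rms))


def first_arrival(raw: RawSignalSet, background_window: tuple[int, int],
                  element: int | None = None) -> np.ndarray:
    """Per-shot first-arrival sample index on a reference element.

    The threshold is mu_bg + 3 sigma_bg of the absolute trace over the
    background window (which must precede any source signal).  Shots with no
    sample above threshold get the sentinel ``NO_ARRIVAL``.
    """
    b0, b1 = background_window
    if not 0 <= b0 < b1 <= raw.traces.shape[2]:
        raise ValueError("invalid background window")
    el = _reference_element(raw) if element is None else int(element)
    signed = raw.traces[:, el, :].astype(np.float64)
    tr = np.abs(signed)
    bg = signed[:, b0:b1]
    thr = np.abs(bg).mean(axis=1) + 3.0 * bg.std(axis=1)
    above = tr > thr[:, None]
    # require two consecutive supra-threshold samples so an isolated noise
    # spike cannot masquerade as the surface arrival
    onset = above[:, :-1] & above[:, 1:]
    idx = np.argmax(onset, axis=1)
    none = ~onset.any(axis=1)
    idx[none] = NO_ARRIVAL
    if none.any():
        log.warning("no arrival detected on %d/%d shots", none.sum(), len(idx))
    return idx


def smooth_and_diff(trace: np.ndarray, w_median: int = 5,
                    w_gauss: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Median filter, Gaussian-weighted moving average, then first difference.

    The median stage rejects single-shot detection glitches; the Gaussian
    moving average smooths shot-to-shot jitter before differencing.
    """
    t = np.asarray(trace, dtype=float)
    if len(t) < max(w_median, w_gauss):
        raise ValueError("trace shorter than the filter window")
    med = median_filter(t, size=w_median, mode="nearest")
    win = gaussian_window(w_gauss, std=w_gauss / 4.0)
    win /= win.sum()
    pad = w_gauss // 2
    padded = np.pad(med, pad, mode="edge")
    smoothed = np.convolve(padded, win, mode="valid")[:len(t)]
    diff = np.gradient(smoothed)
    return smoothed, diff


def find_breath_events(smoothed: np.ndarray, prominence: float | None = None,
                       distance: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Locate respiration peaks and troughs of the smoothed arrival trace.

    Troughs are found by peak-searching the negated trace.  A minimum
    prominence (default: twice the residual noise level of the trace) and a
    minimum separation reject heartbeat-scale ripple; alternation is
    enforced by keeping the most extreme event of any same-kind run.
    Returns empty arrays for a motionless trace.
    """
    t = np.asarray(smoothed, dtype=float)
    if len(t) < 3:
        raise ValueError("trace too short")
    if prominence is None:
        noise = np.std(np.diff(t)) / np.sqrt(2.0)
        prominence = max(2.0 * noise, 1e-12)
        if t.max() - t.min() <= 4.0 * noise:
            return np.array([], dtype=int), np.array([], dtype=int)
    peaks, _ = find_peaks(t, prominence=prominence, distance=distance)
    troughs, _ = find_peaks(-t, prominence=prominence, distance=distance)
    return _enforce_alternation(t, peaks, troughs)


def _enforce_alternation(t, peaks, troughs):
    events = sorted([(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs])
    kept = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = t[i] > t[prev] if kind > 0 else t[i] < t[prev]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    p = np.array([i for i, k in kept if k > 0], dtype=int)
    tr = np.array([i for i, k in kept if k < 0], dtype=int)
    return p, tr


def half_cycle_from_events(peaks: np.ndarray, troughs: np.ndarray) -> float:
    """Averaged peak-trough distance, the half respiratory cycle in shots."""
    events = np.sort(np.concatenate([peaks, troughs]))
    if len(events) < 2:
        return float("nan")
    return float(np.mean(np.diff(events)))


def motion_frame_mask(events: tuple[np.ndarray, np.ndarray],
                      gate_halfwidth_shots: int, n_shots: int) -> np.ndarray:
    """Mark shots within +-gate_halfwidth of any peak or trough as removed."""
    if gate_halfwidth_shots < 0:
        raise ValueError("gate halfwidth must be >= 0")
    peaks, troughs = events
    mask = np.zeros(n_shots, dtype=bool)
    for i in np.concatenate([peaks, troughs]).astype(int):
        lo = max(0, i - gate_halfwidth_shots)
        hi = min(n_shots, i + gate_halfwidth_shots + 1)
        mask[lo:hi] = True
    frac = mask.mean() if n_shots else 0.0
    if frac > 0.8:
        log.warning("motion gate removes %.0f%% of shots", 100 * frac)
    return mask


def merge_round_trip(fwd: RawSignalSet, bwd: RawSignalSet,
                     fwd_mask: np.ndarray, bwd_mask: np.ndarray) -> RawSignalSet:
    """Merge forward and backward sweeps into one full-scan signal set.

    The backward sweep is re-ordered onto the forward angular grid.  At each
    angle: both sweeps retained -> average; one retained -> that trace;
    both removed -> linear interpolation along angle between the nearest
    retained neighbours (clamped at the ends).
    """
    if fwd.traces.shape != bwd.traces.shape:
        raise ValueError("sweeps must share shot/element/sample shape")
    n = fwd.n_shots
    fwd_keep = ~np.asarray(fwd_mask, dtype=bool)
    bwd_keep = ~np.asarray(bwd_mask, dtype=bool)
    b_tr = bwd.traces
    if bwd.geometry.sweep_direction == "backward":
        b_tr = b_tr[::-1]
        bwd_keep = bwd_keep[::-1]

    merged = np.zeros_like(fwd.traces, dtype=np.float64)
    both = fwd_keep & bwd_keep
    merged[both] = 0.5 * (fwd.traces[both] + b_tr[both])
    only_f = fwd_keep & ~bwd_keep
    merged[only_f] = fwd.traces[only_f]
    only_b = bwd_keep & ~fwd_keep
    merged[only_b] = b_tr[only_b]

    retained = fwd_keep | bwd_keep
    if not retained.any():
        raise ValueError("no angular position retained in either sweep")
    ridx = np.nonzero(retained)[0]
    for i in np.nonzero(~retained)[0]:
        right = np.searchsorted(ridx, i)
        if right == 0:
            merged[i] = merged[ridx[0]]
        elif right == len(ridx):
            merged[i] = merged[ridx[-1]]
        else:
            lo, hi = ridx[right - 1], ridx[right]
            w = (i - lo) / (hi - lo)
            merged[i] = (1 - w) * merged[lo] + w * merged[hi]

    return RawSignalSet(merged.astype(fwd.traces.dtype), fwd.time_axis_s,
                        fwd.geometry, None,
                        {"merged": True, "interpolated_shots": int((~retained).sum())})


def assign_phases(events: tuple[np.ndarray, np.ndarray], half_cycle_shots: float,
                  laser_rep_period_s: float, n_shots: int) -> np.ndarray:
    """Label every shot with its respiratory phase bin.

    The cycle period (2 x half cycle, in shots) is converted to a phase
    count by the laser repetition period (20 ms default): phase_count =
    round(cycle_period_s / 0.02 s).  Each shot is labelled by its offset
    from the preceding trough modulo phase_count.  A cycle-to-cycle period
    spread above 20% triggers a warning.
    """
    peaks, troughs = events
    if len(troughs) < 1 or not np.isfinite(half_cycle_shots):
        raise ValueError("need at least one detected cycle to assign phases")
    cycle_shots = 2.0 * half_cycle_shots
    phase_count = max(int(round(cycle_shots * laser_rep_period_s / 0.02)), 1)
    if len(troughs) >= 3:
        periods = np.diff(troughs)
        if periods.mean() > 0 and periods.std() / periods.mean() > 0.2:
            log.warning("unstable respiratory period: %.0f%% spread",
                        100 * periods.std() / periods.mean())
    shots = np.arange(n_shots)
    anchor = int(troughs[0])
    labels = np.mod(shots - anchor, int(round(cycle_shots)))
    labels = np.minimum((labels * phase_count) // int(round(cycle_shots)),
                        phase_count - 1)
    return labels.astype(int)


def gate_sweep(raw: RawSignalSet, background_window: tuple[int, int],
               gate_fraction: float = 0.1, w_median: int = 5,
               w_gauss: int = 9, with_phases: bool = False) -> GatingResult:
    """Run the full gating chain on one sweep."""
    fa = first_arrival(raw, background_window)
    valid = fa != NO_ARRIVAL
    fa_f = fa.astype(float)
    if not valid.all() and valid.any():
        fa_f[~valid] = np.interp(np.nonzero(~valid)[0], np.nonzero(valid)[0],
                                 fa_f[valid])
    smoothed, diff = smooth_and_diff(fa_f, w_median, w_gauss)
    # two-pass event search: a first pass estimates the half cycle, a second
    # enforces a minimum separation of half of it to reject ripple
    peaks, troughs = find_breath_events(smoothed)
    half_cycle = half_cycle_from_events(peaks, troughs)
    if np.isfinite(half_cycle) and half_cycle >= 4:
        peaks, troughs = find_breath_events(
            smoothed, distance=max(int(half_cycle / 2), 1))
        half_cycle = half_cycle_from_events(peaks, troughs)
    if np.isfinite(half_cycle):
        gate = max(int(round(gate_fraction * 2 * half_cycle)), 0)
    else:
        gate = 0
    removed = motion_frame_mask((peaks, troughs), gate, raw.n_shots)
    labels = None
    if with_phases and len(troughs):
        labels = assign_phases((peaks, troughs), half_cycle,
                               raw.geometry.laser_rep_period_s, raw.n_shots)
    return GatingResult(first_arrival=fa, smoothed=smoothed, diff=diff,
                        peaks=peaks, troughs=troughs, removed_mask=removed,
                        half_cycle_shots=half_cycle, phase_labels=labels,
                        meta={"gate_halfwidth_shots": gate})
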