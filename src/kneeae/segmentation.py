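"""Sit-stand-sit cycle detection and movement-quadrant segmentation.

A goniometer trace (knee flexion, degrees; seated ≈ 90°, standing ≈ 0°)
is low-pass smoothed, differentiated, and scanned for seated→standing→
seated excursions.  Each detected cycle is divided into the four kinematic
quadrants used to localise AE activity: the ascent (standing up) is split
at its peak angular speed into Q1 (ascending-acceleration) and Q2
(ascending-deceleration), and the descent likewise into Q3
(descending-acceleration) and Q4 (descending-deceleration).  Quadrant
intervals are half-open ``[t0, t1)`` and tile the cycle exactly, so a hit
on a boundary is assigned to the later quadrant deterministically.

Cycle detection uses the trace's own empirical range (5th/95th angle
percentiles) to place the 50%-of-range crossing, which makes segmentation
invariant to a constant offset of the angle signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .types import AngleTrace, KinematicTrace, MovementCycle, QUADRANTS

logger = logging.getLogger(__name__)


def smooth_and_differentiate(trace: AngleTrace,
                             cutoff_hz: float = 2.0) -> KinematicTrace:
    """Zero-phase low-pass smoothing plus central-difference derivatives.

    The default 2 Hz cutoff is far above the sit-stand-sit cadence
    (~0.2–0.5 Hz) and far below goniometer noise.  Raises on traces shorter
    than the filter warm-up.
    """
    fs = trace.sampling_rate
    if cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff_hz must be below the Nyquist frequency")
    b, a = signal.butter(4, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trace.angle.size <= padlen:
        raise ValueError(
            f"trace too short for filter warm-up ({trace.angle.size} samples, "
            f"need > {padlen})")
    smooth = signal.filtfilt(b, a, trace.angle)
    vel = np.gradient(smooth, trace.time)
    acc = np.gradient(vel, trace.time)
    return KinematicTrace(time=trace.time, angle=smooth, velocity=vel,
                         acceleration=acc, sampling_rate=fs)


def detect_cycles(kin: KinematicTrace, seated_angle: float = 90.0,
                  standing_angle: float = 5.0,
                  min_range_fraction: float = 0.5) -> list[MovementCycle]:
    """Detect complete sit-stand-sit cycles in a kinematic trace.

    A cycle spans from the departure below the mid-range crossing
    (seated→standing) back to the return crossing, extended outward to the
    adjacent seated rests (where angular speed falls off).  Incomplete
    excursions (a departure that never returns) are logged and dropped.
    ``seated_angle``/``standing_angle`` are nominal values used only to
    require a plausible excursion range.
    """
    if seated_angle <= standing_angle:
        raise ValueError("seated_angle must exceed standing_angle")
    ang, t, v = kin.angle, kin.time, kin.velocity
    if ang.size < 3:
        return []
    lo, hi = np.percentile(ang, [5, 95])
    if hi - lo < min_range_fraction * (seated_angle - standing_angle):
        return []                       # flat trace: no movement
    mid = 0.5 * (lo + hi)

    below = ang < mid
    change = np.flatnonzero(np.diff(below.astype(int)))
    downs = [i + 1 for i in change if below[i + 1]]
    ups = [i + 1 for i in change if not below[i + 1]]

    v_thresh = max(2.0, 0.02 * np.max(np.abs(v)))
    cycles: list[MovementCycle] = []
    prev_end_idx = 0
    ui = 0
    for d in downs:
        while ui < len(ups) and ups[ui] <= d:
            ui += 1
        if ui >= len(ups):
            logger.info("incomplete sit-stand segment at t=%.2fs dropped", t[d])
            break
        u = ups[ui]
        # extend to adjacent seated rests: walk out while descending/ascending fast
        s_idx = d
        while s_idx > prev_end_idx and v[s_idx - 1] < -v_thresh:
            s_idx -= 1
        e_idx = u
        next_down = None
        for d2 in downs:
            if d2 > u:
                next_down = d2
                break
        limit = next_down if next_down is not None else ang.size - 1
        while e_idx < limit and v[e_idx + 1] > v_thresh:
            e_idx += 1
        stand_idx = d + int(np.argmin(ang[d:u + 1]))
        cycles.append(MovementCycle(start_time=float(t[s_idx]),
                                    end_time=float(t[e_idx]),
                                    stand_time=float(t[stand_idx])))
        prev_end_idx = e_idx
    return cycles


def quadrant_boundaries(kin: KinematicTrace,
                        cycle: MovementCycle) -> MovementCycle:
    """Fill the cycle's quadrant intervals from the speed profile.

    The ascent (start → stand) splits at its maximum angular speed into
    Q1/Q2 and the descent (stand → end) at its maximum speed into Q3/Q4;
    ``np.argmax`` takes the earliest sample on exact speed ties.
    """
    t = kin.time
    speed = np.abs(kin.velocity)
    i0 = int(np.searchsorted(t, cycle.start_time))
    i_st = int(np.searchsorted(t, cycle.stand_time))
    i1 = int(np.searchsorted(t, cycle.end_time))
    if i_st <= i0 or i1 <= i_st:
        raise ValueError("cycle not resolvable on this trace")
    asc_peak = i0 + int(np.argmax(speed[i0:i_st]))
    dsc_peak = i_st + int(np.argmax(speed[i_st:i1]))
    cycle.quadrants = {
        "Q1": (cycle.start_time, float(t[asc_peak])),
        "Q2": (float(t[asc_peak]), cycle.stand_time),
        "Q3": (cycle.stand_time, float(t[dsc_peak])),
        "Q4": (float(t[dsc_peak]), cycle.end_time),
    }
    cycle.validate_partition(tol=1.0 / kin.sampling_rate)
    return cycle


def assign_hits_to_quadrants(hits: pd.DataFrame,
                             cycles: list[MovementCycle]) -> pd.DataFrame:
    """Label each hit with its movement quadrant and cycle index.

    Hits whose onset falls outside every cycle (seated rest, lead-in/out)
    are labelled ``"off"`` with cycle index −1; they are counted in the log
    and excluded from quadrant analyses downstream.
    """
    out = hits.copy()
    quad = np.array(["off"] * len(out), dtype=object)
    cyc = np.full(len(out), -1, dtype=int)
    onset = out["onset_time_s"].to_numpy(dtype=float)
    for ci, c in enumerate(cycles):
        if not c.quadrants:
            raise ValueError("cycles must have quadrant intervals filled")
        for q in QUADRANTS:
            t0, t1 = c.quadrants[q]
            sel = (onset >= t0) & (onset < t1)
            quad[sel] = q
            cyc[sel] = ci
    out["quadrant"] = quad
    out["cycle_index"] = cyc
    n_off = int((quad == "off").sum())
    if n_off:
        logger.info("%d of %d hits fall outside all cycles (off-cycle)",
                    n_off, len(out))
    return out


def cycles_to_frame(cycles: list[MovementCycle]) -> pd.DataFrame:
    """Cycle/quadrant table: cycle_index, q, t0_s, t1_s."""
    rows = []
    for ci, c in enumerate(cycles):
        for q in QUADRANTS:
            t0, t1 = c.quadrants[q]
            rows.append((ci, q, t0, t1))
    return pd.DataFrame(rows, columns=["cycle_index", "q", "t0_s", "t1_s"])
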