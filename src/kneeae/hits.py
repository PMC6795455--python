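"""Threshold-crossing AE hit detection with per-hit features.

Reproduces event-based acquisition: the machine records a "hit" whenever
the rectified signal reaches the acquisition threshold (36 dB re 1 μV by
default) and keeps it open until the signal has stayed below threshold for
the hit-definition time.  Detection is sample-wise on the rectified raw
trace; no band-pass filtering is applied in software (the 20–400 kHz vs
20–80 kHz acquisition ranges are configuration labels only).

Hit semantics, in order:

1. a hit opens at the first at/above-threshold sample outside any earlier
   hit's merge or lockout window;
2. above-threshold samples within ``hit_definition_time`` of the last
   above-threshold sample extend the hit; the hit window ends at its last
   above-threshold sample;
3. the hit closes ``hit_definition_time`` after its last above-threshold
   sample, and no new hit may open before closure plus
   ``hit_lockout_time``.

Features per hit: peak amplitude = dB of the maximum rectified voltage in
the window, average signal level (ASL) = dB of the mean rectified voltage
over the window, duration = time from onset to last above-threshold sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import DEFAULT_THRESHOLD_DB, HIT_COLUMNS, HitTiming, Waveform


def volts_to_db(v):
    """Convert a voltage in μV to dB re 1 μV: ``20·log10(v / 1 μV)``.

    Raises ``ValueError`` for non-positive voltages (the level is undefined).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("voltage must be > 0 to express in dB re 1 uV")
    out = 20.0 * np.log10(v)
    return float(out) if out.ndim == 0 else out


def db_to_volts(db):
    """Inverse of :func:`volts_to_db` (μV)."""
    db = np.asarray(db, dtype=float)
    out = 10.0 ** (db / 20.0)
    return float(out) if out.ndim == 0 else out


def empty_hit_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in HIT_COLUMNS})
    df["quadrant"] = df["quadrant"].astype(object)
    df["cycle_index"] = df["cycle_index"].astype(int)
    return df


def detect_hits(w: Waveform, threshold_db: float = DEFAULT_THRESHOLD_DB,
                timing: HitTiming | None = None) -> pd.DataFrame:
    """Detect AE hits in a waveform; returns a hit table in onset order.

    Parameters
    ----------
    w
        Raw voltage trace in μV.
    threshold_db
        Acquisition threshold in dB re 1 μV (machine setting, default 36).
    timing
        Hit-closure parameters; defaults to :class:`HitTiming` defaults.
    """
    timing = timing or HitTiming()
    if w.samples.size == 0:
        return empty_hit_table()
    rect = np.abs(w.samples)
    thr_v = db_to_volts(threshold_db)
    above = rect >= thr_v
    if above.mean() > 0.2:
        warnings.warn("more than 20% of samples exceed the threshold; it may "
                      "be at or below the noise floor", RuntimeWarning)
    if not above.any():
        return empty_hit_table()

    fs = w.sampling_rate
    # runs of consecutive above-threshold samples
    edges = np.flatnonzero(np.diff(np.r_[False, above, False]))
    starts, ends = edges[::2], edges[1::2] - 1          # inclusive ends

    hdt_samp = timing.hit_definition_time * fs
    lock_samp = timing.hit_lockout_time * fs

    records = []
    cur_s = cur_e = None
    next_free = 0.0       # first sample index at which a new hit may open

    def _open(s, e):
        # a hit opens at the first above-threshold sample past the lockout
        s_eff = max(s, int(np.ceil(next_free)))
        return (s_eff, e) if s_eff <= e else (None, None)

    for s, e in zip(starts, ends):
        if cur_s is None:
            cur_s, cur_e = _open(s, e)
            continue
        if s - cur_e < hdt_samp:          # gap shorter than hit definition
            cur_e = e
        else:
            records.append((cur_s, cur_e))
            next_free = cur_e + hdt_samp + lock_samp
            cur_s, cur_e = _open(s, e)
    if cur_s is not None:
        records.append((cur_s, cur_e))

    t0 = w.start_time
    rows = []
    for s, e in records:
        win = rect[s:e + 1]
        rows.append((t0 + s / fs,
                     volts_to_db(win.max()),
                     volts_to_db(win.mean()),
                     (e - s) / fs))
    df = pd.DataFrame(rows, columns=["onset_time_s", "peak_db", "asl_db",
                                     "duration_s"])
    df["quadrant"] = pd.Series(["off"] * len(df), dtype=object)
    df["cycle_index"] = -1
    return df
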