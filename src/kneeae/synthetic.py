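"""Synthetic raw signals and measurement tables with the statistical
structure the downstream analysis assumes.

Three layers are generated, matching the acquisition chain:

* a goniometer knee-angle trace containing smooth sit-stand-sit excursions
  (raised-cosine profile) separated by seated rests;
* an AE hit stream whose onset times are allocated to movement quadrants
  by a multinomial law (default skewed to Q1/Q4, the high-load phases) and
  whose peak amplitudes follow threshold + Exponential(8 dB) truncated at
  100 dB, with the average signal level a Uniform(5, 15) dB below the peak;
* optionally, a raw voltage waveform embedding one decaying-sinusoid burst
  per hit in Gaussian noise, so the threshold detector can be exercised
  end-to-end.

The measurement-level generator emulates the repeated-measures cohort
design (day-1 sessions by each of three practitioners, later days by one,
two sets per session, three machines) and produces the biomarker response
as a Gaussian linear mixed model: fixed KL/weight/pain/machine effects plus
independent patient, session-in-patient, day-in-patient and practitioner
random effects and a residual per set.  Counts are generated continuous by
default (the analysis models are Gaussian); an integer mode rounds and
clips at zero for realism.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (DEFAULT_THRESHOLD_DB, AngleTrace, GenerativeParams,
                    HitTiming, MovementCycle, QUADRANTS, StudyDesign, Waveform)

__all__ = [
    "simulate_angle_trace", "nominal_cycle_windows", "simulate_hit_stream",
    "simulate_waveform", "simulate_measurement_table",
]


# ----------------------------------------------------------------------
# raw signals
# ----------------------------------------------------------------------
def simulate_angle_trace(n_cycles: int, cycle_duration: float = 4.0,
                         sampling_rate: float = 100.0,
                         seated_angle: float = 90.0,
                         standing_angle: float = 5.0,
                         noise_sd: float = 0.5,
                         rest_duration: float = 1.5,
                         seed: int | np.random.Generator = 0) -> AngleTrace:
    """Goniometer trace with ``n_cycles`` raised-cosine sit-stand-sit cycles.

    Each cycle runs seated → standing → seated over ``cycle_duration``
    seconds (angle ``standing + (seated−standing)·(1+cos(2πt/T))/2``),
    followed by a seated rest of ``rest_duration``; the trace starts at the
    first cycle's onset, so the mid-cycle time of cycle ``k`` is
    ``k·(T+rest) + T/2``.  Additive Gaussian noise of SD ``noise_sd``
    degrees is applied.  ``n_cycles = 0`` yields a flat seated trace.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if seated_angle <= standing_angle:
        raise ValueError("seated_angle must exceed standing_angle "
                         "(flexion positive: seated ~90, standing ~0-5)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    total = n_cycles * (cycle_duration + rest_duration)
    if n_cycles == 0:
        total = max(rest_duration, 2.0)
    t = np.arange(0.0, total, 1.0 / sampling_rate)
    angle = np.full_like(t, float(seated_angle))
    amp = seated_angle - standing_angle
    for k in range(n_cycles):
        t0 = k * (cycle_duration + rest_duration)
        sel = (t >= t0) & (t < t0 + cycle_duration)
        phase = (t[sel] - t0) / cycle_duration
        angle[sel] = standing_angle + amp * 0.5 * (1 + np.cos(2 * np.pi * phase))
    if noise_sd > 0:
        angle = angle + rng.normal(0.0, noise_sd, size=t.size)
    return AngleTrace(time=t, angle=angle, sampling_rate=float(sampling_rate))


def nominal_cycle_windows(n_cycles: int, cycle_duration: float = 4.0,
                          rest_duration: float = 1.5) -> list[tuple[float, float]]:
    """Ground-truth (start, end) windows of the cycles a trace contains."""
    step = cycle_duration + rest_duration
    return [(k * step, k * step + cycle_duration) for k in range(n_cycles)]


def simulate_hit_stream(cycles: list[MovementCycle], total_hits: int,
                        quadrant_proportions=(0.4, 0.1, 0.1, 0.4),
                        amplitude_mean_above_threshold_db: float = 8.0,
                        amplitude_max_db: float = 100.0,
                        asl_offset_range_db: tuple[float, float] = (5.0, 15.0),
                        threshold_db: float = DEFAULT_THRESHOLD_DB,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Hit table with onsets multinomially allocated to movement quadrants.

    Within a quadrant, onsets are uniform over the union of that quadrant's
    intervals across cycles (intervals weighted by length).  Peak
    amplitudes are ``threshold + Exponential(mean)`` truncated at
    ``amplitude_max_db``; the average signal level sits a uniform positive
    offset below the peak.  The returned table carries the generating
    quadrant and cycle labels, which segmentation should reproduce.
    """
    q = np.asarray(quadrant_proportions, dtype=float)
    if q.shape != (4,) or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("quadrant_proportions must be 4 non-negative "
                         "fractions summing to 1")
    if total_hits > 0 and not cycles:
        raise ValueError("cannot place hits without movement cycles")
    rng = np.random.default_rng(seed)
    rows = []
    counts = rng.multinomial(total_hits, q) if total_hits else np.zeros(4, int)
    for qi, qname in enumerate(QUADRANTS):
        n_q = int(counts[qi])
        if n_q == 0:
            continue
        ivals = [(ci, c.quadrants[qname]) for ci, c in enumerate(cycles)]
        lengths = np.array([t1 - t0 for _, (t0, t1) in ivals])
        if lengths.sum() <= 0:
            raise ValueError(f"quadrant {qname} has zero total duration")
        pick = rng.choice(len(ivals), size=n_q, p=lengths / lengths.sum())
        for j in pick:
            ci, (t0, t1) = ivals[j]
            onset = rng.uniform(t0, t1)
            peak = threshold_db + rng.exponential(amplitude_mean_above_threshold_db)
            peak = min(peak, amplitude_max_db)
            asl = peak - rng.uniform(*asl_offset_range_db)
            dur = rng.uniform(0.5e-3, 3e-3)
            rows.append((onset, peak, asl, dur, qname, ci))
    df = pd.DataFrame(rows, columns=["onset_time_s", "peak_db", "asl_db",
                                     "duration_s", "quadrant", "cycle_index"])
    if len(df) == 0:
        df = df.astype({"onset_time_s": float, "peak_db": float,
                        "asl_db": float, "duration_s": float})
        df["cycle_index"] = df.get("cycle_index", pd.Series(dtype=int))
    return df.sort_values("onset_time_s", ignore_index=True)


def simulate_waveform(hits: pd.DataFrame, sampling_rate: float = 50_000.0,
                      duration: float | None = None,
                      carrier_hz: float | None = None,
                      decay_tau_s: float = 1.5e-3,
                      noise_floor_db: float = 20.0,
                      threshold_db: float = DEFAULT_THRESHOLD_DB,
                      timing: HitTiming | None = None,
                      seed: int | np.random.Generator = 0) -> Waveform:
    """Raw μV waveform with one decaying-cosine burst per hit in noise.

    Each burst starts at the hit's onset sample with instantaneous peak
    ``10^(peak_db/20)`` μV (cosine carrier, so the first sample attains the
    peak exactly) and decays with time constant ``decay_tau_s``.  Gaussian
    noise with RMS ``10^(noise_floor_db/20)`` μV is added; the noise floor
    must sit at least 6 dB below the detection threshold.  Bursts closer
    together than the hit-definition time are flagged with a warning, as
    the detector will merge them.
    """
    timing = timing or HitTiming()
    if noise_floor_db > threshold_db - 6.0:
        raise ValueError("noise floor must be at least 6 dB below threshold")
    rng = np.random.default_rng(seed)
    onsets = np.sort(hits["onset_time_s"].to_numpy(float)) if len(hits) else np.array([])
    if onsets.size > 1 and np.any(np.diff(onsets) < timing.hit_definition_time):
        warnings.warn("bursts closer than the hit-definition time will merge "
                      "in detection", RuntimeWarning)
    tail = 8.0 * decay_tau_s
    if duration is None:
        duration = (onsets.max() + tail + 0.05) if onsets.size else 1.0
    n = int(round(duration * sampling_rate))
    w = rng.normal(0.0, 10.0 ** (noise_floor_db / 20.0), size=n)
    f0 = carrier_hz if carrier_hz is not None else sampling_rate / 20.0
    n_tail = int(tail * sampling_rate)
    tt = np.arange(n_tail) / sampling_rate
    kernel = np.exp(-tt / decay_tau_s) * np.cos(2 * np.pi * f0 * tt)
    for _, h in hits.iterrows():
        i0 = int(round(h["onset_time_s"] * sampling_rate))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        w[i0:i0 + seg.size] += 10.0 ** (h["peak_db"] / 20.0) * seg
    return Waveform(samples=w, sampling_rate=float(sampling_rate))


# ----------------------------------------------------------------------
# measurement tables
# ----------------------------------------------------------------------
def _measurement_days(design: StudyDesign) -> list[tuple[int, int]]:
    """(week, day-index) pairs: consecutive days in week 1, then one per week."""
    days = [(1, d) for d in range(1, design.n_days + 1)]
    for w in range(2, design.n_weeks + 1):
        days.append((w, design.n_days + (w - 1)))
    return days


def simulate_measurement_table(design: StudyDesign, params: GenerativeParams,
                               seed: int | np.random.Generator = 0,
                               biomarker_name: str = "number_of_hits",
                               integer_mode: bool = False) -> pd.DataFrame:
    """Measurement-level table: one row per participant × day × session × set.

    The biomarker response follows the Gaussian mixed model described in
    :class:`~kneeae.types.GenerativeParams`, with every random effect drawn
    once per grouping unit and shared by its rows; the two sets within a
    session differ only by the residual.  Weight enters centred at the
    generated sample mean, so the intercept is the mean response at mean
    weight, no contralateral pain, averaged over KL levels.
    """
    rng = np.random.default_rng(seed)
    if len(params.machine_offsets) < design.n_machines:
        raise ValueError("machine_offsets shorter than n_machines")

    nP = design.n_participants
    rp_labels = [f"RP{i+1}" for i in range(design.n_practitioners_day1)]
    u_rp = dict(zip(rp_labels, rng.normal(0.0, params.sd_rp, len(rp_labels))))

    kl = rng.choice([1, 2, 3, 4], size=nP, p=params.kl_probs)
    weight = rng.normal(params.weight_mean_kg, params.weight_sd_kg, nP)
    weight = np.clip(weight, 40.0, 160.0)
    pain = rng.binomial(1, params.pain_prob, nP)
    age = np.clip(rng.normal(62.0, 9.0, nP), 40.0, 88.0)
    sex = rng.choice(["F", "M"], size=nP)
    bmi = np.clip(rng.normal(29.0, 5.0, nP), 18.0, 45.0)
    womac_pain = np.clip(rng.normal(17.0, 12.0, nP), 0.0, 50.0)
    womac_stiff = np.clip(rng.normal(10.0, 6.0, nP), 0.0, 20.0)
    womac_func = np.clip(rng.normal(58.0, 32.0, nP), 0.0, 170.0)
    vas = np.clip(rng.normal(55.0, 20.0, nP), 0.0, 100.0)
    machine = rng.integers(1, design.n_machines + 1, size=nP)
    weight_c = weight - weight.mean()

    kl_eff = params.kl_level_effects()
    u_pat = rng.normal(0.0, params.sd_patient, nP)

    days = _measurement_days(design)
    rows = []
    for p in range(nP):
        pid = f"P{p+1:04d}"
        day1_rps = rng.permutation(rp_labels) if design.day1_multi_rp \
            else [rng.choice(rp_labels)]
        followup_rp = rng.choice(day1_rps)
        fixed_part = (params.intercept + kl_eff[kl[p] - 1]
                      + params.weight_coef * weight_c[p]
                      + params.contralateral_pain_coef * pain[p]
                      + params.machine_offsets[machine[p] - 1])
        for (week, day) in days:
            u_day = rng.normal(0.0, params.sd_day_in_patient)
            if day == 1 and design.day1_multi_rp:
                session_rps = list(day1_rps)
            else:
                session_rps = [followup_rp]
            for s_idx, rp in enumerate(session_rps, start=1):
                u_sess = rng.normal(0.0, params.sd_session_in_patient)
                for set_idx in range(1, design.n_sets_per_session + 1):
                    eps = rng.normal(0.0, params.sd_residual)
                    y = fixed_part + u_pat[p] + u_day + u_sess + u_rp[rp] + eps
                    rows.append((pid, week, day, s_idx, set_idx, rp,
                                 int(machine[p]), int(kl[p]), weight[p],
                                 int(pain[p]), age[p], sex[p], bmi[p],
                                 womac_pain[p], womac_stiff[p], womac_func[p],
                                 vas[p], biomarker_name, y))
    df = pd.DataFrame(rows, columns=[
        "participant_id", "week", "day", "session", "set", "practitioner_id",
        "machine_id", "kl_grade", "weight_kg", "contralateral_pain", "age",
        "sex", "bmi", "womac_pain", "womac_stiffness", "womac_function",
        "vas_pain_worst_knee", "biomarker_name", "biomarker_value"])
    if integer_mode:
        df["biomarker_value"] = np.clip(
            np.rint(df["biomarker_value"]), 0, None)
    return df
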