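"""Shared domain types for the knee acoustic-emission (AE) analysis pipeline.

Conventions used throughout the package:

* Amplitudes are in dB relative to 1 μV (``20·log10(v/1 μV)``); voltages in μV.
* Knee flexion angle is in degrees, flexion positive: seated ≈ 90°,
  standing ≈ 0–5°.  "Ascending" means standing up, i.e. decreasing angle.
* A "session" is a period during which the AE sensor is not removed and
  re-applied; each session contains two recorded sets of five
  sit-stand-sit movements (an initial practice set is never recorded).
* Movement quadrants: Q1 ascending-acceleration, Q2 ascending-deceleration,
  Q3 descending-acceleration, Q4 descending-deceleration.  Quadrant
  intervals are half-open ``[t0, t1)`` and tile each movement cycle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Acquisition threshold of the JAAS machines, dB re 1 μV.
DEFAULT_THRESHOLD_DB = 36.0

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

#: Columns of a hit table (pandas DataFrame) as produced by detection or
#: simulation.  ``quadrant``/``cycle_index`` are filled by segmentation;
#: off-cycle hits carry quadrant ``"off"`` and cycle_index ``-1``.
HIT_COLUMNS = ("onset_time_s", "peak_db", "asl_db", "duration_s",
               "quadrant", "cycle_index")

#: Columns of a measurement-level table: one row per
#: participant × day × session × set with the biomarker value and covariates.
MEASUREMENT_COLUMNS = (
    "participant_id", "week", "day", "session", "set", "practitioner_id",
    "machine_id", "kl_grade", "weight_kg", "contralateral_pain", "age",
    "sex", "bmi", "womac_pain", "womac_stiffness", "womac_function",
    "vas_pain_worst_knee", "biomarker_name", "biomarker_value",
)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the repeated-measures reproducibility study.

    Defaults follow the cohort protocol: 45 participants measured on day 1
    by each of 3 research practitioners (RPs, one session per RP, sensor
    re-applied between sessions), then on further days by a single RP;
    measurement days are 3 consecutive days in week 1 plus one day in each
    of the following ``n_weeks - 1`` weeks; 2 recorded sets of 5 movements
    per session; participants randomised to one of 3 JAAS machines.
    """

    n_participants: int = 45
    n_days: int = 3
    n_weeks: int = 3
    n_practitioners_day1: int = 3
    n_sets_per_session: int = 2
    n_movements_per_set: int = 5
    n_machines: int = 3
    day1_multi_rp: bool = True

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_days", "n_weeks",
                     "n_practitioners_day1", "n_sets_per_session",
                     "n_movements_per_set", "n_machines"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n_measurement_days(self) -> int:
        """Distinct measurement days per participant."""
        return self.n_days + (self.n_weeks - 1)


@dataclass
class GenerativeParams:
    """Parameters of the measurement-level generative model.

    The biomarker response for one set is

    ``y = β0 + a[kl] + weight_coef·(weight − mean weight)
        + contralateral_pain_coef·pain + machine_offset
        + u_patient + u_session + u_day + u_rp + ε``

    where the KL adjustments ``a`` are determined by the successive-level
    contrasts in ``kl_contrasts`` (``a[KL j] − a[KL j+1]``) with the
    convention that the unweighted mean of the four level effects is zero,
    so the intercept is the across-KL average at mean weight and no
    contralateral pain.  All random effects are independent Gaussians with
    the stated SDs, shared by rows belonging to the same grouping unit; the
    two sets within a session differ only by ε.

    Defaults are the study-scale estimates: fixed effects from the final
    association model, random-effect SDs from the day-one reproducibility
    model, and a day-to-day SD chosen so that the combined session+day SD
    matches the longitudinal model's day-in-patient estimate.
    """

    intercept: float = 160.13
    kl_contrasts: tuple[float, float, float] = (-81.77, 22.54, 38.39)
    weight_coef: float = 2.06
    contralateral_pain_coef: float = 57.05
    sd_patient: float = 82.06
    sd_session_in_patient: float = 46.02
    sd_day_in_patient: float = 31.5
    sd_rp: float = 6.05
    sd_residual: float = 18.74
    machine_offsets: tuple[float, ...] = (0.0, 20.39, -66.38)
    quadrant_proportions: tuple[float, float, float, float] = (0.4, 0.1, 0.1, 0.4)
    amplitude_mean_above_threshold_db: float = 8.0
    amplitude_max_db: float = 100.0
    asl_offset_range_db: tuple[float, float] = (5.0, 15.0)
    kl_probs: tuple[float, float, float, float] = (12 / 68, 22 / 68, 27 / 68, 7 / 68)
    weight_mean_kg: float = 85.0
    weight_sd_kg: float = 16.0
    pain_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sd_patient", "sd_session_in_patient", "sd_day_in_patient",
                     "sd_rp", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        q = np.asarray(self.quadrant_proportions, dtype=float)
        if q.shape != (4,) or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-12:
            raise ValueError("quadrant_proportions must be 4 non-negative "
                             "fractions summing to 1")
        if self.machine_offsets[0] != 0.0:
            raise ValueError("machine offset for the reference machine must be 0")

    @classmethod
    def variance_only(cls, **kwargs) -> "GenerativeParams":
        """Params with all covariate and machine effects zeroed — the
        generating model of an unadjusted variance-component experiment."""
        base = dict(kl_contrasts=(0.0, 0.0, 0.0), weight_coef=0.0,
                    contralateral_pain_coef=0.0,
                    machine_offsets=(0.0, 0.0, 0.0))
        base.update(kwargs)
        return cls(**base)

    def kl_level_effects(self) -> np.ndarray:
        """Per-KL-level effects (mean zero) implied by the contrasts."""
        d12, d23, d34 = self.kl_contrasts
        a = np.array([0.0, -d12, -d12 - d23, -d12 - d23 - d34])
        return a - a.mean()


@dataclass(frozen=True)
class HitTiming:
    """AE acquisition timing parameters (conventional wide-band defaults).

    ``hit_definition_time`` is the silence gap that closes a hit;
    ``peak_definition_time`` bounds the search for the peak after onset
    (informational here — the full hit window is always searched);
    ``hit_lockout_time`` is the dead time after closure during which no new
    hit may open.
    """

    hit_definition_time: float = 800e-6
    peak_definition_time: float = 200e-6
    hit_lockout_time: float = 1000e-6

    def __post_init__(self) -> None:
        if self.hit_definition_time <= 0:
            raise ValueError("hit_definition_time must be > 0")
        if self.peak_definition_time < 0 or self.hit_lockout_time < 0:
            raise ValueError("timing parameters must be >= 0")


@dataclass
class Waveform:
    """A raw AE voltage trace for one knee channel."""

    samples: np.ndarray          # μV
    sampling_rate: float         # Hz
    start_time: float = 0.0
    channel: str = "worst"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class AngleTrace:
    """Goniometer knee-flexion trace (degrees vs seconds)."""

    time: np.ndarray
    angle: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape:
            raise ValueError("time and angle must have equal length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.angle.size and not np.all(np.isfinite(self.angle)):
            raise ValueError("angles must be finite")


@dataclass
class KinematicTrace:
    """Smoothed angle with derivatives, aligned with the source trace."""

    time: np.ndarray
    angle: np.ndarray            # smoothed, degrees
    velocity: np.ndarray         # degrees/s
    acceleration: np.ndarray     # degrees/s²
    sampling_rate: float


@dataclass
class MovementCycle:
    """One sit-stand-sit cycle with its four quadrant intervals.

    ``quadrants`` maps Q1–Q4 to half-open ``[t0, t1)`` intervals which tile
    ``[start_time, end_time)``; Q1/Q2 precede ``stand_time``, Q3/Q4 follow.
    """

    start_time: float
    end_time: float
    stand_time: float
    quadrants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate_partition(self, tol: float = 1e-9) -> None:
        t = self.start_time
        for q in QUADRANTS:
            t0, t1 = self.quadrants[q]
            if abs(t0 - t) > tol or t1 < t0:
                raise ValueError(f"quadrant {q} does not tile the cycle")
            t = t1
        if abs(t - self.end_time) > tol:
            raise ValueError("quadrants do not cover the cycle")


@dataclass(frozen=True)
class BinConfig:
    """Bin grid of the 2D (ASL × peak amplitude) feature histograms.

    Default: average signal level 30–90 dB and peak amplitude 36–100 dB,
    8 bins each, so a profile is a 4 × 8 × 8 array (256-dim when flattened).
    Hits outside the ranges are clamped into the edge bins.
    """

    asl_edges: tuple[float, ...] = tuple(np.linspace(30.0, 90.0, 9))
    amp_edges: tuple[float, ...] = tuple(np.linspace(36.0, 100.0, 9))

    def __post_init__(self) -> None:
        for edges in (self.asl_edges, self.amp_edges):
            e = np.asarray(edges, float)
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.asarray(self.asl_edges, float).tobytes())
        h.update(np.asarray(self.amp_edges, float).tobytes())
        return h.hexdigest()[:16]

    @property
    def shape(self) -> tuple[int, int, int]:
        return (4, len(self.asl_edges) - 1, len(self.amp_edges) - 1)


@dataclass
class FeatureProfile:
    """Per-knee quadrant-wise 2D histograms of (ASL, peak amplitude)."""

    counts: np.ndarray           # (4, n_asl_bins, n_amp_bins)
    bins: BinConfig
    normalized: bool = False
    n_off_cycle: int = 0

    def flattened(self) -> np.ndarray:
        return self.counts.reshape(-1).astype(float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PCABasis:
    """Frozen PCA basis fitted on a developmental set of feature profiles."""

    mean: np.ndarray                  # (n_bins_total,)
    components: np.ndarray            # (n_components, n_bins_total)
    explained_variance_ratio: np.ndarray
    fingerprint: str
    n_profiles: int


@dataclass
class ParamEstimate:
    estimate: float
    lcl: float = float("nan")
    ucl: float = float("nan")


@dataclass
class VarianceComponents:
    """Fitted reproducibility model: random-effect SDs (with CIs) and JAAS
    machine fixed-effect contrasts relative to machine 1."""

    model_tag: str                         # "day_one" | "longitudinal"
    sds: dict[str, ParamEstimate]
    machine_contrasts: dict[str, ParamEstimate]
    covariate_adjusted: bool
    loglik: float
    converged: bool
    n_obs: int

    def to_frame(self):
        """Table-2-shaped frame: parameter, estimate, lcl, ucl."""
        import pandas as pd

        rows = []
        label = {"session": "Session in patient variability",
                 "day": "Day in patient variability",
                 "patient": "Patient variability",
                 "rp": "RP variability",
                 "residual": "Residual variability"}
        for k, p in self.sds.items():
            rows.append((label.get(k, k), p.estimate, p.lcl, p.ucl))
        for k, p in self.machine_contrasts.items():
            rows.append((k, p.estimate, p.lcl, p.ucl))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "lcl", "ucl"])


@dataclass
class TrialSpec:
    """Specification of a notional two-arm parallel trial with "number of
    hits" as outcome, analysed by comparing participant means."""

    n_per_group: int
    effect_fraction: float = 0.5
    alpha: float = 0.05
    baseline_mean: float = 160.13
    sd_between_participant: float = 93.17
    sd_residual: float = 22.51
    measurements_per_participant: int = 1
    n_replicates: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.effect_fraction <= 1):
            raise ValueError("effect_fraction must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100 for reporting")
        if self.measurements_per_participant < 1:
            raise ValueError("measurements_per_participant must be >= 1")

    @property
    def sd_participant_mean(self) -> float:
        m = self.measurements_per_participant
        return float(np.hypot(self.sd_between_participant,
                              self.sd_residual / np.sqrt(m)))
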