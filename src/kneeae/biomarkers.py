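"""Candidate AE biomarkers per knee recording.

Four candidates are computed from one recorded set of five sit-stand-sit
movements: the raw "number of hits" above the acquisition threshold, and
the first three principal-component scores of the knee's quadrant-wise 2D
feature histograms over (average signal level × peak amplitude) bins.  The
PCA basis is fitted once on a designated developmental subset and frozen;
evaluation recordings are only projected onto it.  Histograms are used
unnormalized by default so the PC candidates carry intensity as well as
shape information; a normalized mode is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import BinConfig, FeatureProfile, PCABasis, QUADRANTS

logger = logging.getLogger(__name__)


def number_of_hits(hits: pd.DataFrame, t_start: float | None = None,
                   t_end: float | None = None) -> int:
    """Count of hits with onset inside the recording window (default: all)."""
    if len(hits) == 0:
        return 0
    onset = hits["onset_time_s"].to_numpy(float)
    sel = np.ones(onset.size, dtype=bool)
    if t_start is not None:
        sel &= onset >= t_start
    if t_end is not None:
        sel &= onset < t_end
    return int(sel.sum())


def feature_profile(hits: pd.DataFrame, bins: BinConfig | None = None,
                    normalized: bool = False) -> FeatureProfile:
    """Quadrant-wise 2D histograms of (ASL, peak amplitude) for one knee.

    Only on-cycle hits (quadrant labels Q1–Q4) enter; off-cycle hits are
    counted separately.  Values outside the bin ranges are clamped into the
    edge bins (logged), so the unnormalized total equals the on-cycle count.
    """
    bins = bins or BinConfig()
    asl_e = np.asarray(bins.asl_edges, float)
    amp_e = np.asarray(bins.amp_edges, float)
    counts = np.zeros(bins.shape)
    n_off = 0
    n_clamped = 0
    if len(hits):
        quad = hits["quadrant"].to_numpy(object)
        n_off = int(np.sum(~np.isin(quad, QUADRANTS)))
        for qi, qname in enumerate(QUADRANTS):
            sub = hits[quad == qname]
            if len(sub) == 0:
                continue
            asl = sub["asl_db"].to_numpy(float)
            amp = sub["peak_db"].to_numpy(float)
            n_clamped += int(np.sum((asl < asl_e[0]) | (asl > asl_e[-1])
                                    | (amp < amp_e[0]) | (amp > amp_e[-1])))
            eps_a = 1e-9 * (asl_e[-1] - asl_e[0])
            eps_p = 1e-9 * (amp_e[-1] - amp_e[0])
            asl = np.clip(asl, asl_e[0], asl_e[-1] - eps_a)
            amp = np.clip(amp, amp_e[0], amp_e[-1] - eps_p)
            h, _, _ = np.histogram2d(asl, amp, bins=[asl_e, amp_e])
            counts[qi] = h
    if n_clamped:
        logger.info("%d hits outside the bin ranges were clamped to edge bins",
                    n_clamped)
    if normalized and counts.sum() > 0:
        counts = counts / counts.sum()
    return FeatureProfile(counts=counts, bins=bins, normalized=normalized,
                          n_off_cycle=n_off)


def _check_fingerprints(profiles, fingerprint=None):
    fps = {p.bins.fingerprint for p in profiles}
    if fingerprint is not None:
        fps.add(fingerprint)
    if len(fps) != 1:
        raise ValueError("feature profiles use mismatched bin grids "
                         f"(fingerprints {sorted(fps)})")


def fit_pca_basis(profiles: list[FeatureProfile],
                  n_components: int = 3) -> PCABasis:
    """Fit the frozen PCA basis on a developmental set of profiles.

    Profiles are flattened to (4 × n_asl × n_amp)-vectors and column-mean
    centred; the loadings are the top right singular vectors.  Requires at
    least ``n_components + 1`` profiles on an identical bin grid.
    """
    if len(profiles) < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} profiles to fit "
                         f"{n_components} components")
    _check_fingerprints(profiles)
    M = np.vstack([p.flattened() for p in profiles])
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(M)
    return PCABasis(mean=pca.mean_.copy(),
                    components=pca.components_.copy(),
                    explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                    fingerprint=profiles[0].bins.fingerprint,
                    n_profiles=len(profiles))


def project_candidates(profile: FeatureProfile, basis: PCABasis) -> tuple[float, ...]:
    """Scores (pc1, pc2, pc3) of a profile on the frozen developmental basis."""
    if profile.bins.fingerprint != basis.fingerprint:
        raise ValueError("profile bin grid does not match the PCA basis "
                         "fingerprint")
    scores = (profile.flattened() - basis.mean) @ basis.components.T
    return tuple(float(s) for s in scores)


def biomarker_table(per_set_hits: dict, bins: BinConfig | None = None,
                    basis: PCABasis | None = None,
                    normalized: bool = False) -> pd.DataFrame:
    """Biomarker rows for a collection of labelled per-set hit tables.

    ``per_set_hits`` maps a key tuple (participant, day, session, set) to a
    quadrant-labelled hit table.  Columns: n_hits, pc1–pc3 (NaN when no
    basis is supplied), per-quadrant counts and the off-cycle count.
    """
    bins = bins or BinConfig()
    rows = []
    for key, hits in per_set_hits.items():
        prof = feature_profile(hits, bins, normalized=normalized)
        if basis is not None:
            pcs = project_candidates(prof, basis)
        else:
            pcs = (np.nan, np.nan, np.nan)
        quad = hits["quadrant"].to_numpy(object) if len(hits) else np.array([])
        qcounts = [int(np.sum(quad == q)) for q in QUADRANTS]
        rows.append((*key, number_of_hits(hits), *pcs, *qcounts,
                     prof.n_off_cycle))
    cols = ["participant_id", "day", "session", "set", "n_hits",
            "pc1", "pc2", "pc3", "q1", "q2", "q3", "q4", "off_cycle"]
    return pd.DataFrame(rows, columns=cols)


def quadrant_hit_distribution(biomarkers: pd.DataFrame,
                              kl: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-quadrant hit-count summaries for KL 1 versus KL ≥ 2 knees.

    Returns median and IQR of the per-set quadrant counts in each severity
    group — the shape of the quadrant-skew report (hits concentrate in Q1
    and Q4, the ascending-acceleration and descending-deceleration phases).
    """
    kl = np.asarray(kl)
    if kl.shape[0] != len(biomarkers):
        raise ValueError("kl must align with the biomarker rows")
    group = np.where(kl <= 1, "KL1", "KL>=2")
    rows = []
    for g in ("KL1", "KL>=2"):
        sub = biomarkers.loc[group == g]
        for q in ("q1", "q2", "q3", "q4"):
            if len(sub):
                med = float(sub[q].median())
                q1, q3 = np.percentile(sub[q], [25, 75])
            else:
                med, q1, q3 = 0.0, 0.0, 0.0
            rows.append((g, q.upper(), med, float(q1), float(q3), len(sub)))
    return pd.DataFrame(rows, columns=["group", "quadrant", "median",
                                       "iqr_low", "iqr_high", "n_sets"])
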