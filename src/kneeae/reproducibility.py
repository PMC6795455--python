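"""Variance-component reproducibility models for a candidate biomarker.

Two Gaussian linear mixed models quantify the sources of measurement
variability, both with a fixed effect for the JAAS machine (contrasts
relative to machine 1) and crossed random effects for patient and research
practitioner (RP), estimated by restricted maximum likelihood:

* the **day-one model** uses only day-1 data, where every patient is
  measured once by each RP with the sensor re-applied between sessions,
  and adds a session-within-patient random effect — its SD captures
  sensor-reattachment variability, while the residual captures the
  between-set, within-session repeatability;
* the **longitudinal model** uses all measurement days and replaces the
  session effect with a day-within-patient random effect capturing
  day-to-day variability.

Confidence intervals for the random-effect SDs come from the profiled
restricted likelihood (so near-null components report a lower limit of
exactly 0); machine contrasts get normal-approximation intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import LMMFit, LMMProblem, profile_ci_sd
from .types import ParamEstimate, VarianceComponents

DEFAULT_ADJUST = ("kl_grade", "weight_kg", "contralateral_pain")


def _design_matrix(df: pd.DataFrame, adjust: bool):
    """Intercept + machine dummies (+ optional covariate adjustment)."""
    machines = np.sort(df["machine_id"].unique())
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for m in machines[1:]:
        cols.append((df["machine_id"] == m).to_numpy(float))
        names.append(f"JAAS {m}")
    if adjust:
        from .association import successive_difference_columns

        kl_cols, kl_names = successive_difference_columns(
            df["kl_grade"].to_numpy(int))
        cols.extend(list(kl_cols.T))
        names.extend(kl_names)
        w = df["weight_kg"].to_numpy(float)
        cols.append(w - w.mean())
        names.append("weight")
        cols.append(df["contralateral_pain"].to_numpy(float))
        names.append("contralateral pain")
    return np.column_stack(cols), names


def _fit(df: pd.DataFrame, unit_label: str, adjust: bool,
         ci: str | None) -> tuple[VarianceComponents, LMMFit]:
    X, names = _design_matrix(df, adjust)
    prob = LMMProblem(
        df["biomarker_value"].to_numpy(float), X,
        patient=df["participant_id"].to_numpy(),
        within=df[unit_label].to_numpy(),
        crossed=df["practitioner_id"].to_numpy(),
        fe_names=names,
    )
    fit = prob.fit(reml=True)
    tag = "day_one" if unit_label == "session" else "longitudinal"
    unit_key = "session" if tag == "day_one" else "day"
    sd_keys = {"patient": "patient", "within": unit_key, "crossed": "rp",
               "residual": "residual"}
    sds = {}
    for k, out in sd_keys.items():
        est = fit.sds[k]
        if ci == "profile":
            lcl, ucl = profile_ci_sd(fit, k)
        else:
            lcl = ucl = float("nan")
        sds[out] = ParamEstimate(float(est), float(lcl), float(ucl))
    contrasts = {}
    wald = fit.wald_ci()
    for j, nm in enumerate(names):
        if nm.startswith("JAAS"):
            contrasts[nm] = ParamEstimate(float(fit.beta[j]),
                                          float(wald[j, 0]), float(wald[j, 1]))
    vc = VarianceComponents(model_tag=tag, sds=sds,
                            machine_contrasts=contrasts,
                            covariate_adjusted=adjust,
                            loglik=fit.loglik, converged=fit.converged,
                            n_obs=fit.n_obs)
    return vc, fit


def fit_day_one_model(table: pd.DataFrame, adjust_covariates: bool = False,
                      ci: str | None = "profile",
                      return_fit: bool = False):
    """Fit the day-one variance-component model by REML.

    Uses only rows with ``day == 1`` (each patient measured in several
    sessions by different RPs).  Random effects: patient, session within
    patient, RP (crossed), residual.  ``ci="profile"`` computes
    profile-likelihood intervals for the SDs; ``ci=None`` skips them.
    """
    df = table[table["day"] == 1]
    if len(df) == 0:
        raise ValueError("no day-1 rows in the table")
    if df.groupby(["participant_id", "session"]).size().min() < 2 or \
            df.groupby("participant_id")["session"].nunique().min() < 2:
        raise ValueError("day-one model needs >= 2 sets per session and "
                         ">= 2 sessions per patient")
    vc, fit = _fit(df, "session", adjust_covariates, ci)
    return (vc, fit) if return_fit else vc


def fit_longitudinal_model(table: pd.DataFrame, adjust_covariates: bool = False,
                           ci: str | None = "profile",
                           return_fit: bool = False):
    """Fit the longitudinal variance-component model by REML.

    Uses all rows; random effects: patient, measurement day within patient,
    RP (crossed), residual.
    """
    if table.groupby("participant_id")["day"].nunique().min() < 2:
        raise ValueError("longitudinal model needs >= 2 days per patient")
    vc, fit = _fit(table, "day", adjust_covariates, ci)
    return (vc, fit) if return_fit else vc


def profile_confidence_intervals(fit: LMMFit, level: float = 0.95) -> dict:
    """Profile-likelihood intervals for every random-effect SD of a fit.

    ``level = 0`` degenerates to the point estimates.  SD intervals are
    truncated at 0.
    """
    out = {}
    for name in fit.problem.var_names:
        if level <= 0:
            est = fit.sds[name]
            out[name] = (est, est)
        else:
            out[name] = profile_ci_sd(fit, name, level=level)
    return out
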