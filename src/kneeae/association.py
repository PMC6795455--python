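"""Association model for "number of hits": forward selection and REML fit.

The model is a Gaussian linear mixed model with a participant-specific
random intercept (accounting for correlation between repeated measurements
of the same knee) and a residual error.  Candidate covariates enter by
forward selection on the likelihood-ratio test with a significance cut-off
of p < 0.1; selection uses full maximum likelihood so that likelihoods are
comparable across fixed-effect structures, and the final model is refitted
by restricted maximum likelihood on complete cases.

KL grade is coded with successive-difference contrasts, so each reported
coefficient is the difference between adjacent grades (KL 1 vs KL 2 is the
mean at KL 1 minus the mean at KL 2) and the intercept is the unweighted
average response across the four grades at mean weight and no
contralateral pain.  Weight is centred at the sample mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMFit, LMMProblem, lrt_pvalue, profile_ci_fixed, profile_ci_sd

logger = logging.getLogger(__name__)

#: Default candidate pool for forward selection.  "kl_grade" expands to the
#: three successive-difference contrast columns; "cartilage_thickness" is
#: used only when the column is present.
DEFAULT_CANDIDATES = ("kl_grade", "weight_kg", "contralateral_pain", "age",
                      "sex", "bmi", "womac_pain", "womac_stiffness",
                      "womac_function", "vas_pain_worst_knee")

KL_LEVELS = (1, 2, 3, 4)


def successive_difference_columns(kl: np.ndarray):
    """Contrast columns for KL grade: coefficient j is ``mean(KL j) − mean(KL j+1)``.

    The coding is the negated backward-difference scheme, chosen so that
    with an intercept column of ones the intercept estimates the unweighted
    average of the four level means.
    """
    L = len(KL_LEVELS)
    coding = np.zeros((L, L - 1))
    for j in range(L - 1):                 # backward-difference, negated
        coding[: j + 1, j] = -(L - 1 - j) / L
        coding[j + 1:, j] = (j + 1) / L
    coding = -coding
    kl = np.asarray(kl)
    if not np.isin(kl, KL_LEVELS).all():
        raise ValueError("kl_grade values must be in {1, 2, 3, 4}")
    idx = np.searchsorted(KL_LEVELS, kl)
    names = [f"KL {j+1} vs KL {j+2}" for j in range(L - 1)]
    return coding[idx], names


def _covariate_columns(df: pd.DataFrame, name: str):
    """Design columns and labels for one candidate covariate."""
    if name == "kl_grade":
        return successive_difference_columns(df["kl_grade"].to_numpy(int))
    if name == "weight_kg":
        w = df["weight_kg"].to_numpy(float)
        return (w - w.mean())[:, None], ["Weight"]
    if name == "sex":
        return (df["sex"].to_numpy(object) == "M").astype(float)[:, None], ["Sex (M)"]
    if name == "contralateral_pain":
        return df[name].to_numpy(float)[:, None], ["Pain in contralateral knee"]
    return df[name].to_numpy(float)[:, None], [name]


def build_design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones((len(df), 1))]
    names = ["Intercept"]
    for c in covariates:
        X_c, nm = _covariate_columns(df, c)
        cols.append(X_c)
        names.extend(nm)
    return np.hstack(cols), names


def _ml_fit(df: pd.DataFrame, covariates) -> LMMFit:
    X, names = build_design(df, covariates)
    prob = LMMProblem(df["biomarker_value"].to_numpy(float), X,
                      patient=df["participant_id"].to_numpy(),
                      fe_names=names)
    return prob.fit(reml=False)


@dataclass
class SelectionStep:
    covariate: str
    p_value: float
    entered: bool


@dataclass
class AssociationFit:
    """Final association model: fixed effects, random-effect SDs, CIs and
    the forward-selection trace."""

    covariates: list[str]
    coefficients: pd.DataFrame            # parameter, estimate, lcl, ucl
    sd_participant: float
    sd_participant_ci: tuple[float, float]
    sd_residual: float
    sd_residual_ci: tuple[float, float]
    loglik: float
    n_obs: int
    n_participants: int
    n_dropped_incomplete: int
    selection_trace: list[SelectionStep] = field(default_factory=list)
    fit: LMMFit | None = None


def forward_select(table: pd.DataFrame,
                   candidates=DEFAULT_CANDIDATES,
                   cutoff: float = 0.1,
                   response: str = "biomarker_value"):
    """Forward selection of covariates by LRT at significance ``cutoff``.

    Starting from the random-intercept-only model, the candidate with the
    smallest likelihood-ratio p-value is added while that p-value is below
    the cut-off.  Candidates that would make the fixed-effect matrix rank
    deficient are skipped with a log entry.  Returns the ordered list of
    selected covariates and the selection trace.
    """
    df = table.dropna(subset=[c for c in candidates if c in table.columns]
                      + [response, "participant_id"])
    selected: list[str] = []
    trace: list[SelectionStep] = []
    pool = [c for c in candidates if c in df.columns]
    current = _ml_fit(df, selected)
    while pool:
        best = None
        for cand in pool:
            X_try, _ = build_design(df, selected + [cand])
            if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
                logger.info("candidate %s collinear with current model; "
                            "skipped", cand)
                continue
            alt = _ml_fit(df, selected + [cand])
            p = lrt_pvalue(current, alt)
            if best is None or p < best[1]:
                best = (cand, p, alt)
        if best is None:
            break
        cand, p, alt = best
        if p < cutoff:
            selected.append(cand)
            pool.remove(cand)
            current = alt
            trace.append(SelectionStep(cand, p, True))
        else:
            trace.append(SelectionStep(cand, p, False))
            break
    return selected, trace


def fit_final_model(table: pd.DataFrame, covariates,
                    ci_method: str = "wald",
                    selection_trace=None) -> AssociationFit:
    """REML refit of the selected model on complete cases.

    ``ci_method`` is ``"wald"`` (normal approximation, default) or
    ``"profile"`` (likelihood profile: ML profiling for fixed effects,
    REML profiling for the SDs — slower).  Incomplete cases are dropped
    with the count recorded on the returned fit.
    """
    needed = [c for c in covariates if c in table.columns] + \
        ["biomarker_value", "participant_id"]
    df = table.dropna(subset=needed)
    n_dropped = len(table) - len(df)
    if n_dropped:
        logger.info("dropped %d incomplete rows (complete-case analysis)",
                    n_dropped)
    X, names = build_design(df, covariates)
    prob = LMMProblem(df["biomarker_value"].to_numpy(float), X,
                      patient=df["participant_id"].to_numpy(),
                      fe_names=names)
    fit = prob.fit(reml=True)
    if ci_method == "profile":
        ml_fit = prob.fit(reml=False)
        cis = np.array([profile_ci_fixed(ml_fit, j)
                        for j in range(len(names))])
        sd_p_ci = profile_ci_sd(fit, "patient")
        sd_e_ci = profile_ci_sd(fit, "residual")
    elif ci_method == "wald":
        cis = fit.wald_ci()
        sd_p_ci = profile_ci_sd(fit, "patient")
        sd_e_ci = profile_ci_sd(fit, "residual")
    else:
        raise ValueError("ci_method must be 'wald' or 'profile'")
    coef = pd.DataFrame({"parameter": names, "estimate": fit.beta,
                         "lcl": cis[:, 0], "ucl": cis[:, 1]})
    return AssociationFit(
        covariates=list(covariates), coefficients=coef,
        sd_participant=fit.sds["patient"], sd_participant_ci=tuple(sd_p_ci),
        sd_residual=fit.sds["residual"], sd_residual_ci=tuple(sd_e_ci),
        loglik=fit.loglik, n_obs=fit.n_obs,
        n_participants=df["participant_id"].nunique(),
        n_dropped_incomplete=n_dropped,
        selection_trace=list(selection_trace or []), fit=fit)


def association_table(fit: AssociationFit) -> pd.DataFrame:
    """Table-shaped output: fixed effects then random-effect SDs."""
    rows = fit.coefficients.copy()
    extra = pd.DataFrame({
        "parameter": ["Standard deviation of participant specific random effect",
                      "Standard deviation of residual error"],
        "estimate": [fit.sd_participant, fit.sd_residual],
        "lcl": [fit.sd_participant_ci[0], fit.sd_residual_ci[0]],
        "ucl": [fit.sd_participant_ci[1], fit.sd_residual_ci[1]]})
    return pd.concat([rows, extra], ignore_index=True)
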