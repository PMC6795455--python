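"""Parameter-recovery experiments for the fitted models.

The published variance components and regression coefficients for "number
of hits" are estimates from non-public clinical data, so they cannot be
recomputed from raw recordings.  What can be verified is recovery: the
synthetic generator is configured with those printed estimates as
generating truths, and the pipeline's REML fits must give them back.  Each
experiment here builds the appropriate design, simulates, fits, and
returns the estimates alongside the generating values.
"""

from __future__ import annotations

import numpy as np

from .association import fit_final_model
from .reproducibility import fit_day_one_model, fit_longitudinal_model
from .synthetic import simulate_measurement_table
from .types import GenerativeParams, StudyDesign

#: Day-one model, unadjusted point estimates (generating truths).
DAY_ONE_TRUTH = {"patient": 82.06, "session": 46.02, "rp": 6.05,
                 "residual": 18.74}
#: Longitudinal model, unadjusted point estimates.
LONGITUDINAL_TRUTH = {"day": 55.75, "patient": 79.15, "rp": 47.22,
                      "residual": 19.42}
#: Final association model for "number of hits".
ASSOCIATION_TRUTH = {"Intercept": 160.13, "KL 1 vs KL 2": -81.77,
                     "KL 2 vs KL 3": 22.54, "KL 3 vs KL 4": 38.39,
                     "Weight": 2.06, "Pain in contralateral knee": 57.05,
                     "sd_participant": 93.17, "sd_residual": 22.51}


def day_one_recovery(seed: int, n_participants: int = 500) -> dict:
    """Simulate the day-1 design (3 sessions by different practitioners,
    2 sets each) under the day-one truths and refit by REML."""
    design = StudyDesign(n_participants=n_participants, n_days=1, n_weeks=1,
                         day1_multi_rp=True)
    params = GenerativeParams.variance_only(
        sd_patient=DAY_ONE_TRUTH["patient"],
        sd_session_in_patient=DAY_ONE_TRUTH["session"],
        sd_day_in_patient=0.0, sd_rp=DAY_ONE_TRUTH["rp"],
        sd_residual=DAY_ONE_TRUTH["residual"])
    table = simulate_measurement_table(design, params, seed=seed)
    vc = fit_day_one_model(table, ci=None)
    est = {k: vc.sds[k].estimate for k in ("patient", "session", "rp",
                                           "residual")}
    return {"estimates": est, "truth": dict(DAY_ONE_TRUTH),
            "n": n_participants}


def longitudinal_recovery(seed: int, n_participants: int = 500,
                          n_days: int = 6) -> dict:
    """Simulate ``n_days`` measurement days per patient (one session of two
    sets each) under the longitudinal truths and refit by REML."""
    design = StudyDesign(n_participants=n_participants, n_days=n_days,
                         n_weeks=1, day1_multi_rp=False)
    params = GenerativeParams.variance_only(
        sd_patient=LONGITUDINAL_TRUTH["patient"],
        sd_session_in_patient=0.0,
        sd_day_in_patient=LONGITUDINAL_TRUTH["day"],
        sd_rp=LONGITUDINAL_TRUTH["rp"],
        sd_residual=LONGITUDINAL_TRUTH["residual"])
    table = simulate_measurement_table(design, params, seed=seed)
    vc = fit_longitudinal_model(table, ci=None)
    est = {k: vc.sds[k].estimate for k in ("patient", "day", "rp",
                                           "residual")}
    return {"estimates": est, "truth": dict(LONGITUDINAL_TRUTH),
            "n": n_participants}


def association_params() -> GenerativeParams:
    return GenerativeParams(
        intercept=ASSOCIATION_TRUTH["Intercept"],
        kl_contrasts=(ASSOCIATION_TRUTH["KL 1 vs KL 2"],
                      ASSOCIATION_TRUTH["KL 2 vs KL 3"],
                      ASSOCIATION_TRUTH["KL 3 vs KL 4"]),
        weight_coef=ASSOCIATION_TRUTH["Weight"],
        contralateral_pain_coef=ASSOCIATION_TRUTH["Pain in contralateral knee"],
        sd_patient=ASSOCIATION_TRUTH["sd_participant"],
        sd_session_in_patient=0.0, sd_day_in_patient=0.0, sd_rp=0.0,
        sd_residual=ASSOCIATION_TRUTH["sd_residual"],
        machine_offsets=(0.0, 0.0, 0.0))


def association_recovery(seed: int, n_replicates: int = 50,
                         n_participants: int = 1000) -> dict:
    """Replicated recovery of the association model.

    Each replicate simulates ``n_participants`` with two measurements each
    (one session, two sets) from the final-model truths, fits the REML
    model with successive-difference KL coding, and records estimates and
    Wald standard errors; returns replicate means.
    """
    design = StudyDesign(n_participants=n_participants, n_days=1, n_weeks=1,
                         day1_multi_rp=False)
    params = association_params()
    covs = ["kl_grade", "weight_kg", "contralateral_pain"]
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    ests, ses = [], []
    for s in seeds:
        table = simulate_measurement_table(design, params,
                                           seed=np.random.default_rng(s))
        fit = fit_final_model(table, covs)
        row = dict(zip(fit.coefficients["parameter"],
                       fit.coefficients["estimate"]))
        row["sd_participant"] = fit.sd_participant
        row["sd_residual"] = fit.sd_residual
        ests.append(row)
        ses.append(dict(zip(fit.coefficients["parameter"],
                            fit.fit.beta_se())))
    mean_est = {k: float(np.mean([e[k] for e in ests])) for k in ests[0]}
    mean_se = {k: float(np.mean([s[k] for s in ses])) for k in ses[0]}
    return {"estimates": mean_est, "se": mean_se,
            "truth": dict(ASSOCIATION_TRUTH),
            "n": n_participants, "n_replicates": n_replicates}
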