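"""Canned parameter-recovery experiments used by the analysis scripts and checks.

These run the *full* chain — generator, recognizer measurement model, trial
assignment, filtering, scoring, statistics — and report what comes out, so
recovered quantities are honest end-to-end measurements rather than reads of
the configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import default_config
from .scoring import score_cohort
from .stats import fit_random_intercept
from .synthesize import simulate_cohort


def recover_effects(
    group: str, n_participants: int, n_sessions: int, seed: int
) -> dict:
    """Simulate one single-group cohort and average its session effect scores.

    Returns cohort-mean interference/facilitation (seconds, clamped session
    scores as produced by the pipeline), mean accuracy and the session count.
    """
    cfg = default_config(seed)
    cfg.session_count_dist = "fixed"
    if group == "patient":
        cfg.n_nonpatients = 0
        cfg.n_patients = n_participants
        cfg.patient = dataclasses.replace(cfg.patient, n_sessions=n_sessions)
    else:
        cfg.n_patients = 0
        cfg.n_nonpatients = n_participants
        cfg.nonpatient = dataclasses.replace(cfg.nonpatient, n_sessions=n_sessions)
    cohort = simulate_cohort(cfg)
    groups = cohort.participants.set_index("participant_id")["group"]
    scores, _ = score_cohort(cohort.schedules_frame(), cohort.events_frame(), groups)
    return {
        "group": group,
        "interference_s": float(scores["interference_s"].mean()),
        "facilitation_s": float(scores["facilitation_s"].mean()),
        "interference_raw_s": float(scores["interference_raw_s"].mean()),
        "facilitation_raw_s": float(scores["facilitation_raw_s"].mean()),
        "accuracy": float(scores["accuracy"].mean()),
        "n_sessions": int(len(scores)),
    }


def mlm_slope_coverage(
    n_replicates: int = 200,
    n_participants: int = 113,
    k_sessions: int = 5,
    beta: float = -0.0004,
    outcome: str = "mean_rt_congruent",
    seed: int = 0,
) -> dict:
    """Repeated-cohort recovery of a session-covariate slope by the mixed model.

    Each replicate simulates a nonpatient cohort whose latencies carry a
    concentration slope ``beta`` (seconds per slider unit), scores it, fits the
    random-intercept model of ``outcome`` on centered concentration, and checks
    whether the 95% Wald interval covers the generating slope.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    covered = 0
    estimates = []
    for s in seeds:
        cfg = default_config(int(s))
        cfg.n_patients = 0
        cfg.n_nonpatients = n_participants
        cfg.session_count_dist = "fixed"
        cfg.nonpatient = dataclasses.replace(
            cfg.nonpatient, n_sessions=k_sessions, beta_concentration=beta
        )
        cohort = simulate_cohort(cfg)
        groups = cohort.participants.set_index("participant_id")["group"]
        scores, _ = score_cohort(cohort.schedules_frame(), cohort.events_frame(), groups)
        scores = scores.merge(
            cohort.covariates_frame(), on=["participant_id", "session_index"]
        )
        res = fit_random_intercept(scores, outcome, ["concentration"])
        b, se = res.params["concentration"], res.bse["concentration"]
        covered += int(b - 1.96 * se <= beta <= b + 1.96 * se)
        estimates.append(b)
    estimates = np.array(estimates)
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "beta_true": beta,
        "beta_mean": float(estimates.mean()),
        "relative_bias": float((estimates.mean() - beta) / beta),
    }
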