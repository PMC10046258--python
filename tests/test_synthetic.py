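"""Synthetic cohort generator: latent structure, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

from voicestroop.config import GroupParams, default_config
from voicestroop.paradigm import build_stimulus_set, make_schedule
from voicestroop.synthesize import sample_participant, simulate_cohort, simulate_session


def _noiseless(params: GroupParams) -> GroupParams:
    return dataclasses.replace(
        params,
        sd_between_s=0.0, sd_session_s=0.0, exg_sigma_s=0.0, exg_tau_s=0.0,
        p_lapse=0.0, p_wrong_word=0.0, wer=0.0,
        beta_concentration=0.0, beta_days=0.0, beta_days_ama=0.0,
        sd_dur_between_s=0.0,
    )


def test_zero_between_variance_gives_identical_means():
    params = dataclasses.replace(GroupParams(), sd_between_s=0.0)
    profiles = [sample_participant(params, seed) for seed in range(5)]
    means = {tuple(sorted(p.condition_means_s.items())) for p in profiles}
    assert len(means) == 1


def test_latent_effects_equal_group_deltas():
    params = GroupParams()
    p = sample_participant(params, 3)
    m = p.condition_means_s
    assert m["incongruent"] - m["neutral"] == pytest.approx(params.delta_interference_s)
    assert m["neutral"] - m["congruent"] == pytest.approx(params.delta_facilitation_s)


def test_sample_participant_deterministic():
    params = GroupParams(group="patient", p_ama=0.5)
    a = sample_participant(params, 42)
    b = sample_participant(params, 42)
    assert a == b


def test_lapse_probability_one_gives_no_events():
    params = dataclasses.replace(GroupParams(), p_lapse=1.0)
    profile = sample_participant(params, 0)
    sched = make_schedule(build_stimulus_set(), 0)
    rec = simulate_session(profile, sched, {"session_index": 1}, params, 0)
    assert rec.events == []


def test_noiseless_limit_latency_equals_condition_mean():
    params = _noiseless(GroupParams())
    profile = sample_participant(params, 0)
    sched = make_schedule(build_stimulus_set(), 1)
    rec = simulate_session(profile, sched, {"session_index": 1, "concentration": 80}, params, 2)
    assert len(rec.events) == 32
    for ev in rec.events:
        stim = sched.stimuli[ev.trial_index]
        latency = ev.true_onset_s - sched.onsets[ev.trial_index]
        assert latency == pytest.approx(profile.condition_means_s[stim.condition], abs=1e-12)
        assert ev.spoken_word == stim.ink_color.upper()


def test_pooled_neutral_mean_matches_configured_mean():
    """Law of large numbers: pooled neutral-trial latency -> configured neutral mean."""
    params = dataclasses.replace(
        default_config().patient, sd_between_s=0.0, p_lapse=0.0,
        beta_concentration=0.0, beta_days=0.0, beta_days_ama=0.0,
    )
    profile = sample_participant(params, 1)
    rng = np.random.default_rng(5)
    lat = []
    n_sessions = 640  # ~1e4 neutral trials pooled
    for s in range(n_sessions):
        sched = make_schedule(build_stimulus_set(), rng)
        rec = simulate_session(profile, sched, {"session_index": 1}, params, rng)
        for ev in rec.events:
            if sched.stimuli[ev.trial_index].condition == "neutral":
                lat.append(ev.true_onset_s - sched.onsets[ev.trial_index])
    lat = np.array(lat)
    trial_var = params.exg_sigma_s**2 + params.exg_tau_s**2
    se = np.sqrt(params.sd_session_s**2 / n_sessions + trial_var / lat.size)
    assert abs(lat.mean() - params.mu_neutral_s) < 3 * se


def test_cohort_session_count_and_determinism():
    cfg = default_config(99)
    cfg.n_nonpatients, cfg.n_patients = 6, 4
    a = simulate_cohort(cfg)
    assert len(a.records) == 6 * cfg.nonpatient.n_sessions + 4 * cfg.patient.n_sessions
    b = simulate_cohort(cfg)
    assert a.events_frame().to_csv(index=False) == b.events_frame().to_csv(index=False)
    assert a.covariates_frame().to_csv(index=False) == b.covariates_frame().to_csv(index=False)


def test_cohort_seed_changes_data():
    cfg = default_config(99)
    cfg.n_nonpatients, cfg.n_patients = 3, 0
    a = simulate_cohort(cfg, rng_seed=1)
    b = simulate_cohort(cfg, rng_seed=2)
    assert not a.events_frame()["true_onset_s"].equals(b.events_frame()["true_onset_s"])


def test_patient_recognized_correct_rate_matches_composite():
    """Detected-correct rate ~ (1-p_lapse)(1-p_wrong)(1-wer) in the mid-80s %."""
    cfg = default_config(17)
    cfg.n_nonpatients, cfg.n_patients = 0, 30
    cohort = simulate_cohort(cfg)
    n_correct = 0
    n_total = 0
    for rec in cohort.records:
        stimuli = rec.schedule.stimuli
        n_total += len(stimuli)
        for ev in rec.events:
            if (
                ev.detected_word is not None
                and ev.detected_word.lower() == stimuli[ev.trial_index].ink_color
            ):
                n_correct += 1
    p = cfg.patient
    composite = (1 - p.p_lapse) * (1 - p.p_wrong_word) * (1 - p.wer)
    rate = n_correct / n_total
    assert composite == pytest.approx(0.859, abs=0.01)
    assert abs(rate - composite) < 0.025
    assert 0.80 < rate < 0.92


def test_patient_covariates_structure():
    cfg = default_config(23)
    cfg.n_nonpatients, cfg.n_patients = 2, 3
    cohort = simulate_cohort(cfg)
    cov = cohort.covariates_frame()
    assert cov["concentration"].between(0, 100).all()
    assert cov["helplessness"].between(0, 100).all()
    pt = cov[cov["group"] == "patient"]
    assert pt["days_to_discharge"].notna().all()
    # discharge countdown is non-increasing across a patient's sessions
    for _, sub in pt.groupby("participant_id"):
        days = sub.sort_values("session_index")["days_to_discharge"].to_numpy()
        assert (np.diff(days) <= 0).all()
    assert cov.loc[cov["group"] == "nonpatient", "days_to_discharge"].isna().all()
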