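"""Synthetic cohort generator: participants x sessions x trials of speech events.

The generator emulates the latent structure the downstream analysis assumes:
per-participant random intercepts, per-session random shifts, ex-Gaussian
trial noise, condition effects (interference slows incongruent trials,
facilitation speeds congruent ones), utterance durations, response lapses and
wrong-word errors, session-level self-report covariates (0-100 sliders) and,
for patients, a discharge countdown with an optional against-medical-advice
(AMA) interaction.  Detected (recognizer-side) fields are produced by
:func:`voicestroop.measurement.apply_recognizer`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortConfig, GroupParams
from .measurement import apply_recognizer
from .paradigm import COLOR_WORDS, ISI_S, TrialSchedule, build_stimulus_set, make_schedule

#: sessions are spaced every other day
SESSION_SPACING_DAYS = 2
#: minimum physically plausible utterance duration (s)
MIN_DURATION_S = 0.05


@dataclass
class SpeechEvent:
    """One utterance: true timing/word plus recognizer-detected counterparts.

    ``spoken_word is None`` encodes a lapse (no utterance); detected fields are
    ``None`` iff nothing was recognized.  ``trial_index`` is 0-based internally.
    """

    trial_index: int
    true_onset_s: float
    true_duration_s: float | None = None
    spoken_word: str | None = None
    detected_onset_s: float | None = None
    detected_offset_s: float | None = None
    detected_word: str | None = None


@dataclass
class ParticipantProfile:
    """Latent truth for one participant (before trial noise)."""

    participant_id: str
    group: str
    intercept_s: float
    condition_means_s: dict[str, float]
    duration_mean_s: float
    ama_flag: bool = False
    discharge_day: int | None = None


@dataclass
class SessionRecord:
    """One participant-session: schedule, detected events, covariates."""

    participant_id: str
    session_index: int  # 1-based
    schedule: TrialSchedule
    events: list[SpeechEvent]
    covariates: dict


@dataclass
class Cohort:
    """A simulated cohort plus its participant table and provenance."""

    records: list[SessionRecord]
    participants: pd.DataFrame
    config: CohortConfig

    def schedules_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {
            "participant_id": [], "session_index": [], "trial_index": [],
            "word": [], "ink_color": [], "condition": [], "onset_s": [],
        }
        for rec in self.records:
            for k, (stim, onset) in enumerate(rec.schedule.trials):
                cols["participant_id"].append(rec.participant_id)
                cols["session_index"].append(rec.session_index)
                cols["trial_index"].append(k + 1)
                cols["word"].append(stim.word)
                cols["ink_color"].append(stim.ink_color)
                cols["condition"].append(stim.condition)
                cols["onset_s"].append(onset)
        return pd.DataFrame(cols)

    def events_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {
            "participant_id": [], "session_index": [], "trial_index": [],
            "condition": [], "true_onset_s": [], "true_duration_s": [],
            "spoken_word": [], "detected_onset_s": [], "detected_offset_s": [],
            "detected_word": [],
        }
        for rec in self.records:
            stimuli = rec.schedule.stimuli
            for ev in rec.events:
                cols["participant_id"].append(rec.participant_id)
                cols["session_index"].append(rec.session_index)
                cols["trial_index"].append(ev.trial_index + 1)  # 1-based in reports
                cols["condition"].append(stimuli[ev.trial_index].condition)
                cols["true_onset_s"].append(ev.true_onset_s)
                cols["true_duration_s"].append(ev.true_duration_s)
                cols["spoken_word"].append(ev.spoken_word)
                cols["detected_onset_s"].append(ev.detected_onset_s)
                cols["detected_offset_s"].append(ev.detected_offset_s)
                cols["detected_word"].append(ev.detected_word)
        return pd.DataFrame(cols)

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"participant_id": rec.participant_id, "session_index": rec.session_index}
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_participant(
    params: GroupParams, rng_seed, participant_id: str = "p0001"
) -> ParticipantProfile:
    """Draw one participant's latent profile.

    The random intercept is N(0, sd_between_s); the latent condition means are
    neutral + intercept, shifted by the group interference/facilitation deltas
    (plus optional between-participant effect heterogeneity when the
    ``sd_interference_s`` / ``sd_facilitation_s`` fields are nonzero).
    """
    params.validate()
    rng = _as_rng(rng_seed)
    intercept = rng.normal(0.0, params.sd_between_s) if params.sd_between_s > 0 else 0.0
    d_int = params.delta_interference_s
    d_fac = params.delta_facilitation_s
    if params.sd_interference_s > 0:
        d_int = d_int + rng.normal(0.0, params.sd_interference_s)
    if params.sd_facilitation_s > 0:
        d_fac = d_fac + rng.normal(0.0, params.sd_facilitation_s)
    neutral = params.mu_neutral_s + intercept
    means = {
        "neutral": neutral,
        "incongruent": neutral + d_int,
        "congruent": neutral - d_fac,
    }
    dur_mean = params.dur_mean_s
    if params.sd_dur_between_s > 0:
        dur_mean = max(MIN_DURATION_S, dur_mean + rng.normal(0.0, params.sd_dur_between_s))
    ama = bool(rng.random() < params.p_ama) if params.group == "patient" else False
    discharge = int(rng.integers(14, 29)) if params.group == "patient" else None
    return ParticipantProfile(
        participant_id=participant_id,
        group=params.group,
        intercept_s=intercept,
        condition_means_s=means,
        duration_mean_s=dur_mean,
        ama_flag=ama,
        discharge_day=discharge,
    )


def simulate_session(
    profile: ParticipantProfile,
    schedule: TrialSchedule,
    covariates: dict,
    params: GroupParams,
    rng_seed,
) -> SessionRecord:
    """Generate the true speech events of one session.

    Per trial: with probability ``p_lapse`` no utterance; otherwise the voice
    latency is the participant's condition mean plus a session random shift,
    covariate terms, Gaussian noise and a centered exponential tail
    (ex-Gaussian trial noise with mean equal to the condition mean).  The
    spoken word names the ink color with probability ``1 - p_wrong_word``,
    else a different color word.  Latencies may exceed the 3 s window; the
    scoring stage decides which trial such a response belongs to.
    """
    rng = _as_rng(rng_seed)
    n = len(schedule)
    stimuli = schedule.stimuli
    onsets = schedule.onsets

    session_eff = rng.normal(0.0, params.sd_session_s) if params.sd_session_s > 0 else 0.0
    conc = float(covariates.get("concentration", 50.0))
    days = covariates.get("days_to_discharge")
    days = 0.0 if days is None else float(days)
    cov_term = (
        params.beta_concentration * (conc - 50.0)
        + params.beta_days * days
        + (params.beta_days_ama * days if profile.ama_flag else 0.0)
    )

    cond_mu = np.array([profile.condition_means_s[s.condition] for s in stimuli])
    gauss = rng.normal(0.0, params.exg_sigma_s, size=n) if params.exg_sigma_s > 0 else 0.0
    expo = (
        rng.exponential(params.exg_tau_s, size=n) - params.exg_tau_s
        if params.exg_tau_s > 0
        else 0.0
    )
    latency = cond_mu + session_eff + cov_term + gauss + expo
    lapse = rng.random(n) < params.p_lapse
    wrong = rng.random(n) < params.p_wrong_word
    durations = np.maximum(
        MIN_DURATION_S, rng.normal(profile.duration_mean_s, params.dur_sd_s, size=n)
    )

    vocab = np.array(COLOR_WORDS)
    events: list[SpeechEvent] = []
    for k in range(n):
        if lapse[k]:
            continue
        correct_word = stimuli[k].ink_color.upper()
        if wrong[k]:
            others = [w for w in vocab if w != correct_word]
            word = str(others[rng.integers(0, len(others))])
        else:
            word = correct_word
        events.append(
            SpeechEvent(
                trial_index=k,
                true_onset_s=float(onsets[k] + latency[k]),
                true_duration_s=float(durations[k]),
                spoken_word=word,
            )
        )
    events.sort(key=lambda e: e.true_onset_s)
    return SessionRecord(
        participant_id=profile.participant_id,
        session_index=int(covariates.get("session_index", 1)),
        schedule=schedule,
        events=events,
        covariates=dict(covariates),
    )


def _session_counts(params: GroupParams, dist: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist == "fixed":
        return np.full(n, params.n_sessions, dtype=int)
    draws = 1 + rng.poisson(max(0, params.n_sessions - 1), size=n)
    return np.clip(draws, 1, 10)


def simulate_cohort(config: CohortConfig, rng_seed=None) -> Cohort:
    """Generate a full two-group cohort, reproducible from (config, seed).

    The recognizer is applied with each group's word error rate substituted
    into the shared recognizer settings, so the returned records carry both
    true and detected fields.
    """
    config.validate()
    seed = config.master_seed if rng_seed is None else rng_seed
    ss = np.random.SeedSequence(seed)
    records: list[SessionRecord] = []
    participant_rows = []

    for group_name, n_group in (("nonpatient", config.n_nonpatients), ("patient", config.n_patients)):
        params = config.group_params(group_name)
        group_ss, count_ss = ss.spawn(2)
        count_rng = np.random.default_rng(count_ss)
        counts = _session_counts(params, config.session_count_dist, n_group, count_rng)
        rec_params = dataclasses.replace(config.recognizer, wer=params.wer)
        for i, child in enumerate(group_ss.spawn(n_group)):
            rng = np.random.default_rng(child)
            pid = f"{'np' if group_name == 'nonpatient' else 'pt'}{i + 1:04d}"
            profile = sample_participant(params, rng, participant_id=pid)
            participant_rows.append(
                {
                    "participant_id": pid,
                    "group": group_name,
                    "intercept_s": profile.intercept_s,
                    "duration_mean_s": profile.duration_mean_s,
                    "ama_flag": profile.ama_flag,
                    "discharge_day": profile.discharge_day,
                    "n_sessions": int(counts[i]),
                }
            )
            for j in range(1, int(counts[i]) + 1):
                schedule = make_schedule(build_stimulus_set(), rng)
                covs = {
                    "session_index": j,
                    "concentration": int(rng.integers(0, 101)),
                    "helplessness": int(rng.integers(0, 101)),
                    "days_to_discharge": (
                        max(profile.discharge_day - SESSION_SPACING_DAYS * (j - 1), 0)
                        if profile.discharge_day is not None
                        else None
                    ),
                    "group": group_name,
                    "ama_flag": profile.ama_flag,
                }
                rec = simulate_session(profile, schedule, covs, params, rng)
                rec.events = apply_recognizer(rec.events, rec_params, rng)
                records.append(rec)

    participants = pd.DataFrame(participant_rows)
    return Cohort(records=records, participants=participants, config=config)
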