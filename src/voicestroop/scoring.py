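"""Scoring pipeline: trial assignment, accuracy, RT filters, session features.

Rules implemented:

* A detected utterance belongs to the trial whose half-open 3 s window
  ``[onset, onset + 3.0)`` contains its detected onset; the first utterance in
  a window is that trial's response, later ones are discarded.
* A response is *correct* when the recognized word names the trial's ink color.
* Accuracy = correct responses / total presentations (32), before any RT filter.
* RT processing keeps correct responses only, drops RTs below 200 ms, and drops
  RTs above a per-group cutoff of mean + 3 SD of the group's pooled correct
  RTs (boundaries inclusive on the keep side).
* Session features: per-condition and overall mean RT, interference
  (incongruent - neutral) and facilitation (neutral - congruent) with negative
  values clamped to zero (raw values retained), coefficients of variation
  (100 * SD / mean of kept RTs), utterance-duration means and the analogous
  clamped duration effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import CONDITIONS, ISI_S, N_TRIALS, TrialSchedule

logger = logging.getLogger(__name__)

#: minimum plausible response time; faster responses are task-unrelated artifacts
MIN_RT_S = 0.2
#: float tolerance at filter boundaries (RTs are differences of timestamps and
#: can sit an ulp below a nominal frame-aligned boundary)
_RT_TOL = 1e-9


class AssignmentError(ValueError):
    """Raised for schedules whose trial windows overlap or are malformed."""


class InsufficientDataError(ValueError):
    """Raised when a statistic requires more observations than were supplied."""


@dataclass
class TrialResponse:
    """The response (or absence of one) attributed to a single presentation."""

    trial_index: int
    condition: str
    rt_s: float | None = None
    correct: bool = False
    duration_s: float | None = None


@dataclass
class SessionScores:
    """Per-session feature vector; None marks features with no supporting data."""

    accuracy: float | None = None
    mean_rt_s: dict = field(default_factory=dict)        # per condition + "overall"
    interference_s: float | None = None
    facilitation_s: float | None = None
    interference_raw_s: float | None = None
    facilitation_raw_s: float | None = None
    cv: dict = field(default_factory=dict)               # percent, per condition + overall
    mean_duration_s: dict = field(default_factory=dict)
    duration_interference_s: float | None = None
    duration_facilitation_s: float | None = None
    duration_interference_raw_s: float | None = None
    duration_facilitation_raw_s: float | None = None
    n_kept: dict = field(default_factory=dict)


def assign_responses(schedule: TrialSchedule, events) -> list[TrialResponse]:
    """Attribute detected events to trials by their 3 s half-open windows."""
    onsets = schedule.onsets
    if len(onsets) and np.any(np.diff(onsets) < ISI_S - 1e-9):
        raise AssignmentError("trial windows overlap")
    stimuli = schedule.stimuli
    responses = [
        TrialResponse(trial_index=k, condition=stimuli[k].condition)
        for k in range(len(schedule))
    ]
    detected = sorted(
        (e for e in events if e.detected_onset_s is not None),
        key=lambda e: e.detected_onset_s,
    )
    taken: set[int] = set()
    for ev in detected:
        w = int(np.floor(ev.detected_onset_s / ISI_S + 1e-9))
        if w < 0 or w >= len(schedule) or w in taken:
            continue
        taken.add(w)
        resp = responses[w]
        resp.rt_s = float(ev.detected_onset_s - onsets[w])
        resp.correct = (
            ev.detected_word is not None
            and ev.detected_word.lower() == stimuli[w].ink_color
        )
        if ev.detected_offset_s is not None:
            resp.duration_s = float(ev.detected_offset_s - ev.detected_onset_s)
    return responses


def accuracy(responses) -> float:
    """Correct responses over total presentations."""
    responses = list(responses)
    if not responses:
        raise InsufficientDataError("no presentations")
    return sum(r.correct for r in responses) / len(responses)


def group_rt_cutoff(rts) -> float:
    """Group-level upper RT cutoff: mean + 3 * sample SD of pooled correct RTs >= 0.2 s."""
    arr = np.asarray(list(rts), dtype=float)
    arr = arr[arr >= MIN_RT_S - _RT_TOL]
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 pooled RTs to set a cutoff")
    return float(arr.mean() + 3.0 * arr.std(ddof=1))


def filter_rts(responses, cutoff_s: float) -> list[TrialResponse]:
    """Keep correct responses with MIN_RT_S <= rt <= cutoff (both ends inclusive)."""
    if cutoff_s <= MIN_RT_S:
        raise ValueError(f"cutoff must exceed {MIN_RT_S} s")
    return [
        r
        for r in responses
        if r.correct
        and r.rt_s is not None
        and MIN_RT_S - _RT_TOL <= r.rt_s <= cutoff_s + _RT_TOL
    ]


def _mean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def _cv(values) -> float | None:
    vals = np.array([v for v in values if v is not None], dtype=float)
    if vals.size < 2 or vals.mean() == 0:
        return None
    return float(100.0 * vals.std(ddof=1) / vals.mean())


def _clamped_diff(a: float | None, b: float | None) -> tuple[float | None, float | None]:
    """(clamped, raw) difference a - b; None propagates."""
    if a is None or b is None:
        return None, None
    raw = a - b
    return max(0.0, raw), raw


def session_scores(kept_responses, accuracy: float | None = None) -> SessionScores:
    """Compute the session feature vector from the filtered (kept) responses.

    ``accuracy`` is computed from all 32 presentations upstream and passed in,
    since the kept responses no longer carry the discarded trials.
    """
    kept = list(kept_responses)
    scores = SessionScores(accuracy=accuracy)
    by_cond = {c: [r for r in kept if r.condition == c] for c in CONDITIONS}
    for c in CONDITIONS:
        if not by_cond[c]:
            logger.warning("no kept responses in condition %r; features absent", c)
    groups = {**by_cond, "overall": kept}
    for name, rs in groups.items():
        scores.mean_rt_s[name] = _mean(r.rt_s for r in rs)
        scores.cv[name] = _cv(r.rt_s for r in rs)
        scores.mean_duration_s[name] = _mean(r.duration_s for r in rs)
        scores.n_kept[name] = len(rs)
    scores.interference_s, scores.interference_raw_s = _clamped_diff(
        scores.mean_rt_s["incongruent"], scores.mean_rt_s["neutral"]
    )
    scores.facilitation_s, scores.facilitation_raw_s = _clamped_diff(
        scores.mean_rt_s["neutral"], scores.mean_rt_s["congruent"]
    )
    scores.duration_interference_s, scores.duration_interference_raw_s = _clamped_diff(
        scores.mean_duration_s["incongruent"], scores.mean_duration_s["neutral"]
    )
    scores.duration_facilitation_s, scores.duration_facilitation_raw_s = _clamped_diff(
        scores.mean_duration_s["neutral"], scores.mean_duration_s["congruent"]
    )
    return scores


# ---------------------------------------------------------------------------
# Cohort-level (vectorized) pipeline on DataFrames
# ---------------------------------------------------------------------------

def assign_responses_cohort(schedules: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trial assignment for a whole cohort.

    ``schedules`` has one row per (participant_id, session_index, trial_index)
    with ink_color/condition/onset_s; ``events`` one row per utterance with
    detected_onset_s/detected_offset_s/detected_word.  Returns one row per
    presentation with rt_s, correct, duration_s (NaN where absent).
    """
    keys = ["participant_id", "session_index"]
    ev = events.loc[events["detected_onset_s"].notna()].copy()
    ev["assigned_trial"] = np.floor(ev["detected_onset_s"] / ISI_S + 1e-9).astype(int) + 1
    ev = ev[(ev["assigned_trial"] >= 1) & (ev["assigned_trial"] <= N_TRIALS)]
    ev = ev.sort_values(keys + ["detected_onset_s"], kind="mergesort")
    ev = ev.drop_duplicates(subset=keys + ["assigned_trial"], keep="first")

    resp = schedules.merge(
        ev[keys + ["assigned_trial", "detected_onset_s", "detected_offset_s", "detected_word"]],
        how="left",
        left_on=keys + ["trial_index"],
        right_on=keys + ["assigned_trial"],
    )
    resp["rt_s"] = resp["detected_onset_s"] - resp["onset_s"]
    resp["duration_s"] = resp["detected_offset_s"] - resp["detected_onset_s"]
    det = resp["detected_word"].astype("string").str.lower()
    resp["correct"] = (det == resp["ink_color"]).fillna(False).astype(bool)
    return resp[
        keys
        + ["trial_index", "condition", "ink_color", "rt_s", "correct", "duration_s"]
    ]


def group_cutoffs(responses: pd.DataFrame, groups: pd.Series) -> dict[str, float]:
    """Per-group RT cutoffs from the cohort's pooled correct RTs."""
    df = responses.merge(groups.rename("group"), left_on="participant_id", right_index=True)
    out = {}
    for g, sub in df.groupby("group"):
        rts = sub.loc[sub["correct"], "rt_s"].dropna()
        out[str(g)] = group_rt_cutoff(rts)
    return out


def score_cohort(
    schedules: pd.DataFrame,
    events: pd.DataFrame,
    participant_groups: pd.Series,
    winsorize_z: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full scoring pipeline for a cohort of serialized sessions.

    ``participant_groups`` maps participant_id -> group.  Returns the
    per-session scores table and a log dict with the cutoffs and the counts
    removed by each filter stage (auditable filter behavior).
    """
    keys = ["participant_id", "session_index"]
    responses = assign_responses_cohort(schedules, events)
    acc = (
        responses.groupby(keys)["correct"].mean().rename("accuracy").reset_index()
    )
    cutoffs = group_cutoffs(responses, participant_groups)
    resp = responses.merge(
        participant_groups.rename("group"), left_on="participant_id", right_index=True
    )
    resp["cutoff"] = resp["group"].map(cutoffs)

    answered = resp["rt_s"].notna()
    is_correct = resp["correct"] & answered
    too_fast = is_correct & (resp["rt_s"] < MIN_RT_S - _RT_TOL)
    too_slow = is_correct & (resp["rt_s"] > resp["cutoff"] + _RT_TOL)
    keep = is_correct & ~too_fast & ~too_slow
    log = {
        "cutoffs_s": cutoffs,
        "n_presentations": int(len(resp)),
        "n_answered": int(answered.sum()),
        "n_removed_incorrect_or_absent": int((~is_correct).sum()),
        "n_removed_below_200ms": int(too_fast.sum()),
        "n_removed_above_cutoff": int(too_slow.sum()),
        "n_kept": int(keep.sum()),
    }
    logger.info("scoring filter log: %s", log)

    kept = resp[keep]
    per_cond = kept.groupby(keys + ["condition"], observed=True).agg(
        mean_rt=("rt_s", "mean"),
        sd_rt=("rt_s", "std"),
        mean_dur=("duration_s", "mean"),
        n=("rt_s", "size"),
    )
    wide = per_cond.unstack("condition")
    overall = kept.groupby(keys).agg(
        mean_rt_overall=("rt_s", "mean"),
        sd_rt_overall=("rt_s", "std"),
        mean_dur_overall=("duration_s", "mean"),
        n_kept_overall=("rt_s", "size"),
    )

    scores = acc.set_index(keys)
    for cond in CONDITIONS:
        for src, dst in (("mean_rt", "mean_rt"), ("mean_dur", "mean_dur")):
            col = (src, cond)
            scores[f"{dst}_{cond}"] = wide[col] if col in wide.columns else np.nan
        if ("sd_rt", cond) in wide.columns and ("mean_rt", cond) in wide.columns:
            scores[f"cv_{cond}"] = 100.0 * wide[("sd_rt", cond)] / wide[("mean_rt", cond)]
        else:
            scores[f"cv_{cond}"] = np.nan
        scores[f"n_kept_{cond}"] = (
            wide[("n", cond)].fillna(0).astype(int) if ("n", cond) in wide.columns else 0
        )
    scores = scores.join(overall)
    scores["cv_overall"] = 100.0 * scores["sd_rt_overall"] / scores["mean_rt_overall"]
    scores = scores.drop(columns=["sd_rt_overall"])

    scores["interference_raw_s"] = scores["mean_rt_incongruent"] - scores["mean_rt_neutral"]
    scores["facilitation_raw_s"] = scores["mean_rt_neutral"] - scores["mean_rt_congruent"]
    scores["interference_s"] = scores["interference_raw_s"].clip(lower=0.0)
    scores["facilitation_s"] = scores["facilitation_raw_s"].clip(lower=0.0)
    scores["dur_interference_raw_s"] = scores["mean_dur_incongruent"] - scores["mean_dur_neutral"]
    scores["dur_facilitation_raw_s"] = scores["mean_dur_neutral"] - scores["mean_dur_congruent"]
    scores["dur_interference_s"] = scores["dur_interference_raw_s"].clip(lower=0.0)
    scores["dur_facilitation_s"] = scores["dur_facilitation_raw_s"].clip(lower=0.0)

    scores = scores.reset_index().merge(
        participant_groups.rename("group"), left_on="participant_id", right_index=True
    )
    if winsorize_z is not None:
        feature_cols = [
            c for c in scores.columns
            if scores[c].dtype.kind == "f" and not c.startswith("n_kept")
        ]
        scores = winsorize_features(scores, z=winsorize_z, columns=feature_cols)
    return scores, log


def winsorize_features(
    table: pd.DataFrame, z: float = 3.5, columns=None
) -> pd.DataFrame:
    """Replace values beyond grand mean +/- z * SD by the nearer bound, per column.

    The SD is the sample SD of the full original column; all in-bound values
    are untouched.  Non-numeric columns are passed through.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if table[c].dtype.kind in "fi"]
    for col in columns:
        vals = out[col].astype(float)
        if vals.notna().sum() < 2:
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        out[col] = vals.clip(lower=mean - z * sd, upper=mean + z * sd)
    return out


def score_session(schedule: TrialSchedule, events, cutoff_s: float) -> SessionScores:
    """Single-session convenience wrapper: assign, filter at the given cutoff, score."""
    responses = assign_responses(schedule, events)
    acc = accuracy(responses)
    kept = filter_rts(responses, cutoff_s)
    return session_scores(kept, accuracy=acc)
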