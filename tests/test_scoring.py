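"""Trial assignment, accuracy, RT filters and session feature scoring."""

import dataclasses
import random

import numpy as np
import pandas as pd
import pytest

from voicestroop.paradigm import build_stimulus_set, make_schedule, TrialSchedule
from voicestroop.scoring import (
    InsufficientDataError,
    TrialResponse,
    accuracy,
    assign_responses,
    filter_rts,
    group_rt_cutoff,
    session_scores,
    winsorize_features,
)
from voicestroop.synthesize import SpeechEvent


@pytest.fixture(scope="module")
def schedule() -> TrialSchedule:
    return make_schedule(build_stimulus_set(), seed=0)


def _event(onset, word, duration=0.4):
    return SpeechEvent(
        trial_index=-1, true_onset_s=onset, true_duration_s=duration,
        spoken_word=word, detected_onset_s=onset,
        detected_offset_s=onset + duration, detected_word=word,
    )


def test_event_within_isi_belongs_to_preceding_word(schedule):
    k = 5
    word = schedule.stimuli[k].ink_color.upper()
    responses = assign_responses(schedule, [_event(schedule.onsets[k] + 2.9, word)])
    assert responses[k].rt_s == pytest.approx(2.9)
    assert responses[k].correct


def test_event_after_isi_belongs_to_next_trial(schedule):
    k = 5
    responses = assign_responses(schedule, [_event(schedule.onsets[k] + 3.1, "RED")])
    assert responses[k].rt_s is None
    assert responses[k + 1].rt_s == pytest.approx(0.1)


def test_first_event_in_window_wins(schedule):
    k = 2
    word = schedule.stimuli[k].ink_color.upper()
    events = [_event(schedule.onsets[k] + 1.5, "RED"), _event(schedule.onsets[k] + 0.6, word)]
    responses = assign_responses(schedule, events)
    assert responses[k].rt_s == pytest.approx(0.6)


def test_no_events_gives_empty_incorrect_responses(schedule):
    responses = assign_responses(schedule, [])
    assert len(responses) == 32
    assert all(not r.correct and r.rt_s is None for r in responses)
    assert accuracy(responses) == 0.0


def test_accuracy_exact_ratio(schedule):
    responses = [TrialResponse(i, "neutral", rt_s=0.5, correct=i < 28) for i in range(32)]
    assert accuracy(responses) == pytest.approx(0.875)
    responses = [TrialResponse(i, "neutral", rt_s=0.5, correct=True) for i in range(32)]
    assert accuracy(responses) == 1.0


def test_group_cutoff_arithmetic():
    assert group_rt_cutoff([0.8, 0.8, 0.8]) == pytest.approx(0.8)
    assert group_rt_cutoff([0.6, 0.8, 1.0]) == pytest.approx(0.8 + 3 * 0.2)
    # sub-200 ms artifacts do not contaminate the pooled cutoff
    assert group_rt_cutoff([0.6, 0.8, 1.0, 0.05]) == pytest.approx(1.4)
    with pytest.raises(InsufficientDataError):
        group_rt_cutoff([0.8])


def test_cutoff_at_default_calibration_matches_closed_form(small_scores):
    """Pooled patient cutoff ~ mean + 3 SD of the configured latency mixture."""
    _, log = small_scores
    cut = log["cutoffs_s"]["patient"]
    # mixture SD: trial (sigma, tau), participant, session and condition spread
    assert 1.0 < cut < 1.4


def test_filter_rules():
    rs = [
        TrialResponse(0, "neutral", rt_s=0.15, correct=True),    # too fast
        TrialResponse(1, "neutral", rt_s=0.5, correct=False),    # incorrect
        TrialResponse(2, "neutral", rt_s=0.20, correct=True),    # boundary kept
        TrialResponse(3, "neutral", rt_s=1.36, correct=True),    # at cutoff kept
        TrialResponse(4, "neutral", rt_s=1.37, correct=True),    # above cutoff
        TrialResponse(5, "neutral", rt_s=None, correct=False),   # absent
    ]
    kept = filter_rts(rs, cutoff_s=1.36)
    assert [r.trial_index for r in kept] == [2, 3]
    with pytest.raises(ValueError):
        filter_rts(rs, cutoff_s=0.1)


def _kept(cond_means: dict, n_per=4, durations=None):
    out = []
    i = 0
    for cond, mean in cond_means.items():
        for _ in range(n_per):
            out.append(
                TrialResponse(i, cond, rt_s=mean, correct=True,
                              duration_s=(durations or {}).get(cond, 0.5))
            )
            i += 1
    return out


def test_interference_and_facilitation_from_condition_means():
    scores = session_scores(
        _kept({"incongruent": 0.862, "neutral": 0.749, "congruent": 0.702})
    )
    assert scores.interference_s == pytest.approx(0.113)
    assert scores.facilitation_s == pytest.approx(0.047)


def test_negative_effects_clamped_to_zero_raw_retained():
    scores = session_scores(
        _kept({"incongruent": 0.74, "neutral": 0.75, "congruent": 0.76})
    )
    assert scores.interference_s == 0.0
    assert scores.interference_raw_s == pytest.approx(-0.01)
    assert scores.facilitation_s == 0.0
    assert scores.facilitation_raw_s == pytest.approx(-0.01)


def test_cv_arithmetic():
    rs = [TrialResponse(i, "neutral", rt_s=v, correct=True) for i, v in enumerate([0.7, 0.8, 0.9])]
    scores = session_scores(rs)
    assert scores.mean_rt_s["neutral"] == pytest.approx(0.8)
    assert scores.cv["neutral"] == pytest.approx(12.5)
    assert scores.cv["overall"] == pytest.approx(12.5)


def test_empty_condition_features_absent():
    scores = session_scores(_kept({"incongruent": 0.9, "neutral": 0.75}))
    assert scores.mean_rt_s["congruent"] is None
    assert scores.facilitation_s is None
    assert scores.interference_s == pytest.approx(0.15)


def test_scoring_order_invariant_and_deterministic(schedule):
    events = []
    for k in range(0, 32, 2):
        word = schedule.stimuli[k].ink_color.upper()
        events.append(_event(schedule.onsets[k] + 0.5 + 0.01 * k, word))
    shuffled = events.copy()
    random.Random(4).shuffle(shuffled)
    a = session_scores(filter_rts(assign_responses(schedule, events), 1.36))
    b = session_scores(filter_rts(assign_responses(schedule, shuffled), 1.36))
    assert a == b


def test_clamping_floor_everywhere(small_scores):
    scores, _ = small_scores
    for col in ("interference_s", "facilitation_s", "dur_interference_s", "dur_facilitation_s"):
        assert (scores[col].dropna() >= 0).all()


def test_winsorize_matches_direct_clip_oracle():
    rng = np.random.default_rng(0)
    col = np.concatenate([rng.normal(0, 1, 50), [25.0, -30.0]])
    df = pd.DataFrame({"x": col})
    out = winsorize_features(df, z=3.5)
    m, s = col.mean(), col.std(ddof=1)
    expected = np.clip(col, m - 3.5 * s, m + 3.5 * s)
    np.testing.assert_allclose(out["x"].to_numpy(), expected, rtol=0, atol=1e-12)
    assert out["x"].max() == pytest.approx(m + 3.5 * s)


def test_winsorize_identity_when_within_bounds():
    df = pd.DataFrame({"x": [0.0, 0.0, 0.0, 10.0], "label": list("abcd")})
    out = winsorize_features(df, z=3.5)
    # mean 2.5, sample SD 5: the bound (20) exceeds the extreme, nothing moves
    pd.testing.assert_frame_equal(out, df)
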