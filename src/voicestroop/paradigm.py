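"""Stimulus set and timed trial schedule for the spoken color-word (Stroop) task.

One testing session presents 32 words, one every 3.0 s (1.5 s word on screen,
1.5 s fixation cross), for a total span of 96 s.  The 32 stimuli comprise
8 congruent color words (printed in the color they name), 8 incongruent color
words (printed in a non-matching color), and 16 neutral animal words (each of
4 animal words in each of the 4 ink colors).  The participant names the ink
color aloud on every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLOR_WORDS: tuple[str, ...] = ("RED", "BLUE", "GREEN", "PURPLE")
ANIMAL_WORDS: tuple[str, ...] = ("DOG", "BEAR", "TIGER", "MONKEY")
INK_COLORS: tuple[str, ...] = ("red", "blue", "green", "purple")

CONDITIONS = ("congruent", "incongruent", "neutral")

#: seconds the word stays on screen
WORD_ON_S = 1.5
#: seconds of fixation cross after the word
FIXATION_S = 1.5
#: inter-stimulus (onset-to-onset) interval in seconds
ISI_S = WORD_ON_S + FIXATION_S
#: number of trials per session
N_TRIALS = 32
#: total span of one session in seconds
TOTAL_S = N_TRIALS * ISI_S


class ScheduleCompositionError(ValueError):
    """Raised when a stimulus list does not form a valid 32-trial session."""


@dataclass(frozen=True)
class StimulusSpec:
    """A single word stimulus: the printed word, its ink color, its condition."""

    word: str
    ink_color: str
    condition: str

    def __post_init__(self) -> None:
        if self.ink_color not in INK_COLORS:
            raise ValueError(f"unknown ink color {self.ink_color!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        is_color_word = self.word in COLOR_WORDS
        names_ink = self.word.lower() == self.ink_color
        if self.condition == "congruent" and not (is_color_word and names_ink):
            raise ValueError("congruent stimulus must be a color word in its own color")
        if self.condition == "incongruent" and not (is_color_word and not names_ink):
            raise ValueError("incongruent stimulus must be a color word in another color")
        if self.condition == "neutral" and self.word not in ANIMAL_WORDS:
            raise ValueError("neutral stimulus must be an animal word")


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered, timed sequence of the 32 stimuli of one session.

    Trial k (0-based) has onset ``3.0 * k`` seconds; its response window is the
    half-open interval ``[onset, onset + 3.0)``.
    """

    trials: tuple[tuple[StimulusSpec, float], ...]
    word_on_s: float = WORD_ON_S
    fixation_s: float = FIXATION_S
    isi_s: float = ISI_S
    total_s: float = TOTAL_S

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([onset for _, onset in self.trials])

    @property
    def stimuli(self) -> tuple[StimulusSpec, ...]:
        return tuple(stim for stim, _ in self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a table (trial_index is 1-based for reporting)."""
        return pd.DataFrame(
            {
                "trial_index": np.arange(1, len(self.trials) + 1),
                "word": [s.word for s in self.stimuli],
                "ink_color": [s.ink_color for s in self.stimuli],
                "condition": [s.condition for s in self.stimuli],
                "onset_s": self.onsets,
            }
        )


def build_stimulus_set() -> list[StimulusSpec]:
    """Construct the canonical 32-stimulus set in deterministic (pre-shuffle) order.

    * 8 congruent: each color word in its own color, twice.
    * 8 incongruent: each color word twice, each time in a distinct non-matching
      color, balanced so every ink color also appears exactly twice (the two
      cyclic derangements of the four colors).
    * 16 neutral: the full cross product of the 4 animal words by 4 ink colors.
    """
    stimuli: list[StimulusSpec] = []
    for word in COLOR_WORDS:
        for _ in range(2):
            stimuli.append(StimulusSpec(word, word.lower(), "congruent"))
    n = len(COLOR_WORDS)
    for shift in (1, 2):
        for i, word in enumerate(COLOR_WORDS):
            ink = INK_COLORS[(i + shift) % n]
            stimuli.append(StimulusSpec(word, ink, "incongruent"))
    for word in ANIMAL_WORDS:
        for ink in INK_COLORS:
            stimuli.append(StimulusSpec(word, ink, "neutral"))
    return stimuli


def _check_composition(stimuli: list[StimulusSpec]) -> None:
    if len(stimuli) != N_TRIALS:
        raise ScheduleCompositionError(
            f"a session requires exactly {N_TRIALS} stimuli, got {len(stimuli)}"
        )
    counts = {c: sum(s.condition == c for s in stimuli) for c in CONDITIONS}
    if counts != {"congruent": 8, "incongruent": 8, "neutral": 16}:
        raise ScheduleCompositionError(f"bad condition composition: {counts}")


def make_schedule(stimuli: list[StimulusSpec], seed: int | np.random.Generator) -> TrialSchedule:
    """Uniformly shuffle the 32 stimuli and assign onsets at a fixed 3.0 s pace.

    The shuffle is unconstrained (immediate condition repeats allowed).  The
    same seed always yields the identical trial order.
    """
    _check_composition(stimuli)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(N_TRIALS)
    trials = tuple((stimuli[i], ISI_S * k) for k, i in enumerate(order))
    return TrialSchedule(trials=trials)
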