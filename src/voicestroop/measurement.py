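"""Recognizer measurement model: frame quantization, onset bias, word errors.

Automatic speech recognizers emit word timestamps on a fixed frame grid
(typically 10 ms, from the moving-window decoding procedure), so a true onset
anywhere inside a frame is reported as the frame start.  On top of the grid
error, automatic onsets run systematically *early* relative to manual
annotation (here modeled as a per-utterance Gaussian bias, default
36 +/- 12 ms), and a fraction of transcripts are substituted by another
in-vocabulary color word (the word error rate).
"""

from __future__ import annotations

import numpy as np

from .config import RecognizerParams
from .paradigm import COLOR_WORDS

_EPS = 1e-9  # guards float division at exact frame boundaries


def quantize_to_frame(t, frame_s: float, rounding: str = "floor"):
    """Snap time(s) ``t`` (seconds, >= 0) onto the frame grid.

    Floor indexing by default: ``floor(t / frame_s) * frame_s``, i.e. the start
    of the frame containing ``t``.  Accepts scalars or arrays.
    """
    if frame_s <= 0:
        raise ValueError("frame_s must be > 0")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cannot quantize negative times")
    ratio = arr / frame_s + _EPS
    k = np.floor(ratio) if rounding == "floor" else np.round(arr / frame_s)
    out = k * frame_s
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def _substitute_words(words: np.ndarray, sub_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace flagged words by a uniformly chosen *different* color word."""
    out = words.copy()
    idx = np.flatnonzero(sub_mask)
    if idx.size == 0:
        return out
    vocab = np.array(COLOR_WORDS)
    # draw an offset in {1, 2, 3} within the vocabulary, cyclically: never the same word
    pos = np.array([np.flatnonzero(vocab == w)[0] if w in COLOR_WORDS else -1 for w in out[idx]])
    offs = rng.integers(1, len(vocab), size=idx.size)
    new_pos = (np.where(pos >= 0, pos, 0) + offs) % len(vocab)
    out[idx] = vocab[new_pos]
    return out


def apply_recognizer(events, params: RecognizerParams, rng_seed) -> list:
    """Populate detected fields of speech events from their true fields.

    One bias draw per utterance is subtracted from both onset and offset (the
    early-detection shift is a property of the utterance, not of each edge),
    the result truncated at 0 and floor-quantized to the frame grid.  With
    probability ``params.wer`` the transcript is a different color word.
    Events with no utterance stay absent.
    """
    from .synthesize import SpeechEvent  # local import to avoid a cycle

    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    spoken_idx = [i for i, e in enumerate(events) if e.spoken_word is not None]
    n = len(spoken_idx)
    out = [
        SpeechEvent(
            trial_index=e.trial_index,
            true_onset_s=e.true_onset_s,
            true_duration_s=e.true_duration_s,
            spoken_word=e.spoken_word,
        )
        for e in events
    ]
    if n == 0:
        return out
    onsets = np.array([events[i].true_onset_s for i in spoken_idx])
    durs = np.array([events[i].true_duration_s for i in spoken_idx])
    words = np.array([events[i].spoken_word for i in spoken_idx], dtype=object)

    bias = rng.normal(params.onset_bias_mean_s, params.onset_bias_sd_s, size=n)
    det_on = quantize_to_frame(np.maximum(0.0, onsets - bias), params.frame_s, params.rounding)
    det_off = quantize_to_frame(np.maximum(0.0, onsets + durs - bias), params.frame_s, params.rounding)
    sub = rng.random(n) < params.wer
    det_words = _substitute_words(words, sub, rng)

    for j, i in enumerate(spoken_idx):
        out[i].detected_onset_s = float(det_on[j])
        out[i].detected_offset_s = float(det_off[j])
        out[i].detected_word = str(det_words[j])
    return out
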