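"""State encodings: binary bag-of-words and prosodic-feature vectors.

The learner's input for a situation is a real vector of vocabulary size N.
In *binary* (attentional) mode the vector marks which words occurred in the
utterance.  In *prosodic* (attentional-prosodic) mode each occurring word is
marked with its scalar prosodic feature -- the difference between the 75th
percentile of the word's pitch track and that of the whole utterance, so
prosodically prominent words (typically the referent name in infant-directed
speech) carry large positive values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import Situation, Vocabulary


class EncodingError(ValueError):
    pass


@dataclass
class StateVector:
    """Length-N input vector with its encoding mode ('binary' | 'prosodic')."""

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _check_tokens(situation: Situation, vocab: Vocabulary) -> None:
    for token in situation.words:
        if token not in vocab:
            raise EncodingError(
                f"situation {situation.index}: token {token!r} is not in the "
                "vocabulary; build the vocabulary from the full corpus first"
            )


def encode_binary(situation: Situation, vocab: Vocabulary) -> StateVector:
    """1 at the index of every word occurring in the utterance, 0 elsewhere."""
    _check_tokens(situation, vocab)
    values = np.zeros(len(vocab))
    for token in situation.words:
        values[vocab[token]] = 1.0
    return StateVector(values, "binary")


def percentile75(values: Sequence[float]) -> float:
    """75th percentile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EncodingError("percentile of an empty sequence is undefined")
    return float(np.percentile(values, 75))


def prosodic_feature(
    word_pitch: Sequence[float], utterance_pitch: Sequence[float]
) -> float:
    """Pitch-prominence feature of a word within its utterance (Hz).

    The difference between the 75th-percentile pitch of the word and of the
    utterance.  Adding a shared constant to both tracks leaves it unchanged.
    """
    return percentile75(word_pitch) - percentile75(utterance_pitch)


def encode_prosodic(situation: Situation, vocab: Vocabulary) -> StateVector:
    """Per-word prosodic feature at each occurring word's index, 0 elsewhere.

    If a word occurs more than once in the utterance with distinct prosodic
    values, the maximum is kept: prominence is the signal of interest.
    """
    if situation.prosody is None:
        raise EncodingError(
            f"situation {situation.index} has no prosody field; use binary "
            "encoding or supply per-word prosodic values"
        )
    _check_tokens(situation, vocab)
    values = np.zeros(len(vocab))
    filled = np.zeros(len(vocab), dtype=bool)
    for token, feat in zip(situation.words, situation.prosody):
        j = vocab[token]
        values[j] = feat if not filled[j] else max(values[j], feat)
        filled[j] = True
    return StateVector(values, "prosodic")


def encode(situation: Situation, vocab: Vocabulary, mode: str) -> StateVector:
    if mode == "binary":
        return encode_binary(situation, vocab)
    if mode == "prosodic":
        return encode_prosodic(situation, vocab)
    raise EncodingError(f"unknown encoding mode {mode!r}")
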