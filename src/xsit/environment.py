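"""Interaction environment: candidate actions and the internal reward.

The agent's action is internal -- it picks one word from the current
utterance as its hypothesis for the attended object's name.  The reward
implements the novel-name--nameless-category constraint over consecutive
situations: keeping the same word for the same attended object, or switching
words when attention switches objects, is consistent and rewarded; anything
else is penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import Corpus, Situation, Vocabulary
from .encoding import encode_binary


@dataclass
class RewardConfig:
    """Reward magnitudes for consistent / inconsistent word choices.

    The default (100, -1) follows the executable training procedures;
    ``unit()`` gives the (+1, -1) scale used when reasoning about single
    transitions.  Only the relative ordering matters for greedy behaviour.
    """

    r_match: float = 100.0
    r_mismatch: float = -1.0

    def __post_init__(self) -> None:
        if not self.r_match > self.r_mismatch:
            raise ValueError("r_match must exceed r_mismatch")

    @classmethod
    def unit(cls) -> "RewardConfig":
        return cls(r_match=1.0, r_mismatch=-1.0)


@dataclass
class Transition:
    """One (s, a, s', a', r) experience, plus bookkeeping for masked targets.

    ``candidates`` / ``next_candidates`` are the word indices available in
    each utterance; value maxima over the next state are restricted to
    ``next_candidates``.
    """

    state: np.ndarray
    action: int
    attended: str
    next_state: np.ndarray
    next_action: int
    reward: float
    candidates: tuple[int, ...] = ()
    next_candidates: tuple[int, ...] = ()


def action_space(situation: Situation, vocab: Vocabulary) -> list[int]:
    """Indices of the distinct word types in the utterance, ascending.

    Duplicate tokens within the utterance collapse to one action: actions are
    word types, not utterance positions.
    """
    return sorted({vocab[t] for t in situation.words})


def compute_reward(
    prev_attended: str,
    prev_word: int,
    curr_attended: str,
    curr_word: int,
    cfg: RewardConfig,
) -> float:
    """Consistency reward over one attended-object transition.

    r_match when (same object and same word) or (different object and
    different word); r_mismatch otherwise.  Word equality is vocabulary
    word-type equality.
    """
    same_object = prev_attended == curr_attended
    same_word = prev_word == curr_word
    return cfg.r_match if same_object == same_word else cfg.r_mismatch


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """Discounted sum sum_j gamma^(j-i) r_j from the first element onward."""
    rewards = np.asarray(rewards, dtype=float)
    if rewards.size == 0:
        raise ValueError("rewards sequence is empty")
    return float(rewards @ gamma ** np.arange(rewards.size))


Policy = Callable[[Situation, Sequence[int]], int]
"""A policy maps (situation, candidate word indices) to a chosen index."""


def run_episode(
    corpus: Corpus,
    vocab: Vocabulary,
    policy: Policy,
    cfg: RewardConfig,
) -> tuple[list[Transition], float]:
    """One in-order pass over the corpus under ``policy``.

    The first situation has no predecessor and produces no reward, so a
    corpus of P situations yields P-1 transitions.  Returns the transition
    list and the total (undiscounted) episode reward.
    """
    transitions: list[Transition] = []
    total = 0.0
    if len(corpus) == 0:
        return transitions, total
    prev = corpus.situations[0]
    prev_candidates = action_space(prev, vocab)
    prev_action = policy(prev, prev_candidates)
    prev_state = encode_binary(prev, vocab).values
    for sit in corpus.situations[1:]:
        candidates = action_space(sit, vocab)
        action = policy(sit, candidates)
        state = encode_binary(sit, vocab).values
        reward = compute_reward(
            prev.attended_object, prev_action, sit.attended_object, action, cfg
        )
        transitions.append(
            Transition(
                state=prev_state,
                action=prev_action,
                attended=prev.attended_object,
                next_state=state,
                next_action=action,
                reward=reward,
                candidates=tuple(prev_candidates),
                next_candidates=tuple(candidates),
            )
        )
        total += reward
        prev, prev_action, prev_state, prev_candidates = sit, action, state, candidates
    return transitions, total
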