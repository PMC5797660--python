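"""Table-based learners: Q-learning, SARSA, and SARSA-lambda.

The value table has one row per situation and one column per vocabulary
word.  During training, each visit to a situation folds that situation's
(utterance-masked) value row into the attended object's row of the
word-object matrix ``QW`` as a running mean; the lexicon is later read off
``QW``.

All stochastic choices flow through one seeded generator, so training is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Vocabulary
from .environment import RewardConfig, compute_reward


@dataclass
class TabularParams:
    """Hyperparameters of the table-based learners.

    alpha : learning rate (step size of the temporal-difference update)
    gamma : discount factor for future reward
    epsilon : exploration probability, held fixed for tabular training
    lam : eligibility-trace decay (SARSA-lambda only)
    episodes : number of full passes over the corpus
    """

    alpha: float = 0.001
    gamma: float = 0.99
    epsilon: float = 0.99
    lam: float = 0.9
    episodes: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("gamma", "epsilon", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.episodes < 0:
            raise ValueError("episodes must be non-negative")


class QWMatrix:
    """Objects-by-words matrix of running-averaged value vectors.

    Row ``j`` is the arithmetic mean of all value vectors contributed while
    object ``j`` was attended; ``counts[j]`` tracks how many.
    """

    def __init__(self, objects: Sequence[str], words: Sequence[str]):
        self.objects = list(objects)
        self.words = list(words)
        self.values = np.zeros((len(self.objects), len(self.words)))
        self.counts = np.zeros(len(self.objects), dtype=int)
        self._object_index = {o: j for j, o in enumerate(self.objects)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def update(self, attended: str, vector: np.ndarray) -> None:
        """Fold one value vector into the attended object's running mean."""
        try:
            j = self._object_index[attended]
        except KeyError:
            raise KeyError(f"unknown object label {attended!r}") from None
        self.counts[j] += 1
        self.values[j] += (vector - self.values[j]) / self.counts[j]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.objects, columns=self.words)
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QWMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        qw = cls(list(frame.index), [str(c) for c in frame.columns])
        qw.values = frame.to_numpy(dtype=float)
        return qw


def update_qw(qw: QWMatrix, attended: str, q_row: np.ndarray) -> QWMatrix:
    """Functional alias for :meth:`QWMatrix.update` (mutates and returns qw)."""
    qw.update(attended, np.asarray(q_row, dtype=float))
    return qw


@dataclass
class EligibilityTraces:
    """Per-(situation, word) memory for SARSA-lambda; zeroed at episode start."""

    values: np.ndarray

    @classmethod
    def zeros(cls, n_situations: int, n_words: int) -> "EligibilityTraces":
        return cls(np.zeros((n_situations, n_words)))

    def reset(self) -> None:
        self.values[:] = 0.0


def epsilon_greedy(
    q_row: np.ndarray,
    candidates: Sequence[int],
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """Pick a candidate word index: explore uniformly w.p. epsilon, else greedy.

    The greedy arm breaks ties toward the lowest word index, so behaviour is
    deterministic given the generator state.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate action set is empty")
    if epsilon > 0 and rng.random() < epsilon:
        return candidates[int(rng.integers(len(candidates)))]
    return greedy(q_row, candidates)


def greedy(q_row: np.ndarray, candidates: Sequence[int]) -> int:
    """Argmax of q_row over candidates, lowest index on ties."""
    candidates = sorted(candidates)
    values = np.asarray(q_row)[candidates]
    return candidates[int(np.argmax(values))]


def q_learning_update(
    Q: np.ndarray,
    s: int,
    a: int,
    r: float,
    s_next: int,
    next_candidates: Sequence[int],
    params: TabularParams,
) -> float:
    """Off-policy one-step update; the bootstrap max is restricted to the
    next utterance's candidate words.  Returns the new entry Q[s, a]."""
    target = r + params.gamma * float(np.max(Q[s_next, list(next_candidates)]))
    Q[s, a] += params.alpha * (target - Q[s, a])
    return float(Q[s, a])


def sarsa_update(
    Q: np.ndarray,
    s: int,
    a: int,
    r: float,
    s_next: int,
    a_next: int,
    params: TabularParams,
) -> float:
    """On-policy one-step update bootstrapping on the actually-chosen a_next."""
    target = r + params.gamma * Q[s_next, a_next]
    Q[s, a] += params.alpha * (target - Q[s, a])
    return float(Q[s, a])


def sarsa_lambda_update(
    Q: np.ndarray,
    e: EligibilityTraces,
    s: int,
    a: int,
    r: float,
    s_next: int,
    a_next: int,
    params: TabularParams,
) -> float:
    """SARSA update with replacing eligibility traces.

    The temporal-difference error is computed once, the current pair's trace
    is set to 1, every pair with a live trace moves by alpha*delta*trace, and
    all traces decay by gamma*lambda.  Only nonzero traces are touched, so a
    lambda of 0 reproduces plain SARSA's single-entry increments exactly.
    """
    delta = r + params.gamma * Q[s_next, a_next] - Q[s, a]
    e.values[s, a] = 1.0
    rows, cols = e.values.nonzero()
    Q[rows, cols] += params.alpha * delta * e.values[rows, cols]
    e.values[rows, cols] *= params.gamma * params.lam
    return float(delta)


@dataclass
class TabularResult:
    q: np.ndarray
    qw: QWMatrix
    history: np.ndarray


ALGORITHMS = ("qlearn", "sarsa", "sarsa_lambda")


def train_tabular(
    corpus: Corpus,
    vocab: Vocabulary,
    algorithm: str = "qlearn",
    params: TabularParams | None = None,
    reward_cfg: RewardConfig | None = None,
) -> TabularResult:
    """Train a table-based learner over repeated in-order corpus passes.

    Each episode walks situations 1..P in order.  For Q-learning the reward
    is computed against the greedy next-step word; for SARSA variants against
    the epsilon-greedy word that will actually be used next.  After every
    update the current situation's value row, masked to its utterance words,
    is contributed to the attended object's QW row.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    params = params or TabularParams()
    reward_cfg = reward_cfg or RewardConfig()
    rng = np.random.default_rng(params.seed)

    P, N = len(corpus), len(vocab)
    from .environment import action_space  # local import to avoid cycle at module load

    candidates = [action_space(s, vocab) for s in corpus]
    attended = [s.attended_object for s in corpus]

    Q = rng.random((P, N))
    qw = QWMatrix(corpus.object_inventory, vocab.words)
    traces = EligibilityTraces.zeros(P, N)
    history = np.zeros(params.episodes)

    def contribute(t: int) -> None:
        row = np.zeros(N)
        row[candidates[t]] = Q[t, candidates[t]]
        qw.update(attended[t], row)

    for episode in range(params.episodes):
        total = 0.0
        if algorithm == "qlearn":
            for t in range(P - 1):
                a = epsilon_greedy(Q[t], candidates[t], params.epsilon, rng)
                a_next = greedy(Q[t + 1], candidates[t + 1])
                r = compute_reward(attended[t], a, attended[t + 1], a_next, reward_cfg)
                q_learning_update(Q, t, a, r, t + 1, candidates[t + 1], params)
                contribute(t)
                total += r
        else:
            traces.reset()
            a = epsilon_greedy(Q[0], candidates[0], params.epsilon, rng)
            for t in range(P - 1):
                a_next = epsilon_greedy(Q[t + 1], candidates[t + 1], params.epsilon, rng)
                r = compute_reward(attended[t], a, attended[t + 1], a_next, reward_cfg)
                if algorithm == "sarsa":
                    sarsa_update(Q, t, a, r, t + 1, a_next, params)
                else:
                    sarsa_lambda_update(Q, traces, t, a, r, t + 1, a_next, params)
                contribute(t)
                total += r
                a = a_next
        history[episode] = total
    return TabularResult(q=Q, qw=qw, history=history)
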