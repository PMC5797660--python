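"""Neural value learners: online Q-NN, batch NFQ, and replay-based DQN.

The action-value function is a four-layer perceptron mapping the length-N
utterance vector to one value per vocabulary word: N -> H -> H -> N with
sigmoid hidden activations and a softmax output head.  The softmax head
concentrates value mass on one word per utterance, which is what the lexicon
readout needs.  Only the chosen action's output enters the squared-error
loss; other outputs receive gradient solely through the softmax coupling.

Three trainers share the loop structure (one in-order pass over the corpus
per episode, reward from attended-object transitions, running-mean QW
bookkeeping) and differ in how the regression step uses experience:

* Q-NN  -- one gradient step per situation on the newest transition;
* NFQ   -- keeps the most recent J transitions and regresses on the whole
           stored batch once per situation;
* DQN   -- samples a minibatch from a replay memory and bootstraps on a
           periodically-synced target copy of the network.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, Vocabulary
from .encoding import encode
from .environment import RewardConfig, Transition, action_space, compute_reward
from .tabular import QWMatrix, epsilon_greedy, greedy


@dataclass
class NeuralParams:
    """Hyperparameters shared by the neural trainers.

    alpha : gradient-descent step size
    gamma : discount factor
    epsilon_start / epsilon_end : linear annealing range of the exploration
        probability (annealed over the configured number of episodes, then
        held at epsilon_end)
    hidden : units per hidden layer
    capacity : replay / storage size J (NFQ and DQN)
    minibatch : DQN minibatch size
    target_sync : DQN target-network refresh period C (gradient steps)
    init_scale : half-range of the uniform weight initialization
    double_dqn : if True, the bootstrap action is chosen by the online
        network and evaluated by the target network
    """

    alpha: float = 0.001
    gamma: float = 0.99
    epsilon_start: float = 0.99
    epsilon_end: float = 0.0001
    hidden: int = 200
    capacity: int = 50
    minibatch: int = 10
    target_sync: int = 4
    episodes: int = 300
    seed: int = 0
    init_scale: float = 0.01
    double_dqn: bool = False

    def __post_init__(self) -> None:
        if self.minibatch > self.capacity:
            raise ValueError("minibatch cannot exceed replay capacity")
        if self.target_sync < 1:
            raise ValueError("target_sync must be >= 1")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class QNetwork:
    """N -> H -> H -> N perceptron (sigmoid, sigmoid, softmax)."""

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")

    def __init__(self, n_words: int, hidden: int, rng: np.random.Generator,
                 init_scale: float = 0.01):
        self.n_words = n_words
        self.hidden = hidden
        s = init_scale
        self.W1 = rng.uniform(-s, s, (n_words, hidden))
        self.b1 = rng.uniform(-s, s, hidden)
        self.W2 = rng.uniform(-s, s, (hidden, hidden))
        self.b2 = rng.uniform(-s, s, hidden)
        self.W3 = rng.uniform(-s, s, (hidden, n_words))
        self.b3 = rng.uniform(-s, s, n_words)

    def _forward_full(self, X: np.ndarray):
        h1 = _sigmoid(X @ self.W1 + self.b1)
        h2 = _sigmoid(h1 @ self.W2 + self.b2)
        out = _softmax(h2 @ self.W3 + self.b3)
        return h1, h2, out

    def forward(self, state: np.ndarray) -> np.ndarray:
        """Per-word value vector for one state or a batch of states."""
        X = np.asarray(state, dtype=float)
        if X.ndim == 1:
            if X.shape[0] != self.n_words:
                raise ValueError(
                    f"state has length {X.shape[0]}, expected {self.n_words}")
            return self._forward_full(X[None, :])[2][0]
        if X.shape[1] != self.n_words:
            raise ValueError(
                f"states have width {X.shape[1]}, expected {self.n_words}")
        return self._forward_full(X)[2]

    def gradient_step(
        self,
        X: np.ndarray,
        actions: Sequence[int],
        targets: np.ndarray,
        alpha: float,
    ) -> float:
        """One SGD step on mean_b (target_b - Q(s_b, a_b))^2.

        Targets are constants (no gradient flows through them).  Returns the
        pre-step loss.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        actions = np.asarray(actions, dtype=int)
        targets = np.atleast_1d(np.asarray(targets, dtype=float))
        B = X.shape[0]
        h1, h2, out = self._forward_full(X)
        chosen = out[np.arange(B), actions]
        loss = float(np.mean((targets - chosen) ** 2))

        # dL/d chosen output, then through the softmax Jacobian row.
        g = -2.0 * (targets - chosen) / B                     # (B,)
        dlogits = (g * chosen)[:, None] * (-out)              # cross terms
        dlogits[np.arange(B), actions] += g * chosen          # + delta term
        dW3 = h2.T @ dlogits
        db3 = dlogits.sum(axis=0)
        dh2 = dlogits @ self.W3.T
        dz2 = dh2 * h2 * (1.0 - h2)
        dW2 = h1.T @ dz2
        db2 = dz2.sum(axis=0)
        dh1 = dz2 @ self.W2.T
        dz1 = dh1 * h1 * (1.0 - h1)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)

        self.W1 -= alpha * dW1
        self.b1 -= alpha * db1
        self.W2 -= alpha * dW2
        self.b2 -= alpha * db2
        self.W3 -= alpha * dW3
        self.b3 -= alpha * db3
        return loss

    def copy(self) -> "QNetwork":
        clone = QNetwork.__new__(QNetwork)
        clone.n_words = self.n_words
        clone.hidden = self.hidden
        for name in self.PARAM_NAMES:
            setattr(clone, name, getattr(self, name).copy())
        return clone

    def copy_from(self, other: "QNetwork") -> None:
        for name in self.PARAM_NAMES:
            getattr(self, name)[...] = getattr(other, name)

    def parameters(self) -> list[np.ndarray]:
        return [getattr(self, name) for name in self.PARAM_NAMES]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path, seed: int | None = None) -> None:
        """Write parameters as JSON: a shape/activation header plus flat data."""
        payload = {
            "meta": {
                "n_words": self.n_words,
                "hidden": self.hidden,
                "activations": ["sigmoid", "sigmoid", "softmax"],
                "seed": seed,
            },
            "params": {
                name: getattr(self, name).ravel().tolist()
                for name in self.PARAM_NAMES
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "QNetwork":
        payload = json.loads(Path(path).read_text())
        meta = payload["meta"]
        net = cls.__new__(cls)
        net.n_words = meta["n_words"]
        net.hidden = meta["hidden"]
        shapes = {
            "W1": (net.n_words, net.hidden), "b1": (net.hidden,),
            "W2": (net.hidden, net.hidden), "b2": (net.hidden,),
            "W3": (net.hidden, net.n_words), "b3": (net.n_words,),
        }
        for name, shape in shapes.items():
            setattr(net, name, np.asarray(payload["params"][name]).reshape(shape))
        return net


def init_network(n_words: int, params: NeuralParams,
                 rng: np.random.Generator | None = None) -> QNetwork:
    """Fresh seeded network with uniform weights in +/- init_scale."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return QNetwork(n_words, params.hidden, rng, params.init_scale)


class ReplayBuffer:
    """Bounded FIFO of transitions; oldest entries are evicted first."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._items: deque[Transition] = deque(maxlen=capacity)

    def append(self, transition: Transition) -> None:
        self._items.append(transition)

    def __len__(self) -> int:
        return len(self._items)

    def __getitem__(self, i: int) -> Transition:
        return self._items[i]

    def __iter__(self):
        return iter(self._items)

    def sample(self, rng: np.random.Generator, k: int) -> list[Transition]:
        idx = rng.choice(len(self._items), size=k, replace=False)
        return [self._items[int(i)] for i in idx]


def anneal_epsilon(episode: int, params: NeuralParams,
                   horizon: int | None = None) -> float:
    """Linear exploration schedule over episodes 1..horizon, then clamped.

    The annealing horizon defaults to the configured episode count.
    """
    if episode < 1:
        raise ValueError("episodes are 1-based")
    horizon = params.episodes if horizon is None else horizon
    if horizon <= 1:
        return params.epsilon_start if episode <= 1 else params.epsilon_end
    if episode >= horizon:
        return params.epsilon_end
    frac = (episode - 1) / (horizon - 1)
    return params.epsilon_start + frac * (params.epsilon_end - params.epsilon_start)


def qnn_step(net: QNetwork, transition: Transition, params: NeuralParams) -> float:
    """Online update: one gradient step on the newest transition.

    Target is r + gamma * Q(s', a'; theta), treated as a constant.
    """
    q_next = net.forward(transition.next_state)
    target = transition.reward + params.gamma * q_next[transition.next_action]
    return net.gradient_step(
        transition.state[None, :], [transition.action], [target], params.alpha
    )


def nfq_step(net: QNetwork, buffer: ReplayBuffer, params: NeuralParams) -> float:
    """Batch regression step over every stored transition.

    Targets r_j + gamma * Q(s_{j+1}, a_{j+1}; theta) are computed for the
    whole store with the current weights, then one gradient step is taken on
    the mean squared error.
    """
    if len(buffer) == 0:
        raise ValueError("NFQ requires a non-empty transition store")
    batch = list(buffer)
    X = np.stack([t.state for t in batch])
    X_next = np.stack([t.next_state for t in batch])
    actions = [t.action for t in batch]
    q_next = net.forward(X_next)
    targets = np.array(
        [t.reward + params.gamma * q_next[j, t.next_action]
         for j, t in enumerate(batch)]
    )
    return net.gradient_step(X, actions, targets, params.alpha)


def dqn_step(
    net: QNetwork,
    target: QNetwork,
    buffer: ReplayBuffer,
    params: NeuralParams,
    rng: np.random.Generator,
    step_counter: int,
) -> tuple[bool, int]:
    """One replay minibatch update; syncs the target every C gradient steps.

    The bootstrap value at s_{j+1} is the maximum of the target network's
    outputs restricted to that situation's candidate words (or, with
    ``double_dqn``, the target network's value at the online network's
    argmax).  If the buffer holds fewer than ``minibatch`` transitions the
    update is skipped.  Returns (stepped, updated step counter).
    """
    if len(buffer) < params.minibatch:
        return False, step_counter
    batch = buffer.sample(rng, params.minibatch)
    X = np.stack([t.state for t in batch])
    X_next = np.stack([t.next_state for t in batch])
    actions = [t.action for t in batch]
    q_next_target = target.forward(X_next)
    if params.double_dqn:
        q_next_online = net.forward(X_next)
        boot = [
            q_next_target[j, greedy(q_next_online[j], t.next_candidates)]
            for j, t in enumerate(batch)
        ]
    else:
        boot = [
            float(np.max(q_next_target[j, list(t.next_candidates)]))
            for j, t in enumerate(batch)
        ]
    targets = np.array([t.reward for t in batch]) + params.gamma * np.array(boot)
    net.gradient_step(X, actions, targets, params.alpha)
    step_counter += 1
    if step_counter % params.target_sync == 0:
        target.copy_from(net)
    return True, step_counter


@dataclass
class NeuralResult:
    net: QNetwork
    qw: QWMatrix
    history: np.ndarray


NEURAL_ALGORITHMS = ("qnn", "nfq", "dqn")


def train_neural(
    corpus: Corpus,
    vocab: Vocabulary,
    algorithm: str = "dqn",
    encoding_mode: str = "binary",
    params: NeuralParams | None = None,
    reward_cfg: RewardConfig | None = None,
) -> NeuralResult:
    """Train a neural learner and accumulate the word-object matrix.

    Each episode is one in-order pass over the corpus.  Per situation pair
    the agent picks a word from the current utterance (epsilon-greedy over
    the network's outputs, exploration annealed across episodes), receives
    the consistency reward against the greedy next-step word, performs the
    algorithm's regression step, and folds the freshly-updated value vector
    of the current state -- masked to the utterance's words, zero elsewhere,
    as in the tabular learners -- into the attended object's QW row (running
    mean).  Masking keeps each word's QW column supported on the situations
    where the word was actually heard.
    """
    if algorithm not in NEURAL_ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {NEURAL_ALGORITHMS}")
    params = params or NeuralParams()
    reward_cfg = reward_cfg or RewardConfig()
    rng = np.random.default_rng(params.seed)

    states = np.stack([encode(s, vocab, encoding_mode).values for s in corpus])
    candidates = [action_space(s, vocab) for s in corpus]
    attended = [s.attended_object for s in corpus]
    P, N = states.shape

    net = init_network(N, params, rng)
    target_net = net.copy() if algorithm == "dqn" else None
    buffer = ReplayBuffer(params.capacity) if algorithm in ("nfq", "dqn") else None
    qw = QWMatrix(corpus.object_inventory, vocab.words)
    history = np.zeros(params.episodes)
    step_counter = 0

    for episode in range(1, params.episodes + 1):
        eps = anneal_epsilon(episode, params)
        total = 0.0
        for t in range(P - 1):
            q_s = net.forward(states[t])
            a = epsilon_greedy(q_s, candidates[t], eps, rng)
            if algorithm == "dqn":
                q_next = target_net.forward(states[t + 1])
            else:
                q_next = net.forward(states[t + 1])
            a_next = greedy(q_next, candidates[t + 1])
            r = compute_reward(attended[t], a, attended[t + 1], a_next, reward_cfg)
            transition = Transition(
                state=states[t],
                action=a,
                attended=attended[t],
                next_state=states[t + 1],
                next_action=a_next,
                reward=r,
                candidates=tuple(candidates[t]),
                next_candidates=tuple(candidates[t + 1]),
            )
            if algorithm == "qnn":
                qnn_step(net, transition, params)
            elif algorithm == "nfq":
                buffer.append(transition)
                nfq_step(net, buffer, params)
            else:
                buffer.append(transition)
                _, step_counter = dqn_step(
                    net, target_net, buffer, params, rng, step_counter
                )
            q_up = net.forward(states[t])
            contrib = np.zeros(N)
            contrib[candidates[t]] = q_up[candidates[t]]
            qw.update(attended[t], contrib)
            total += r
        history[episode - 1] = total
    return NeuralResult(net=net, qw=qw, history=history)
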