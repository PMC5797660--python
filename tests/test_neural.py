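"""Neural learners: network mechanics, replay, annealing, trainers."""

import numpy as np
import pytest

from xsit import (
    GeneratorConfig,
    NeuralParams,
    QNetwork,
    ReplayBuffer,
    RewardConfig,
    Transition,
    anneal_epsilon,
    build_vocabulary,
    dqn_step,
    generate_corpus,
    init_network,
    nfq_step,
    qnn_step,
    train_neural,
)


def small_params(**overrides):
    defaults = dict(hidden=16, episodes=5, seed=0, init_scale=0.5)
    defaults.update(overrides)
    return NeuralParams(**defaults)


def make_transition(rng, n, reward=1.0):
    cand = tuple(sorted(rng.choice(n, 3, replace=False).tolist()))
    return Transition(
        state=rng.random(n),
        action=int(cand[0]),
        attended="o",
        next_state=rng.random(n),
        next_action=int(cand[1]),
        reward=reward,
        candidates=cand,
        next_candidates=cand,
    )


class TestNetwork:
    def test_same_seed_identical_parameters(self):
        p = small_params()
        n1, n2 = init_network(9, p), init_network(9, p)
        for a, b in zip(n1.parameters(), n2.parameters()):
            assert np.array_equal(a, b)

    def test_softmax_head_sums_to_one(self):
        rng = np.random.default_rng(1)
        net = init_network(12, small_params(seed=3))
        for _ in range(5):
            out = net.forward(rng.random(12))
            assert out.shape == (12,)
            assert (out > 0).all()
            assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_init_gives_uniform_output(self):
        net = init_network(8, small_params(init_scale=0.0))
        out = net.forward(np.random.default_rng(0).random(8))
        assert np.allclose(out, 1.0 / 8)

    def test_dimension_mismatch_rejected(self):
        net = init_network(5, small_params())
        with pytest.raises(ValueError):
            net.forward(np.zeros(6))

    def test_backprop_matches_finite_differences(self):
        """Central-difference check of the squared-error gradient on an
        H=5, N=8 network, every parameter tensor, 1e-5 relative."""
        rng = np.random.default_rng(4)
        net = init_network(8, NeuralParams(hidden=5, seed=4, init_scale=0.5))
        x = rng.random(8)
        action, target = 3, 0.8

        def loss_of(n):
            return (target - n.forward(x)[action]) ** 2

        stepped = net.copy()
        stepped.gradient_step(x[None, :], [action], [target], alpha=1.0)
        eps = 1e-6
        for name in QNetwork.PARAM_NAMES:
            analytic = getattr(net, name) - getattr(stepped, name)
            flat = getattr(net, name)
            it = np.nditer(flat, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                plus = net.copy()
                getattr(plus, name)[idx] += eps
                minus = net.copy()
                getattr(minus, name)[idx] -= eps
                numeric = (loss_of(plus) - loss_of(minus)) / (2 * eps)
                assert analytic[idx] == pytest.approx(numeric, rel=1e-5, abs=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        net = init_network(6, small_params(hidden=4))
        path = tmp_path / "model.json"
        net.save(path, seed=0)
        again = QNetwork.load(path)
        x = np.random.default_rng(2).random(6)
        assert np.array_equal(net.forward(x), again.forward(x))


class TestSteps:
    def test_zero_alpha_leaves_parameters(self):
        rng = np.random.default_rng(5)
        net = init_network(7, small_params())
        before = [p.copy() for p in net.parameters()]
        tr = make_transition(rng, 7)
        net.gradient_step(tr.state[None, :], [tr.action], [1.0], alpha=0.0)
        for a, b in zip(net.parameters(), before):
            assert np.array_equal(a, b)

    def test_qnn_step_reduces_loss(self):
        rng = np.random.default_rng(6)
        p = small_params(alpha=0.01)
        net = init_network(7, p)
        tr = make_transition(rng, 7)
        q_next = net.forward(tr.next_state)
        target = tr.reward + p.gamma * q_next[tr.next_action]
        before = (target - net.forward(tr.state)[tr.action]) ** 2
        qnn_step(net, tr, p)
        after = (target - net.forward(tr.state)[tr.action]) ** 2
        assert after <= before

    def test_qnn_step_deterministic(self):
        rng = np.random.default_rng(7)
        tr = make_transition(rng, 7)
        p = small_params()
        n1, n2 = init_network(7, p), init_network(7, p)
        qnn_step(n1, tr, p)
        qnn_step(n2, tr, p)
        for a, b in zip(n1.parameters(), n2.parameters()):
            assert np.array_equal(a, b)

    def test_nfq_batch_of_one_equals_qnn(self):
        rng = np.random.default_rng(8)
        tr = make_transition(rng, 7)
        p = small_params()
        n1, n2 = init_network(7, p), init_network(7, p)
        buf = ReplayBuffer(5)
        buf.append(tr)
        qnn_step(n1, tr, p)
        nfq_step(n2, buf, p)
        for a, b in zip(n1.parameters(), n2.parameters()):
            assert np.allclose(a, b, atol=1e-15)

    def test_nfq_reduces_batch_loss(self):
        rng = np.random.default_rng(9)
        p = small_params(alpha=0.01)
        net = init_network(7, p)
        buf = ReplayBuffer(10)
        for _ in range(6):
            buf.append(make_transition(rng, 7))

        def batch_loss(n):
            total = 0.0
            for t in buf:
                target = t.reward + p.gamma * n.forward(t.next_state)[t.next_action]
                total += (target - n.forward(t.state)[t.action]) ** 2
            return total / len(buf)

        before = batch_loss(net)
        nfq_step(net, buf, p)
        assert batch_loss(net) <= before

    def test_nfq_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            nfq_step(init_network(4, small_params()), ReplayBuffer(3), small_params())

    def test_dqn_underfull_buffer_is_noop(self):
        p = small_params(minibatch=4, capacity=8)
        net = init_network(6, p)
        target = net.copy()
        buf = ReplayBuffer(8)
        buf.append(make_transition(np.random.default_rng(0), 6))
        before = [w.copy() for w in net.parameters()]
        stepped, counter = dqn_step(net, target, buf, p, np.random.default_rng(1), 0)
        assert not stepped and counter == 0
        for a, b in zip(net.parameters(), before):
            assert np.array_equal(a, b)

    def test_dqn_sync_every_step_when_c_is_one(self):
        rng = np.random.default_rng(10)
        p = small_params(minibatch=2, capacity=4, target_sync=1)
        net = init_network(6, p)
        target = net.copy()
        buf = ReplayBuffer(4)
        for _ in range(3):
            buf.append(make_transition(rng, 6))
        _, counter = dqn_step(net, target, buf, p, rng, 0)
        assert counter == 1
        for a, b in zip(net.parameters(), target.parameters()):
            assert np.array_equal(a, b)

    def test_dqn_gamma_zero_targets_are_rewards(self):
        """With gamma=0 the update must match a direct regression onto the
        stored rewards alone."""
        rng = np.random.default_rng(11)
        p = small_params(minibatch=2, capacity=4, gamma=0.0)
        net = init_network(6, p)
        buf = ReplayBuffer(4)
        for _ in range(3):
            buf.append(make_transition(rng, 6, reward=0.5))
        twin = net.copy()
        batch = buf.sample(np.random.default_rng(99), 2)
        twin.gradient_step(
            np.stack([t.state for t in batch]),
            [t.action for t in batch],
            [t.reward for t in batch],
            p.alpha,
        )
        dqn_step(net, net.copy(), buf, p, np.random.default_rng(99), 0)
        for a, b in zip(net.parameters(), twin.parameters()):
            assert np.allclose(a, b, atol=1e-15)


class TestReplayBuffer:
    def test_fifo_eviction_oracle(self):
        """After J+k insertions the oldest k transitions are gone, in order."""
        J, k = 5, 3
        buf = ReplayBuffer(J)
        rng = np.random.default_rng(12)
        items = [make_transition(rng, 4) for _ in range(J + k)]
        for it in items:
            buf.append(it)
        assert len(buf) == J
        assert list(buf) == items[k:]

    def test_capacity_validated(self):
        with pytest.raises(ValueError):
            ReplayBuffer(0)


class TestAnnealing:
    def test_schedule_endpoints_and_midpoint(self):
        p = small_params(episodes=101)
        assert anneal_epsilon(1, p) == pytest.approx(0.99)
        assert anneal_epsilon(101, p) == pytest.approx(0.0001)
        assert anneal_epsilon(500, p) == pytest.approx(0.0001)
        assert anneal_epsilon(51, p) == pytest.approx((0.99 + 0.0001) / 2)

    def test_invalid_episode_rejected(self):
        with pytest.raises(ValueError):
            anneal_epsilon(0, small_params())


def learnable_corpus(seed=3, prosody=False):
    cfg = GeneratorConfig(
        n_objects=4, n_referent_words=6, n_filler_words=15, n_situations=80,
        max_visible=3, p_referent_word=0.9, prosody_mode=prosody, seed=seed,
    )
    corpus, gold = generate_corpus(cfg)
    return corpus, gold, build_vocabulary(corpus)


class TestTrainers:
    def test_zero_episodes_returns_fresh_net(self):
        corpus, _, vocab = learnable_corpus()
        p = small_params(episodes=0)
        res = train_neural(corpus, vocab, "qnn", "binary", p)
        fresh = init_network(len(vocab), p, np.random.default_rng(p.seed))
        for a, b in zip(res.net.parameters(), fresh.parameters()):
            assert np.array_equal(a, b)
        assert res.history.size == 0

    @pytest.mark.parametrize("algorithm", ["qnn", "nfq", "dqn"])
    def test_seeded_runs_are_bit_reproducible(self, algorithm):
        corpus, _, vocab = learnable_corpus()
        p = small_params(episodes=3, seed=21)
        r1 = train_neural(corpus, vocab, algorithm, "binary", p)
        r2 = train_neural(corpus, vocab, algorithm, "binary", p)
        assert np.array_equal(r1.qw.values, r2.qw.values)
        assert np.array_equal(r1.history, r2.history)
        for a, b in zip(r1.net.parameters(), r2.net.parameters()):
            assert np.array_equal(a, b)

    def test_qw_entries_bounded_and_presence_gated(self):
        """Softmax outputs keep every QW entry in [0, 1); words an object
        never co-occurred with keep exactly zero."""
        corpus, _, vocab = learnable_corpus()
        res = train_neural(corpus, vocab, "qnn", "binary", small_params(episodes=2))
        assert (res.qw.values >= 0).all()
        assert (res.qw.values < 1).all()
        heard = np.zeros_like(res.qw.values, dtype=bool)
        for sit in corpus:
            j = corpus.object_index(sit.attended_object)
            for tok in sit.words:
                heard[j, vocab[tok]] = True
        assert not res.qw.values[~heard].any()

    def test_prosodic_mode_requires_prosody(self):
        corpus, _, vocab = learnable_corpus(prosody=False)
        with pytest.raises(Exception, match="prosody|binary"):
            train_neural(corpus, vocab, "qnn", "prosodic", small_params(episodes=1))

    @pytest.mark.parametrize("algorithm", ["qnn", "nfq", "dqn"])
    def test_directional_learning(self, algorithm):
        """Mean episode reward over the last tenth of training exceeds the
        first tenth on a learnable corpus (aggregated over 3 seeds)."""
        corpus, _, vocab = learnable_corpus(seed=5)
        firsts, lasts = [], []
        for seed in (1, 2, 3):
            p = NeuralParams(
                hidden=24, episodes=60, seed=seed, init_scale=0.5, alpha=0.1
            )
            res = train_neural(
                corpus, vocab, algorithm, "binary", p, RewardConfig.unit()
            )
            k = max(1, len(res.history) // 10)
            firsts.append(res.history[:k].mean())
            lasts.append(res.history[-k:].mean())
        assert np.mean(lasts) > np.mean(firsts)
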