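import numpy as np
import pytest

from gazelearn.cog import COGSequence
from gazelearn.srn import (SRNWeights, forward_step, init_weights, initial_state,
                           loss_gradients, run_sequence, train_step)


def _toy_weights(n_pixels=9, n_hidden=5, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    n_in = n_pixels + n_hidden + 2
    return SRNWeights(w1=rng.normal(0, scale, (n_in, n_hidden)),
                      w2=rng.normal(0, scale, (n_hidden, n_pixels)))


def _toy_sequence(L=5, P=3, seed=0):
    rng = np.random.default_rng(seed)
    return COGSequence(patches=rng.random((L, P, P)),
                       coords=rng.random((L, 2)),
                       frame_indices=np.arange(L), observer_id="toy")


class TestInitWeights:
    def test_full_size_shapes(self):
        w = init_weights(0)
        assert w.w1.shape == (2083, 400)
        assert w.w2.shape == (400, 1681)
        assert w.n_inputs == 2083

    def test_fan_in_bounds(self):
        w = init_weights(1)
        assert w.w1.min() >= 0 and w.w1.max() <= 1 / 2083
        assert w.w2.min() >= 0 and w.w2.max() <= 1 / 400

    def test_deterministic(self):
        a, b = init_weights(42), init_weights(42)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)

    def test_mean_matches_uniform_closed_form(self):
        """Uniform(0,1)/fan_in has mean 1/(2 fan_in); the ~833k first-layer
        weights land within 2 SEM of it."""
        w = init_weights(7)
        n = w.w1.size
        sem = (1 / 2083) / np.sqrt(12 * n)
        assert abs(w.w1.mean() - 1 / (2 * 2083)) < 2 * sem


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        w = SRNWeights(w1=np.zeros((16, 5)), w2=np.zeros((5, 9)))
        out, state = forward_step(w, np.zeros(9), initial_state(5), (0.3, 0.7))
        assert np.allclose(out, 0.5) and np.allclose(state, 0.5)

    def test_input_vector_length_enforced(self):
        w = _toy_weights()
        with pytest.raises(ValueError):
            forward_step(w, np.zeros(8), initial_state(5), (0, 0))
        with pytest.raises(ValueError):
            forward_step(w, np.zeros(9), initial_state(4), (0, 0))

    def test_matches_hand_computed_logistic(self):
        """1-pixel patch, 1 hidden unit, all weights 1: hand-computed
        logistic chain."""
        w = SRNWeights(w1=np.ones((4, 1)), w2=np.ones((1, 1)))
        sample, state, coords = np.array([0.2]), np.array([0.5]), (0.1, 0.3)
        z1 = 0.2 + 0.5 + 0.1 + 0.3
        h = 1 / (1 + np.exp(-z1))
        expected = 1 / (1 + np.exp(-h))
        out, new_state = forward_step(w, sample, state, coords)
        assert out[0] == pytest.approx(expected)
        assert new_state[0] == pytest.approx(h)

    def test_activations_strictly_inside_unit_interval(self):
        w = _toy_weights(scale=3.0)
        out, state = forward_step(w, np.random.default_rng(1).random(9),
                                  initial_state(5), (0.5, 0.5))
        assert np.all((out > 0) & (out < 1))
        assert np.all((state > 0) & (state < 1))


class TestTrainStep:
    def test_perfect_prediction_no_update(self):
        w = SRNWeights(w1=np.zeros((16, 5)), w2=np.zeros((5, 9)))
        target = np.full(9, 0.5)  # logistic(0) == 0.5 == target
        w1_before = w.w1.copy()
        _, rmse, _ = train_step(w, np.zeros(9), initial_state(5), (0, 0), target)
        assert rmse == 0.0
        assert np.array_equal(w.w1, w1_before)

    def test_rmse_closed_form(self):
        w = SRNWeights(w1=np.zeros((16, 5)), w2=np.zeros((5, 9)))
        _, rmse, _ = train_step(w, np.zeros(9), initial_state(5), (0, 0),
                                np.ones(9))
        assert rmse == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        """Analytic backprop gradients agree with central differences of
        the half-sum-of-squares loss to 1e-6 relative error."""
        w = _toy_weights(seed=seed)
        rng = np.random.default_rng(seed + 100)
        sample = rng.random(9)
        state = rng.random(5)
        coords = rng.random(2)
        target = rng.random(9)
        g1, g2, _, _ = loss_gradients(w, sample, state, coords, target)

        def loss(weights):
            out, _ = forward_step(weights, sample, state, coords)
            return 0.5 * np.sum((out - target) ** 2)

        eps = 1e-6
        for grad, mat in ((g1, w.w1), (g2, w.w2)):
            idx = [tuple(rng.integers(0, s, 2)) for s in [mat.shape] * 8]
            for i, j in [(int(a), int(b)) for a, b in idx]:
                orig = mat[i, j]
                mat[i, j] = orig + eps
                hi = loss(w)
                mat[i, j] = orig - eps
                lo = loss(w)
                mat[i, j] = orig
                num = (hi - lo) / (2 * eps)
                assert num == pytest.approx(grad[i, j], rel=1e-6, abs=1e-10)


class TestRunSequence:
    def test_two_sample_sequence_one_prediction(self):
        w = _toy_weights()
        seq = _toy_sequence(L=2)
        rmse, _ = run_sequence(w, seq, mode="test")
        out, _ = forward_step(w, seq.patches[0].ravel(), initial_state(5),
                              seq.coords[1])
        assert rmse == pytest.approx(
            np.sqrt(np.mean((out - seq.patches[1].ravel()) ** 2)))

    def test_reset1_equals_canonical_on_two_samples(self):
        w = _toy_weights()
        seq = _toy_sequence(L=2)
        a, _ = run_sequence(w, seq, mode="test", reset_interval=1)
        b, _ = run_sequence(w, seq, mode="test")
        assert a == b

    def test_reset1_equals_memoryless_network(self):
        """Resetting every sample makes the SRN identical to a feedforward
        net whose context is pinned at 0.5."""
        w = _toy_weights(seed=3)
        seq = _toy_sequence(L=8, seed=3)
        rmse_reset, _ = run_sequence(w, seq, mode="test", reset_interval=1)
        total = 0.0
        for t in range(len(seq) - 1):
            out, _ = forward_step(w, seq.patches[t].ravel(), initial_state(5),
                                  seq.coords[t + 1])
            total += np.sqrt(np.mean((out - seq.patches[t + 1].ravel()) ** 2))
        assert rmse_reset == pytest.approx(total / (len(seq) - 1))

    def test_test_mode_leaves_weights_untouched(self):
        w = _toy_weights()
        before = (w.w1.copy(), w.w2.copy())
        run_sequence(w, _toy_sequence(), mode="test")
        assert np.array_equal(w.w1, before[0]) and np.array_equal(w.w2, before[1])

    def test_training_converges_on_constant_sequence(self):
        """A repeated identical patch is a 1-pattern problem: long-run RMSE
        decreases and approaches the representable minimum."""
        w = _toy_weights(seed=5, scale=0.1)
        patch = np.full((1, 3, 3), 0.4)
        seq = COGSequence(patches=np.repeat(patch, 4, axis=0),
                          coords=np.tile([0.5, 0.5], (4, 1)),
                          frame_indices=np.zeros(4, dtype=int))
        errs = []
        for _ in range(300):
            rmse, w = run_sequence(w, seq, mode="train", lr=0.5)
            errs.append(rmse)
        assert errs[-1] < errs[0] / 10
        assert errs[-1] < 0.01

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            run_sequence(_toy_weights(), _toy_sequence(L=1))
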