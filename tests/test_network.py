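"""Forward/backward passes, schedule, dropout and training loop."""

import math

import numpy as np
import pytest

from glycurate.network import (
    Hyperparams,
    NetworkParams,
    TrainingDivergence,
    accuracy,
    backward,
    forward,
    init_params,
    learning_rate,
    loss,
    train,
)


def hand_params():
    """3-input / 2-hidden / 2-output fixture with hand-set weights."""
    return NetworkParams(
        W1=np.array([[0.5, -1.0], [0.25, 0.5], [-0.75, 2.0]]),
        b1=np.array([0.1, -0.2]),
        W2=np.array([[1.0, -0.5], [0.5, 0.25]]),
        b2=np.array([-0.1, 0.3]),
    )


class TestForward:
    def test_zero_params_give_half_half(self):
        params = NetworkParams(
            W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 2)), b2=np.zeros(2)
        )
        out, _ = forward(np.array([1, 0, 1, 1]), params)
        assert np.allclose(out, [0.5, 0.5])

    def test_negative_preactivation_is_exactly_zero(self):
        params = hand_params()
        x = np.array([0.0, 0.0, 1.0])  # z1 = (-0.65, 1.8) -> unit 0 dead
        _, cache = forward(x, params)
        hidden = np.maximum(cache["z1"], 0.0)
        assert hidden[0, 0] == 0.0

    def test_hand_computed_fixture_full_precision(self):
        params = hand_params()
        x = np.array([1.0, 1.0, 0.0])
        z1 = np.array([0.5 + 0.25 + 0.1, -1.0 + 0.5 - 0.2])
        h = np.maximum(z1, 0)  # (0.85, 0.0)
        z2 = np.array([h[0] * 1.0 + h[1] * 0.5 - 0.1, h[0] * -0.5 + h[1] * 0.25 + 0.3])
        expected = 1 / (1 + np.exp(-z2))
        out, _ = forward(x, params)
        assert np.allclose(out, expected, rtol=0, atol=1e-15)

    def test_outputs_are_independent_sigmoids_not_softmax(self):
        out, _ = forward(np.array([1.0, 1.0, 1.0]), hand_params())
        assert not math.isclose(float(out[0] + out[1]), 1.0, abs_tol=1e-6)
        assert 0 < out[0] < 1 and 0 < out[1] < 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            forward(np.ones(5), hand_params())


class TestLoss:
    def test_uninformative_prediction_closed_form(self):
        assert loss(np.array([0.5, 0.5]), np.array([1, 0])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_perfect_prediction_tends_to_zero(self):
        assert loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-10

    def test_symmetry_under_label_swap(self):
        a, b = 0.83, 0.21
        assert loss(np.array([a, b]), np.array([1, 0])) == pytest.approx(
            loss(np.array([b, a]), np.array([0, 1])), abs=1e-15
        )


def finite_difference_grads(x, y, params, mask, keep, step=1e-5):
    """Central-difference oracle through the exact forward/loss path."""
    grads = {}
    for name in ("W1", "b1", "W2", "b2"):
        arr = getattr(params, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + step
            mode = "train" if mask is not None else "eval"
            up, _ = forward(x, params, mode=mode, mask=mask, keep_prob=keep)
            lo_ = None
            arr[idx] = orig - step
            down, _ = forward(x, params, mode=mode, mask=mask, keep_prob=keep)
            arr[idx] = orig
            g[idx] = (loss(up, y) - loss(down, y)) / (2 * step)
        grads[name] = g
    return grads


def random_config(rng, with_dropout=False):
    n_in = int(rng.integers(2, 6))
    n_hidden = int(rng.integers(2, 5))
    n_samples = int(rng.integers(1, 4))
    params = NetworkParams(
        W1=rng.normal(0, 1, (n_in, n_hidden)),
        b1=rng.normal(0, 1, n_hidden),
        W2=rng.normal(0, 1, (n_hidden, 2)),
        b2=rng.normal(0, 1, 2),
    )
    x = rng.integers(0, 2, (n_samples, n_in)).astype(float)
    y = np.zeros((n_samples, 2))
    for i in range(n_samples):
        y[i, int(rng.integers(0, 2))] = 1
    mask = None
    keep = 1.0
    if with_dropout:
        keep = 0.7
        mask = (rng.random((n_samples, n_hidden)) < keep).astype(float)
        if mask.sum() == 0:
            mask.flat[0] = 1.0
    return x, y, params, mask, keep


def assert_grads_match(analytic, fd, rtol=1e-5):
    for name in ("W1", "b1", "W2", "b2"):
        a = getattr(analytic, name)
        f = fd[name]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(f)), 1e-8)
        rel = np.abs(a - f) / denom
        small = np.abs(a - f) < 1e-10  # both effectively zero
        assert np.all((rel < rtol) | small), f"{name}: max rel err {rel.max():.2e}"


class TestBackward:
    def test_gradients_match_finite_differences_100_configs(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            x, y, params, mask, keep = random_config(rng)
            _, cache = forward(x, params, mode="eval")
            if np.abs(cache["z1"]).min() < 1e-3:  # avoid the ReLU kink
                continue
            analytic = backward(cache, y)
            fd = finite_difference_grads(x, y, params, None, 1.0)
            assert_grads_match(analytic, fd)
            checked += 1

    def test_gradients_with_dropout_mask(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            x, y, params, mask, keep = random_config(rng, with_dropout=True)
            _, cache = forward(x, params, mode="train", mask=mask, keep_prob=keep)
            if np.abs(cache["z1"]).min() < 1e-3:
                continue
            analytic = backward(cache, y)
            fd = finite_difference_grads(x, y, params, mask, keep)
            assert_grads_match(analytic, fd)
            checked += 1

    def test_dropped_units_have_zero_gradient(self):
        x = np.array([[1.0, 1.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        params = hand_params()
        mask = np.array([[1.0, 0.0]])  # drop hidden unit 1
        _, cache = forward(x, params, mode="train", mask=mask, keep_prob=0.7)
        grads = backward(cache, y)
        assert np.all(grads.W1[:, 1] == 0)
        assert grads.b1[1] == 0
        assert np.all(grads.W2[1, :] == 0)

    def test_label_shape_mismatch(self):
        _, cache = forward(np.ones(3), hand_params())
        with pytest.raises(ValueError):
            backward(cache, np.ones((3, 2)))


class TestLearningRate:
    H = Hyperparams()

    @pytest.mark.parametrize(
        "epoch,expected",
        [
            (0, 0.25),
            (50, 0.25 * math.exp(-0.05 * 50)),
            (99, 0.25 * math.exp(-0.05 * 99)),
            (100, 0.25 * 0.95),
            (250, 0.25 * 0.95**2 * math.exp(-0.05 * 50)),
            (999, 0.25 * 0.95**9 * math.exp(-0.05 * 99)),
        ],
    )
    def test_closed_form(self, epoch, expected):
        assert learning_rate(epoch, self.H) == pytest.approx(expected, rel=1e-12)

    def test_epoch99_end_of_cycle_magnitude(self):
        # 0.25 * exp(-0.05 * 99) = 0.0017709 (approx 0.001773 at 3 figures)
        assert learning_rate(99, self.H) == pytest.approx(0.001773, abs=5e-6)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            learning_rate(1000, self.H)
        with pytest.raises(ValueError):
            learning_rate(-1, self.H)

    def test_degenerate_schedule_constant(self):
        h = Hyperparams(k=0.0, d=1.0)
        rates = {learning_rate(e, h) for e in range(0, 1000, 97)}
        assert rates == {0.25}

    def test_strictly_decreasing_within_cycle(self):
        rates = [learning_rate(e, self.H) for e in range(100)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_cycle_peaks_strictly_decreasing(self):
        peaks = [learning_rate(c * 100, self.H) for c in range(10)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))


class TestAccuracy:
    def test_all_correct(self):
        preds = np.array([[0.9, 0.1], [0.2, 0.7]])
        labels = np.array([[1, 0], [0, 1]])
        assert accuracy(preds, labels) == 1.0

    def test_hand_built_set_of_four(self):
        preds = np.array([[0.9, 0.2], [0.4, 0.6], [0.3, 0.8], [0.7, 0.1]])
        labels = np.array([[1, 0], [1, 0], [0, 1], [1, 0]])
        assert accuracy(preds, labels) == 0.75

    def test_exact_tie_counts_negative(self):
        preds = np.array([[0.5, 0.5]])
        assert accuracy(preds, np.array([[0, 1]])) == 1.0
        assert accuracy(preds, np.array([[1, 0]])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((0, 2)), np.zeros((0, 2)))


def separable_data(rng, n=40, n_features=20):
    """Single planted discriminative bit at index 0."""
    y_pos = rng.random(n) < 0.5
    X = (rng.random((n, n_features)) < 0.3).astype(float)
    X[:, 0] = y_pos
    Y = np.column_stack([y_pos, ~y_pos]).astype(float)
    return X, Y


class TestTrain:
    def test_trace_has_one_record_per_epoch_default_1000(self):
        rng = np.random.default_rng(0)
        X, Y = separable_data(rng, n=16, n_features=5)
        h = Hyperparams(hidden_units=4, seed=1)  # default 10 cycles x 100 epochs
        params, trace = train(X, Y, X, Y, h)
        assert len(trace) == 1000

    def test_separable_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X, Y = separable_data(rng)
        h = Hyperparams(hidden_units=8, seed=2)  # full 1000-epoch schedule
        _, trace = train(X, Y, X, Y, h)
        assert max(rec[2] for rec in trace.epochs) == 1.0
        first_perfect = next(i for i, rec in enumerate(trace.epochs) if rec[2] == 1.0)
        assert first_perfect < 1000

    def test_returned_params_attain_max_test_accuracy(self):
        rng = np.random.default_rng(3)
        X, Y = separable_data(rng, n=30)
        Xt, Yt = separable_data(rng, n=20)
        h = Hyperparams(hidden_units=8, n_cycles=2, seed=4)
        params, trace = train(X, Y, Xt, Yt, h)
        out, _ = forward(Xt, params)
        assert accuracy(out, Yt) == pytest.approx(trace.test_accuracies().max())
        assert trace.epochs[trace.best_epoch][3] == trace.test_accuracies().max()

    def test_no_dropout_training_is_bit_deterministic(self):
        rng = np.random.default_rng(5)
        X, Y = separable_data(rng, n=20, n_features=6)
        h = Hyperparams(dropout=0.0, hidden_units=6, n_cycles=1, seed=9)
        p1, t1 = train(X, Y, X, Y, h)
        p2, t2 = train(X, Y, X, Y, h)
        assert np.array_equal(p1.W1, p2.W1) and np.array_equal(p1.W2, p2.W2)
        assert np.array_equal(p1.b1, p2.b1) and np.array_equal(p1.b2, p2.b2)
        assert t1.epochs == t2.epochs

    def test_divergent_learning_rate_aborts_with_diagnostic(self):
        rng = np.random.default_rng(6)
        X, Y = separable_data(rng, n=16, n_features=5)
        # a rate this large overflows the weight products past float range
        h = Hyperparams(ilr=1e160, hidden_units=8, n_cycles=1, dropout=0.0, seed=1)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(TrainingDivergence):
                train(X, Y, X, Y, h)

    def test_empty_test_set_rejected(self):
        rng = np.random.default_rng(8)
        X, Y = separable_data(rng, n=10, n_features=4)
        h = Hyperparams(hidden_units=4, n_cycles=1)
        with pytest.raises(ValueError):
            train(X, Y, np.zeros((0, 4)), np.zeros((0, 2)), h)


class TestDropoutExpectation:
    def test_inverted_dropout_preserves_expected_activation(self):
        """Monte-Carlo mean of train-mode hidden output equals eval mode."""
        rng = np.random.default_rng(11)
        params = init_params(6, 8, rng)
        x = rng.integers(0, 2, (1, 6)).astype(float)
        keep = 0.7
        _, cache_eval = forward(x, params, mode="eval")
        eval_hidden = cache_eval["hidden_dropped"]

        n_masks = 10_000
        masks = (rng.random((n_masks, 8)) < keep).astype(float)
        z1 = x @ params.W1 + params.b1
        h = np.maximum(z1, 0.0)
        samples = h * masks / keep  # (n_masks, 8)
        mc_mean = samples.mean(axis=0)
        mc_se = samples.std(axis=0, ddof=1) / np.sqrt(n_masks)
        diff = np.abs(mc_mean - eval_hidden[0])
        assert np.all(diff <= 3 * mc_se + 1e-12)


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        Hyperparams(ilr=0.0)
    with pytest.raises(ValueError):
        Hyperparams(d=0.0)
    with pytest.raises(ValueError):
        Hyperparams(dropout=1.5)
    assert Hyperparams(dropout=0.0).keep_prob == 1.0
    assert Hyperparams(dropout=0.7).keep_prob == 0.7
    assert Hyperparams(dropout=0.7, dropout_is_keep=False).keep_prob == pytest.approx(0.3)


def test_network_params_json_round_trip():
    p = hand_params()
    q = NetworkParams.from_dict(p.to_dict())
    assert np.array_equal(p.W1, q.W1) and np.array_equal(p.b2, q.b2)
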