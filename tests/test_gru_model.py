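"""GRU recurrence, softmax head, loss, gradients and fitting."""

import math

import numpy as np
import pytest

from fediowa.data_model import ValidationError, encode_sequence, stack_encoded
from fediowa.gru_choice_model import (
    PARAM_NAMES,
    ModelParams,
    TrainSchedule,
    fit,
    gru_step,
    init_params,
    loss_and_grads,
    nll_loss,
    predict_probs,
    zero_params,
)
from conftest import make_record


def scalar_oracle_step(params, x, h_prev):
    """Element-by-element reference recurrence: explicit loops, no vectorized
    linear algebra, independent of the implementation under test."""
    N_u = len(h_prev)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = [0.0] * N_u
    for i in range(N_u):
        sz = params.b_z[i] + sum(params.W_z[i, j] * x[j] for j in range(len(x)))
        sz += sum(params.U_z[i, j] * h_prev[j] for j in range(N_u))
        z = sig(sz)
        sr = params.b_r[i] + sum(params.W_r[i, j] * x[j] for j in range(len(x)))
        sr += sum(params.U_r[i, j] * h_prev[j] for j in range(N_u))
        r = sig(sr)
        k = params.b_hU[i] + sum(params.U[i, j] * h_prev[j] for j in range(N_u))
        a = params.b_hW[i] + sum(params.W[i, j] * x[j] for j in range(len(x))) + r * k
        hbar = math.tanh(a)
        h[i] = z * h_prev[i] + (1 - z) * hbar
    return np.array(h)


class TestInit:
    def test_shapes(self):
        p = init_params(10, 4, seed=0)
        assert p.W_z.shape == (10, 6)
        assert p.U.shape == (10, 10)
        assert p.V.shape == (10, 4)
        assert all(getattr(p, b).shape == (10,) for b in ("b_z", "b_r", "b_hW", "b_hU"))

    def test_same_seed_identical(self):
        a, b = init_params(5, seed=3), init_params(5, seed=3)
        for n in PARAM_NAMES:
            np.testing.assert_array_equal(getattr(a, n), getattr(b, n))

    def test_weight_scale_and_zero_biases(self):
        p = init_params(16, seed=1)
        assert np.abs(p.W_z).max() <= 1 / 4
        assert (p.b_z == 0).all() and (p.b_hU == 0).all()

    def test_bad_shapes_rejected(self):
        p = init_params(3, seed=0)
        with pytest.raises(ValidationError):
            ModelParams(**{**p.arrays(), "U": np.zeros((3, 4))})

    def test_save_load_roundtrip(self, tmp_path):
        p = init_params(4, seed=2)
        p.save(tmp_path / "ckpt")
        q = ModelParams.load(tmp_path / "ckpt")
        for n in PARAM_NAMES:
            np.testing.assert_array_equal(getattr(p, n), getattr(q, n))


class TestGruStep:
    def test_zero_params_give_zero_state(self):
        # z = r = sigmoid(0) = 0.5, hbar = tanh(0) = 0, h = 0.5*0 + 0.5*0 = 0
        p = zero_params(3)
        h = gru_step(p, np.ones(6), np.zeros(3))
        np.testing.assert_array_equal(h, np.zeros(3))

    def test_saturated_update_gate_keeps_old_state(self):
        # b_z -> +inf drives z -> 1; the update gate multiplies the OLD state
        p = init_params(4, seed=0)
        p.b_z[...] = 50.0
        h_prev = np.array([0.3, -0.2, 0.7, 0.0])
        h = gru_step(p, np.ones(6), h_prev)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    def test_matches_scalar_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            N_u = int(rng.integers(1, 8))
            p = init_params(N_u, seed=int(rng.integers(1 << 30)))
            for n in PARAM_NAMES:
                getattr(p, n)[...] = rng.normal(0, 1, getattr(p, n).shape)
            x = rng.normal(0, 1, 6)
            h_prev = rng.normal(0, 1, N_u)
            np.testing.assert_allclose(
                gru_step(p, x, h_prev), scalar_oracle_step(p, x, h_prev), atol=1e-8
            )

    def test_single_unit_hand_value(self):
        # N_u = 1, every weight 0.5, x = e_1, h_prev = 0: hand-computed state
        p = zero_params(1)
        for n in ("W_z", "W_r", "W", "U_z", "U_r", "U", "b_z", "b_r", "b_hW", "b_hU", "V"):
            getattr(p, n)[...] = 0.5
        x = np.array([1.0, 0, 0, 0, 0, 0])
        z = r = 1 / (1 + math.exp(-1.0))  # sigmoid(0.5*1 + 0.5)
        hbar = math.tanh(0.5 + 0.5 + r * 0.5)
        expected = (1 - z) * hbar
        np.testing.assert_allclose(gru_step(p, x, np.zeros(1)), [expected], atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = init_params(3, seed=0)
        with pytest.raises(ValidationError):
            gru_step(p, np.ones(5), np.zeros(3))


class TestPredict:
    def test_zero_head_gives_chance_probabilities(self):
        p = init_params(6, seed=1)
        p.V[...] = 0.0
        enc = encode_sequence(make_record(choices=(1, 2, 3, 4, 2)))
        probs = predict_probs(p, enc)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_probabilities_normalized(self):
        p = init_params(8, seed=5)
        probs = predict_probs(p, encode_sequence(make_record(choices=(2, 4, 1))))
        assert ((probs > 0) & (probs < 1)).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_logit_shift_invariance(self):
        p = init_params(4, seed=2)
        enc = encode_sequence(make_record(choices=(1, 3)))
        base = predict_probs(p, enc)
        p.V[...] += 7.0  # adds h.1*7 = same constant to all four logits per trial
        np.testing.assert_allclose(predict_probs(p, enc), base, atol=1e-9)

    def test_batch_padding_independence(self):
        p = init_params(5, seed=3)
        enc = encode_sequence(make_record(choices=(1, 2, 3)))
        other = encode_sequence(make_record(choices=(4, 4, 4)))
        from fediowa.gru_choice_model import predict_probs_batch

        X, _ = stack_encoded([enc, other])
        batch = predict_probs_batch(p, X)
        np.testing.assert_allclose(batch[0], predict_probs(p, enc), atol=1e-12)


class TestLoss:
    def test_one_hot_predictions_have_zero_loss(self):
        Y = np.zeros((1, 3, 4))
        Y[0, :, 1] = 1.0
        assert nll_loss(Y, Y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_closed_form(self):
        S, T = 5, 7
        P = np.full((S, T, 4), 0.25)
        Y = np.zeros((S, T, 4))
        Y[..., 2] = 1.0
        assert nll_loss(P, Y) == pytest.approx(S * T * math.log(4))

    def test_hand_arithmetic_two_trials(self):
        P = np.array([[[0.5, 0.3, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]])
        Y = np.zeros((1, 2, 4))
        Y[0, 0, 0] = 1.0
        Y[0, 1, 1] = 1.0
        assert nll_loss(P, Y) == pytest.approx(-(math.log(0.5) + math.log(0.25)))

    def test_zero_probability_is_floored(self):
        P = np.zeros((1, 1, 4))
        Y = np.zeros((1, 1, 4))
        Y[0, 0, 0] = 1.0
        assert np.isfinite(nll_loss(P, Y))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        rng = np.random.default_rng(0)
        rec = make_record(
            choices=rng.integers(1, 5, 3),
            rewards=rng.uniform(0, 100, 3),
            losses=rng.uniform(0, 100, 3),
        )
        X, Y = stack_encoded([encode_sequence(rec)])
        p = init_params(2, seed=1)
        _, g = loss_and_grads(p, X, Y)
        eps = 1e-5
        for n in PARAM_NAMES:
            arr = getattr(p, n)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                lp, _ = loss_and_grads(p, X, Y)
                arr[i] = orig - eps
                lm, _ = loss_and_grads(p, X, Y)
                arr[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(g[n][i]), 1e-8)
                assert abs(fd - g[n][i]) / denom <= 1e-4, f"{n}[{i}]"


class TestFit:
    def _batch(self, n=20, seed=0):
        # deterministic always-switch-cycle agents: A,B,C,D,A,B,... offset per subject
        encs = []
        for s in range(n):
            choices = [(t + s) % 4 + 1 for t in range(20)]
            encs.append(encode_sequence(make_record(f"s{s}", 1, choices)))
        return encs

    def test_zero_learning_rate_is_identity(self):
        p = init_params(4, seed=0)
        res = fit(p, self._batch(4), TrainSchedule(epochs=3, learn_rate=0.0, seed=1))
        for n in PARAM_NAMES:
            np.testing.assert_array_equal(getattr(res.params, n), getattr(p, n))
        assert len(set(np.round(res.train_loss_history, 9))) == 1

    def test_loss_descends_on_learnable_data(self):
        res = fit(
            init_params(6, seed=2),
            self._batch(20),
            TrainSchedule(epochs=200, batch_size=None, learn_rate=0.02, seed=3),
        )
        assert res.train_loss_history[-1] < res.train_loss_history[0]
        # the cyclic rule is fully predictable: loss should get close to zero
        assert res.train_loss_history[-1] < 0.1 * res.train_loss_history[0]

    def test_seeded_rerun_is_bitwise_identical(self):
        batch = self._batch(10)
        a = fit(init_params(4, seed=5), batch, TrainSchedule(epochs=10, batch_size=4, seed=7))
        b = fit(init_params(4, seed=5), batch, TrainSchedule(epochs=10, batch_size=4, seed=7))
        assert a.train_loss_history == b.train_loss_history
        for n in PARAM_NAMES:
            np.testing.assert_array_equal(getattr(a.params, n), getattr(b.params, n))

    def test_exposure_counts_one_per_epoch(self):
        res = fit(
            init_params(3, seed=0),
            self._batch(7),
            TrainSchedule(epochs=13, batch_size=3, seed=0),
        )
        assert set(res.exposures.values()) == {13}

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            fit(init_params(3, seed=0), [], TrainSchedule(epochs=1))
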