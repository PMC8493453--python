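"""Classifier families: exact LSTM cell arithmetic, attention identities,
architecture wiring, gradient checks, the training loop and its
plateau learning-rate rule."""

import dataclasses

import numpy as np
import pytest

from scentnlp import classifiers as C
from scentnlp.autodiff import Tensor
from scentnlp.embeddings import EmbeddingMatrix
from scentnlp.labels import severe_argmax
from scentnlp.nn import AttentionPool, LSTMLayer, lstm_cell
from tests.conftest import finite_difference, relative_error

RNG = np.random.default_rng(3)


def tiny_embeddings(vocab=40, dim=8, seed=0):
    rng = np.random.default_rng(seed)
    return EmbeddingMatrix(
        words=[f"w{i}" for i in range(vocab)], vectors=rng.normal(0, 0.3, size=(vocab, dim))
    )


# ------------------------------------------------------------ lstm_step


class TestLSTMStep:
    def test_zero_parameters_give_half_gates(self):
        state = C.LSTMState(h=np.zeros(4), c=np.full(4, 0.8))
        params = C.LSTMParams(weight=np.zeros((8, 16)), bias=np.zeros(16))
        out = C.lstm_step(state, np.zeros(4), params)
        assert np.allclose(out.f, 0.5) and np.allclose(out.i, 0.5) and np.allclose(out.o, 0.5)
        assert np.allclose(out.g, 0.0)
        assert np.allclose(out.c, 0.5 * 0.8)
        assert np.allclose(out.h, 0.5 * np.tanh(0.5 * 0.8))

    def test_saturated_forget_preserves_memory(self):
        units = 3
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 40.0  # forget gate ~ 1
        bias[:units] = -40.0  # input gate ~ 0
        params = C.LSTMParams(weight=np.zeros((6, 12)), bias=bias)
        state = C.LSTMState(h=np.zeros(units), c=np.array([0.3, -0.5, 1.2]))
        out = C.lstm_step(state, np.zeros(units), params)
        assert np.allclose(out.c, state.c, atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        units, n_in = 3, 2
        w = RNG.normal(size=(units + n_in, 4 * units))
        b = RNG.normal(size=4 * units)
        h0 = RNG.normal(size=units)
        c0 = RNG.normal(size=units)
        x = RNG.normal(size=n_in)
        out = C.lstm_step(C.LSTMState(h=h0, c=c0), x, C.LSTMParams(w, b))

        def sig(v):
            return 1 / (1 + np.exp(-v))

        hx = np.concatenate([h0, x])
        for u in range(units):  # scalar re-derivation, one unit at a time
            zi = sum(hx[k] * w[k, u] for k in range(units + n_in)) + b[u]
            zf = sum(hx[k] * w[k, units + u] for k in range(units + n_in)) + b[units + u]
            zg = sum(hx[k] * w[k, 2 * units + u] for k in range(units + n_in)) + b[2 * units + u]
            zo = sum(hx[k] * w[k, 3 * units + u] for k in range(units + n_in)) + b[3 * units + u]
            c_u = sig(zf) * c0[u] + sig(zi) * np.tanh(zg)
            h_u = sig(zo) * np.tanh(c_u)
            assert abs(out.c[u] - c_u) < 1e-10
            assert abs(out.h[u] - h_u) < 1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            C.lstm_step(
                C.LSTMState(h=np.zeros(3), c=np.zeros(3)),
                np.zeros(2),
                C.LSTMParams(np.zeros((4, 12)), np.zeros(12)),
            )

    def test_layer_forward_equals_repeated_steps(self):
        rng = np.random.default_rng(5)
        layer = LSTMLayer(4, 3, rng)
        x = rng.normal(size=(2, 6, 4))
        out = layer(Tensor(x, requires_grad=False)).data
        state = C.LSTMState(h=np.zeros((2, 3)), c=np.zeros((2, 3)))
        params = C.LSTMParams(layer.weight.data, layer.bias.data)
        for t in range(6):
            state = C.lstm_step(state, x[:, t], params)
            assert np.allclose(out[:, t], state.h, atol=1e-12)


# ------------------------------------------------------- attention ops


class TestAttentionPool:
    def test_identical_states_give_uniform_weights(self):
        h = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        v, alpha = C.attention_pool(h, np.eye(3), np.zeros(3), np.ones(3))
        assert np.allclose(alpha, 0.2)
        assert np.allclose(v, h[0])

    def test_dominant_score_saturates_to_one_hot(self):
        h = np.eye(3) * 5.0
        v, alpha = C.attention_pool(h, np.eye(3), np.zeros(3), np.array([50.0, 0, 0]))
        assert alpha[0] > 0.99
        assert np.allclose(v, h[0], atol=0.1)

    def test_three_state_numeric_case_matches_brute_force(self):
        h = RNG.normal(size=(3, 4))
        w = RNG.normal(size=(4, 2))
        b = RNG.normal(size=2)
        ctx = RNG.normal(size=2)
        v, alpha = C.attention_pool(h, w, b, ctx)
        scores = np.array([np.tanh(h[i] @ w + b) @ ctx for i in range(3)])
        expected_alpha = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(alpha, expected_alpha, atol=1e-12)
        assert np.allclose(v, sum(expected_alpha[i] * h[i] for i in range(3)), atol=1e-12)
        assert alpha.sum() == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            C.attention_pool(np.zeros((0, 3)), np.eye(3), np.zeros(3), np.ones(3))


class TestScaledDotAttention:
    def test_zero_query_returns_value_mean(self):
        k = RNG.normal(size=(5, 4))
        v = RNG.normal(size=(5, 3))
        out = C.scaled_dot_attention(np.zeros((2, 4)), k, v)
        assert np.allclose(out, v.mean(axis=0))

    def test_single_key_value(self):
        out = C.scaled_dot_attention(RNG.normal(size=(3, 4)), RNG.normal(size=(1, 4)),
                                     np.array([[7.0, -1.0]]))
        assert np.allclose(out, [7.0, -1.0])

    def test_two_by_two_hand_case(self):
        q = np.array([[1.0], [0.0]])
        k = np.array([[1.0], [2.0]])
        v = np.array([[10.0], [20.0]])
        out, w = C.scaled_dot_attention(q, k, v, return_weights=True)
        e = np.exp([1.0, 2.0])
        expected_row0 = (e[0] * 10 + e[1] * 20) / e.sum()
        assert out[0, 0] == pytest.approx(expected_row0)
        assert out[1, 0] == pytest.approx(15.0)
        assert np.allclose(w.sum(axis=-1), 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            C.scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))


# ----------------------------------------------------- gradient checks


class TestGradientChecks:
    def test_attention_pool_parameters(self):
        rng = np.random.default_rng(11)
        pool = AttentionPool(4, 3, rng)
        hidden = Tensor(rng.normal(size=(2, 5, 4)), requires_grad=False)
        loss = (pool(hidden) ** 2.0).sum()
        loss.backward()
        for p in (pool.proj.weight, pool.proj.bias, pool.context):
            fd = finite_difference(
                lambda: float((pool(hidden) ** 2.0).sum().data), p.data
            )
            assert relative_error(p.grad, fd) < 1e-4

    def test_lstm_cell_parameters(self):
        rng = np.random.default_rng(12)
        layer = LSTMLayer(3, 2, rng)
        x = Tensor(rng.normal(size=(2, 4, 3)), requires_grad=False)
        loss = (layer(x) ** 2.0).sum()
        loss.backward()
        for p in (layer.weight, layer.bias):
            fd = finite_difference(lambda: float((layer(x) ** 2.0).sum().data), p.data)
            assert relative_error(p.grad, fd) < 1e-4


# --------------------------------------------------------- architectures


class TestBuildCNN:
    def test_paper_scale_stem_width(self):
        cfg = C.CNNConfig()  # full-scale reference values
        assert cfg.channels == 250 and cfg.block_repeats == 6

    def test_forward_shape_and_row_sums(self):
        cfg = C.CNNConfig(channels=6, block_repeats=1, max_len=32)
        model = C.build_cnn(cfg, embeddings=tiny_embeddings(), seed=0)
        ids = [[1, 2, 3, 4, 5] * 3, [6, 7, 8]]
        probs = C.predict_proba(model, ids)
        assert probs.shape == (2, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_fixed_pretrained_embeddings_do_not_move(self):
        emb = tiny_embeddings()
        cfg = C.CNNConfig(channels=4, block_repeats=1, embedding_mode="fixed_pretrained")
        model = C.build_cnn(cfg, embeddings=emb, seed=0)
        before = model.embedding.table.data.copy()
        ids = [[1, 2, 3, 4, 5, 6]] * 8
        labels = [0, 1, 2, 0, 1, 2, 0, 1]
        C.train_classifier(
            model, (ids, labels), (ids[:2], labels[:2]),
            C.TrainConfig(epochs=1, batch_size=4, learning_rate=0.1, seed=0),
        )
        assert np.array_equal(model.embedding.table.data, before)

    def test_trainable_pretrained_embeddings_do_move(self):
        emb = tiny_embeddings()
        cfg = C.CNNConfig(channels=4, block_repeats=1, embedding_mode="trainable_pretrained")
        model = C.build_cnn(cfg, embeddings=emb, seed=0)
        before = model.embedding.table.data.copy()
        ids = [[1, 2, 3, 4, 5, 6]] * 8
        labels = [0, 1, 2, 0, 1, 2, 0, 1]
        C.train_classifier(
            model, (ids, labels), (ids[:2], labels[:2]),
            C.TrainConfig(epochs=1, batch_size=4, learning_rate=0.1, seed=0),
        )
        assert not np.array_equal(model.embedding.table.data, before)

    def test_short_sequence_padded_not_crashed(self):
        cfg = C.CNNConfig(channels=4, block_repeats=3, max_len=32)
        model = C.build_cnn(cfg, embeddings=tiny_embeddings(), seed=0)
        probs = C.predict_proba(model, [[3]])
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestBuildLSTM:
    def test_paper_scale_widths(self):
        assert C.LSTMConfig().units == 650
        bi = C.LSTMConfig(units=310, bidirectional=True)
        model = C.build_lstm(
            dataclasses.replace(bi, layers=2, shortcuts=()), embeddings=tiny_embeddings()
        )
        probs = C.predict_proba(model, [[1, 2, 3]])
        assert probs.shape == (1, 3)  # concatenated width 620 internally

    def test_shortcuts_change_forward_output(self):
        emb = tiny_embeddings()
        with_sc = C.build_lstm(
            C.LSTMConfig(layers=3, units=5, shortcuts=((1, 3),), dropout=0.0),
            embeddings=emb, seed=4,
        )
        without_sc = C.build_lstm(
            C.LSTMConfig(layers=3, units=5, shortcuts=(), dropout=0.0),
            embeddings=emb, seed=4,
        )
        ids = [[1, 2, 3, 4, 5, 6, 7]]
        p1 = C.predict_proba(with_sc, ids)
        p2 = C.predict_proba(without_sc, ids)
        assert not np.allclose(p1, p2)

    def test_invalid_shortcut_rejected(self):
        with pytest.raises(ValueError, match="shortcut"):
            C.LSTMConfig(layers=2, shortcuts=((1, 3),)).validate()

    def test_bidirectional_output_independent_of_batch_padding(self):
        model = C.build_lstm(
            C.LSTMConfig(layers=2, units=4, bidirectional=True, shortcuts=(), dropout=0.0),
            embeddings=tiny_embeddings(), seed=1,
        )
        short = [[5, 6, 7]]
        padded_batch = [[5, 6, 7], list(range(1, 20))]
        assert np.allclose(
            C.predict_proba(model, short)[0], C.predict_proba(model, padded_batch)[0],
            atol=1e-9,
        )


class TestBuildTransformer:
    def test_dim_head_invariant(self):
        cfg = C.TransformerConfig(layers=1, heads=4, dim=32, d_ff=64)
        assert cfg.d_k == 8
        with pytest.raises(ValueError):
            C.TransformerConfig(layers=1, heads=5, dim=32, d_ff=64).validate()

    def test_masked_pad_positions_do_not_change_logits(self):
        cfg = C.TransformerConfig(layers=2, heads=2, dim=16, d_ff=32, dropout=0.0, max_len=32)
        model = C.build_transformer(cfg, vocab_size=30, seed=0)
        model.eval()
        ids = np.array([[2, 5, 6, 7, 3, 0, 0, 0]])  # CLS ... SEP PAD PAD PAD
        mask = ids != 0
        logits1 = model.forward(ids, mask).data
        ids2 = ids.copy()
        ids2[0, 5:] = 9  # rewrite pad content
        logits2 = model.forward(ids2, mask).data
        assert np.allclose(logits1, logits2, atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        from scentnlp.autodiff import softmax as t_softmax
        from scentnlp.nn import MultiHeadSelfAttention

        rng = np.random.default_rng(0)
        mha = MultiHeadSelfAttention(8, 2, rng)
        x = Tensor(rng.normal(size=(2, 5, 8)), requires_grad=False)
        q = mha.wq(x).reshape(2, 5, 2, 4).transpose(0, 2, 1, 3)
        k = mha.wk(x).reshape(2, 5, 2, 4).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1 / 2.0)
        attn = t_softmax(scores, axis=-1)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)


# -------------------------------------------------------- training loop


class TestPlateauSchedule:
    def test_no_improvement_multiplies_by_factor(self):
        lrs = C.plateau_lr_schedule([1.0, 1.1], 1e-3, factor=0.7)
        assert lrs == [1e-3, pytest.approx(0.7e-3)]

    def test_strict_improvement_keeps_rate(self):
        lrs = C.plateau_lr_schedule([1.0, 0.9, 0.5, 0.2], 1e-3, factor=0.7)
        assert lrs == [1e-3] * 4

    def test_scripted_sequence_exact_trace(self):
        # plateau at epochs 2,3 then recovery then plateau again
        losses = [1.0, 1.0, 1.2, 0.8, 0.9]
        lrs = C.plateau_lr_schedule(losses, 1.0, factor=0.7, patience=1)
        assert lrs == [1.0, 0.7, pytest.approx(0.49), pytest.approx(0.49), pytest.approx(0.343)]


class TestTrainClassifier:
    def _toy_data(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        ids, labels = [], []
        for _ in range(n):
            lab = int(rng.integers(0, 3))
            marker = [10 + lab] * 3  # class-revealing token
            filler = list(rng.integers(20, 39, size=5))
            ids.append(filler[:2] + marker + filler[2:])
            labels.append(lab)
        return ids, labels

    def test_training_reduces_loss(self):
        ids, labels = self._toy_data()
        model = C.build_cnn(
            C.CNNConfig(channels=6, block_repeats=1, dropout=0.0), embeddings=tiny_embeddings(),
            seed=0,
        )
        hist = C.train_classifier(
            model, (ids, labels), (ids, labels),
            C.TrainConfig(epochs=8, batch_size=8, learning_rate=5e-3, seed=0),
        )
        assert hist.epochs[-1]["train_loss"] < hist.epochs[0]["train_loss"]

    def test_history_applies_decay_rule_exactly(self):
        ids, labels = self._toy_data()
        model = C.build_cnn(
            C.CNNConfig(channels=4, block_repeats=1), embeddings=tiny_embeddings(), seed=0
        )
        tc = C.TrainConfig(epochs=5, batch_size=8, learning_rate=1e-3, seed=0)
        hist = C.train_classifier(model, (ids, labels), (ids, labels), tc)
        val = [e["val_loss"] for e in hist.epochs]
        expected = C.plateau_lr_schedule(val, 1e-3, factor=0.7, patience=1)
        assert [e["lr"] for e in hist.epochs] == pytest.approx(expected)

    @pytest.mark.parametrize("arch", ["cnn", "lstm", "transformer"])
    def test_overfits_small_separable_set(self, arch):
        ids, labels = self._toy_data(n=32, seed=1)
        emb = tiny_embeddings(vocab=40, dim=8)
        if arch == "cnn":
            model = C.build_cnn(
                C.CNNConfig(channels=8, block_repeats=1, dropout=0.0), embeddings=emb, seed=1
            )
            tc = C.TrainConfig(epochs=25, batch_size=8, learning_rate=5e-3, seed=1)
        elif arch == "lstm":
            model = C.build_lstm(
                C.LSTMConfig(layers=1, units=12, shortcuts=(), dropout=0.0),
                embeddings=emb, seed=1,
            )
            tc = C.TrainConfig(epochs=25, batch_size=8, learning_rate=1e-2, seed=1)
        else:
            model = C.build_transformer(
                C.TransformerConfig(layers=1, heads=2, dim=16, d_ff=32, dropout=0.0,
                                    max_len=16),
                vocab_size=40, seed=1,
            )
            tc = C.TrainConfig(epochs=50, batch_size=8, learning_rate=2e-3,
                               decay_factor=None, seed=1)
        C.train_classifier(model, (ids, labels), (ids, labels), tc)
        # at most 200 optimization steps (4 batches x <=50 epochs)
        acc = np.mean(severe_argmax(C.predict_proba(model, ids)) == np.array(labels))
        assert acc >= 0.99

    def test_deterministic_under_seed(self):
        ids, labels = self._toy_data()
        outs = []
        for _ in range(2):
            model = C.build_lstm(
                C.LSTMConfig(layers=1, units=6, shortcuts=(), dropout=0.2),
                embeddings=tiny_embeddings(), seed=2,
            )
            C.train_classifier(
                model, (ids, labels), (ids[:8], labels[:8]),
                C.TrainConfig(epochs=2, batch_size=8, learning_rate=1e-3, seed=2),
            )
            outs.append(C.predict_proba(model, ids))
        assert np.array_equal(outs[0], outs[1])


@pytest.fixture(scope="module")
def model():
    return C.build_cnn(
        C.CNNConfig(channels=4, block_repeats=1), embeddings=tiny_embeddings(), seed=0
    )


class TestPredictProba:
    def test_rows_sum_to_one_and_duplicates_identical(self, model):
        ids = [[1, 2, 3], [4, 5, 6, 7], [1, 2, 3]]
        probs = C.predict_proba(model, ids)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(probs[0], probs[2], atol=1e-12)

    def test_permuting_batch_permutes_rows(self, model):
        rng = np.random.default_rng(0)
        ids = [list(rng.integers(1, 39, size=rng.integers(2, 12))) for _ in range(9)]
        probs = C.predict_proba(model, ids)
        perm = rng.permutation(9)
        probs_perm = C.predict_proba(model, [ids[i] for i in perm])
        assert np.allclose(probs_perm, probs[perm], atol=1e-9)

    def test_empty_document_gets_uniform_fallback(self, model):
        probs = C.predict_proba(model, [[], [1, 2, 3]])
        assert np.allclose(probs[0], 1 / 3)
        assert np.allclose(probs[1].sum(), 1.0)
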