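"""Modality Q-former: fixed-size output contract, the three alignment losses
against closed forms and direct arithmetic oracles, and negative mining."""

import math

import numpy as np
import pytest

from varfuse._tensor import Tensor
from varfuse.qformer import (
    QFormer,
    QFormerConfig,
    binary_match_loss,
    causal_lm_loss,
    mine_hard_negatives,
    stage1_total_loss,
)


def tiny_model(input_dim=6, num_queries=4, vocab=16, seed=0, **kw):
    cfg = QFormerConfig(input_dim=input_dim, num_layers=2, hidden_dim=16,
                        num_heads=2, num_queries=num_queries, vocab_size=vocab,
                        max_text_len=600, proj_dim=8, **kw)
    return QFormer(cfg, np.random.default_rng(seed))


class TestEncode:
    @pytest.mark.parametrize("length", [1, 16, 512])
    def test_output_size_invariant_to_input_length(self, length):
        model = tiny_model()
        rng = np.random.default_rng(length)
        out = model.encode(rng.normal(size=(2, length, 6)))
        assert out.shape == (2, 4, 16)

    def test_paper_scale_sequence_config_emits_32_tokens(self):
        cfg = QFormerConfig(input_dim=8)  # defaults: 12 layers, d=128, K=32
        model = QFormer(cfg, np.random.default_rng(0))
        out = model.encode(np.random.default_rng(1).normal(size=(1, 10, 8)))
        assert out.shape == (1, 32, 128)
        # cross-attention present at even-indexed layers only
        assert [blk.has_cross for blk in model.blocks] == [i % 2 == 0 for i in range(12)]

    def test_forward_deterministic(self):
        model = tiny_model()
        x = np.random.default_rng(2).normal(size=(3, 7, 6))
        assert np.array_equal(model.encode(x).data, model.encode(x).data)

    def test_dimension_mismatch_names_dims(self):
        with pytest.raises(ValueError, match="expected 6.*got 5"):
            tiny_model().encode(np.zeros((1, 3, 5)))

    def test_raw_inputs_never_receive_gradient(self):
        model = tiny_model()
        emb = Tensor(np.random.default_rng(0).normal(size=(2, 5, 6)))
        ids = np.array([[1, 4, 5, 2], [1, 6, 7, 2]])
        qtok = model.encode(emb)
        _, pooled = model.encode_text(ids)
        loss = model.itc_loss(qtok, pooled) + model.itg_loss(qtok, ids)
        loss.backward()
        assert emb.grad is None  # precomputed embeddings are constants
        assert model.queries.grad is not None


class TestITC:
    def test_single_item_batch_gives_zero(self):
        model = tiny_model()
        qtok = model.encode(np.random.default_rng(0).normal(size=(1, 5, 6)))
        _, pooled = model.encode_text(np.array([[1, 5, 2]]))
        assert model.itc_loss(qtok, pooled).item() == pytest.approx(0.0, abs=1e-6)

    def test_identical_pairs_give_log_batch_size(self):
        model = tiny_model()
        b = 5
        emb = np.tile(np.random.default_rng(0).normal(size=(1, 5, 6)), (b, 1, 1))
        ids = np.tile(np.array([[1, 5, 2]]), (b, 1))
        qtok = model.encode(emb)
        _, pooled = model.encode_text(ids)
        assert model.itc_loss(qtok, pooled).item() == pytest.approx(math.log(b), abs=1e-6)

    def test_matches_direct_arithmetic_evaluation(self):
        model = tiny_model()
        rng = np.random.default_rng(3)
        qtok = model.encode(rng.normal(size=(2, 4, 6)))
        _, pooled = model.encode_text(np.array([[1, 5, 7, 2], [1, 8, 9, 2]]))
        qhat = model.project_queries(qtok).data
        that = model.project_text(pooled).data
        tau = float(model.tau.item())
        s = np.einsum("ikp,jp->ikj", qhat, that).max(axis=1)  # (B, B)
        logits = s / tau
        expected = 0.0
        for i in range(2):
            row = logits[i] - logits[i].max()
            col = logits[:, i] - logits[:, i].max()
            expected -= 0.5 / 2 * (
                row[i] - math.log(np.exp(row).sum())
                + col[i] - math.log(np.exp(col).sum())
            )
        assert model.itc_loss(qtok, pooled).item() == pytest.approx(expected, abs=1e-5)

    def test_symmetric_in_softmax_directions(self):
        # transposing roles of embeddings and captions leaves the loss unchanged
        model = tiny_model()
        rng = np.random.default_rng(4)
        qtok = model.encode(rng.normal(size=(3, 6, 6)))
        _, pooled = model.encode_text(np.array([[1, 5, 2], [1, 6, 2], [1, 7, 2]]))
        qhat = model.project_queries(qtok).data
        that = model.project_text(pooled).data
        s = np.einsum("ikp,jp->ikj", qhat, that).max(axis=1)
        tau = float(model.tau.item())

        def infonce(m):
            z = m / tau
            z = z - z.max(axis=1, keepdims=True)
            return float(np.mean(-np.diag(z) + np.log(np.exp(z).sum(axis=1))))

        direct = 0.5 * (infonce(s) + infonce(s.T))
        swapped = 0.5 * (infonce(s.T) + infonce(s))
        assert direct == pytest.approx(swapped)
        assert model.itc_loss(qtok, pooled).item() == pytest.approx(direct, abs=1e-5)


class TestHardNegativeMining:
    def test_two_item_batch_has_unique_negative(self):
        s = np.array([[1.0, 0.2], [0.1, 1.0]])
        tneg, eneg = mine_hard_negatives(s, np.random.default_rng(0))
        assert list(tneg) == [1, 0] and list(eneg) == [1, 0]

    def test_dominant_negative_selected_at_softmax_rate(self):
        # row 0: off-diagonal softmax puts >0.99 weight on column 2
        s = np.array([[0.0, -10.0, 10.0, -10.0],
                      [0.0, 0.0, 0.0, 0.0],
                      [0.0, 0.0, 0.0, 0.0],
                      [0.0, 0.0, 0.0, 0.0]])
        rng = np.random.default_rng(1)
        picks = [mine_hard_negatives(s, rng)[0][0] for _ in range(1000)]
        assert np.mean(np.asarray(picks) == 2) > 0.95

    def test_diagonal_never_selected(self):
        rng = np.random.default_rng(2)
        s = np.full((3, 3), 5.0)  # diagonal similarity as large as any other
        for _ in range(1000):
            tneg, eneg = mine_hard_negatives(s, rng)
            assert not np.any(tneg == np.arange(3))
            assert not np.any(eneg == np.arange(3))

    def test_singleton_batch_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no negatives"):
            tneg, eneg = mine_hard_negatives(np.ones((1, 1)), np.random.default_rng(0))
        assert tneg.size == 0 and eneg.size == 0


class TestITM:
    def test_zero_logits_give_ln2(self):
        logits = Tensor(np.zeros((4, 2)))
        loss = binary_match_loss(logits, np.array([1, 0, 1, 0]))
        assert loss.item() == pytest.approx(math.log(2), abs=1e-6)

    def test_saturated_logits_give_negligible_loss(self):
        logits = Tensor(np.array([[-20.0, 20.0], [20.0, -20.0]]))
        loss = binary_match_loss(logits, np.array([1, 0]))
        assert loss.item() < 1e-6

    def test_hand_computed_bce_on_three_pairs(self):
        # match probabilities via logit pairs (0 vs z): p = sigmoid(z)
        z = np.array([[0.0, 1.2], [0.0, -0.4], [0.0, 2.0]])
        labels = np.array([1, 0, 1])
        p = 1 / (1 + np.exp(-(z[:, 1] - z[:, 0])))
        expected = -np.mean(np.where(labels == 1, np.log(p), np.log(1 - p)))
        assert binary_match_loss(Tensor(z), labels).item() == pytest.approx(expected, abs=1e-6)

    def test_model_level_loss_runs_with_mixed_labels(self):
        model = tiny_model()
        qtok = model.encode(np.random.default_rng(0).normal(size=(2, 5, 6)))
        pairs = [(qtok[0:1], [1, 5, 2], 1), (qtok[1:2], [1, 5, 2], 0)]
        assert model.itm_loss(pairs).item() > 0.0

    def test_all_one_class_batch_allowed(self):
        model = tiny_model()
        qtok = model.encode(np.random.default_rng(0).normal(size=(1, 5, 6)))
        model.itm_loss([(qtok[0:1], [1, 5, 2], 1)])  # no error


class TestITG:
    def test_uniform_logits_give_log_vocab(self):
        model = tiny_model(vocab=16)
        model.lm_head.weight.data[:] = 0.0
        model.lm_head.bias.data[:] = 0.0
        qtok = model.encode(np.random.default_rng(0).normal(size=(1, 5, 6)))
        loss = model.itg_loss(qtok, np.array([[1, 5, 7, 2]]))
        assert loss.item() == pytest.approx(math.log(16), abs=1e-6)

    def test_near_one_hot_correct_logits_give_near_zero(self):
        ids = np.array([[1, 5, 7, 2]])
        logits = np.full((1, 4, 16), -30.0)
        for t in range(3):
            logits[0, t, ids[0, t + 1]] = 30.0
        loss = causal_lm_loss(Tensor(logits), ids)
        assert loss.item() < 1e-6

    def test_two_token_caption_hand_computed(self):
        ids = np.array([[3, 7]])
        logits = np.zeros((1, 2, 16))
        logits[0, 0, 7] = 1.5
        logits[0, 0, 3] = 0.5
        z = logits[0, 0]
        expected = -(z[7] - np.log(np.exp(z).sum()))
        assert causal_lm_loss(Tensor(logits), ids).item() == pytest.approx(expected, abs=1e-6)

    def test_empty_caption_rejected(self):
        model = tiny_model()
        qtok = model.encode(np.random.default_rng(0).normal(size=(1, 5, 6)))
        with pytest.raises(ValueError, match="at least one transition"):
            model.itg_loss(qtok, np.array([[1]]))


class TestStage1TotalLoss:
    def test_plain_sum_arithmetic(self):
        one = [(Tensor(np.array(1.0)), Tensor(np.array(1.0)), Tensor(np.array(1.0)))]
        assert stage1_total_loss(one).item() == pytest.approx(3.0)
        three = [(Tensor(np.array(1.0)), Tensor(np.array(2.0)), Tensor(np.array(3.0)))] * 3
        assert stage1_total_loss(three).item() == pytest.approx(18.0)

    def test_additivity_on_synthetic_batch(self):
        model = tiny_model()
        rng = np.random.default_rng(6)
        qtok = model.encode(rng.normal(size=(2, 5, 6)))
        ids = np.array([[1, 5, 7, 2], [1, 8, 9, 2]])
        _, pooled = model.encode_text(ids)
        itc = model.itc_loss(qtok, pooled)
        itm = model.itm_loss([(qtok[0:1], list(ids[0]), 1), (qtok[1:2], list(ids[1]), 0)])
        itg = model.itg_loss(qtok, ids)
        total = stage1_total_loss([(itc, itm, itg)])
        assert total.item() == pytest.approx(itc.item() + itm.item() + itg.item(), rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stage1_total_loss([])


def test_config_validates_divisibility():
    with pytest.raises(ValueError, match="divisible"):
        QFormerConfig(input_dim=4, hidden_dim=10, num_heads=4)
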