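"""Multi-head pooling, intersentence attention, fusion, coattention."""

import numpy as np
import pytest

from qdsum.autodiff import Tensor
from qdsum.config import tiny_config
from qdsum.encoder import DocumentEncoding
from qdsum.nn import masked_mean
from qdsum.two_step_attention import (
    Coattention,
    IntersentenceAttention,
    MultiHeadPooling,
    TokenFusion,
    TwoStepAttention,
)


def make_doc(rng, b=1, l_s=2, n_s=4, d=32, mask=None):
    hidden = Tensor(rng.normal(size=(b, l_s, n_s, d)))
    token_mask = np.ones((b, l_s, n_s), dtype=bool) if mask is None else mask
    return DocumentEncoding(hidden, token_mask, token_mask.any(-1))


class TestMultiHeadPooling:
    def test_zero_logits_give_uniform_weights_and_mean_pooling(self, rng):
        config = tiny_config()
        pool = MultiHeadPooling(config, rng)
        pool.score.weight.data[:] = 0.0
        pool.score.bias.data[:] = 0.0
        mask = np.array([[[True, True, True, False], [True, False, False, False]]])
        doc = make_doc(rng, mask=mask)
        heads = pool(doc)
        # uniform over valid tokens, zero on padding
        np.testing.assert_allclose(heads.probs.data[0, :, 0, :3], 1 / 3, atol=1e-12)
        assert np.all(heads.probs.data[0, :, 0, 3] == 0)
        # weighted sum with uniform weights == masked mean of value vectors
        values = heads.values.data
        expected = values[0, :, 0, :3, :].mean(axis=1)
        np.testing.assert_allclose(heads.summed.data[0, :, 0], expected, atol=1e-10)

    def test_singleton_sentence_weight_is_one(self, rng):
        config = tiny_config()
        pool = MultiHeadPooling(config, rng)
        mask = np.array([[[True, False, False, False], [True, True, False, False]]])
        doc = make_doc(rng, mask=mask)
        heads = pool(doc)
        np.testing.assert_allclose(heads.probs.data[0, :, 0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(
            heads.summed.data[0, :, 0], heads.values.data[0, :, 0, 0, :], atol=1e-12
        )

    def test_head_dimension_is_d_over_n_heads(self, rng):
        config = tiny_config()  # d=32, h=2
        pool = MultiHeadPooling(config, rng)
        heads = pool(make_doc(rng))
        assert heads.summed.shape == (1, 2, 2, 16)
        assert heads.pooled.shape == (1, 2, 32)

    def test_probabilities_normalize_within_each_sentence(self, rng):
        config = tiny_config()
        pool = MultiHeadPooling(config, rng)
        mask = np.array([[[True, True, False, False], [True, True, True, True]]])
        heads = pool(make_doc(rng, mask=mask))
        np.testing.assert_allclose(heads.probs.data.sum(-1), 1.0, atol=1e-10)


class TestIntersentenceAttention:
    def test_permutation_equivariance(self, rng):
        config = tiny_config(dropout=0.0)
        attn = IntersentenceAttention(config, rng)
        pooled = Tensor(rng.normal(size=(1, 4, config.d_model)))
        mask = np.ones((1, 4), dtype=bool)
        base = attn(pooled, mask).data
        perm = rng.permutation(4)
        permuted = attn(Tensor(pooled.data[:, perm]), mask).data
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-10)

    def test_identical_sentences_get_equal_context(self, rng):
        config = tiny_config(dropout=0.0)
        attn = IntersentenceAttention(config, rng)
        row = rng.normal(size=config.d_model)
        two = attn(Tensor(np.tile(row, (1, 2, 1))), np.ones((1, 2), dtype=bool)).data
        one = attn(Tensor(row[None, None, :]), np.ones((1, 1), dtype=bool)).data
        np.testing.assert_allclose(two[0, 0], two[0, 1], atol=1e-12)
        np.testing.assert_allclose(two[0, 0], one[0, 0], atol=1e-10)


class TestTokenFusion:
    def test_zero_context_zero_mlp_reduces_to_layer_norm(self, rng):
        config = tiny_config()
        fusion = TokenFusion(config, rng)
        fusion.mlp.w2.weight.data[:] = 0.0
        fusion.mlp.w2.bias.data[:] = 0.0
        doc = make_doc(rng)
        out = fusion(doc.hidden, Tensor(np.zeros((1, 2, config.d_model))))
        expected = fusion.ln(doc.hidden)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_context_broadcasts_to_every_token_of_its_sentence(self, rng):
        config = tiny_config()
        fusion = TokenFusion(config, rng)
        fusion.mlp.w2.weight.data[:] = 0.0
        fusion.mlp.w2.bias.data[:] = 0.0
        hidden = Tensor(np.zeros((1, 2, 3, config.d_model)))
        context = Tensor(rng.normal(size=(1, 2, config.d_model)))
        out = fusion(hidden, context)
        for j in range(1, 3):
            np.testing.assert_allclose(out.data[0, :, j], out.data[0, :, 0], atol=1e-12)

    def test_cross_sentence_information_flow(self, rng):
        """Perturbing sentence 1's tokens must move sentence 0's fused states."""
        config = tiny_config(dropout=0.0)
        two_step = TwoStepAttention(config, rng)
        doc = make_doc(rng, l_s=3, n_s=4)
        v_q = Tensor(rng.normal(size=(1, config.d_model)))
        base, _ = two_step(doc, v_q)
        bumped = DocumentEncoding(
            Tensor(doc.hidden.data + np.eye(1)[0, 0] * (np.arange(3) == 1)[None, :, None, None] * 0.5),
            doc.token_mask, doc.sentence_mask,
        )
        out, _ = two_step(bumped, v_q)
        delta = np.abs(out.hidden.data[0, 0] - base.hidden.data[0, 0]).max()
        assert delta > 1e-6


class TestCoattention:
    def test_identical_sentence_vectors_give_uniform_alpha(self, rng):
        config = tiny_config()
        co = Coattention(config, rng)
        row = rng.normal(size=config.d_model)
        out = co(
            Tensor(rng.normal(size=(1, config.d_model))),
            Tensor(np.tile(row, (1, 3, 1))),
            np.ones((1, 3), dtype=bool),
        )
        np.testing.assert_allclose(out.alpha.data, 1 / 3, atol=1e-12)

    def test_alpha_masked_and_normalized(self, rng):
        config = tiny_config()
        co = Coattention(config, rng)
        mask = np.array([[True, True, False, False]])
        out = co(
            Tensor(rng.normal(size=(1, config.d_model))),
            Tensor(rng.normal(size=(1, 4, config.d_model))),
            mask,
        )
        assert np.all(out.alpha.data[~mask] == 0)
        np.testing.assert_allclose(out.alpha.data.sum(-1), 1.0, atol=1e-10)

    def test_additive_scores_match_hand_computation(self, rng):
        """d=2 oracle: score_i = w . tanh(W1 s_i + W2 v_q), brute force."""
        config = tiny_config(d_model=2, n_heads=1, ffn_dim=4)
        co = Coattention(config, rng)
        w1 = np.array([[0.5, -1.0], [2.0, 0.25]])
        w2 = np.array([[1.5, 0.0], [-0.5, 1.0]])
        w = np.array([[2.0], [-1.0]])
        co.w_sent.weight.data = w1.copy()
        co.w_query.weight.data = w2.copy()
        co.v.weight.data = w.copy()
        sents = np.array([[[0.2, -0.4], [1.0, 0.3]]])
        v_q = np.array([[0.5, -0.1]])
        scores = np.array(
            [float((np.tanh(s @ w1 + v_q[0] @ w2) @ w)[0]) for s in sents[0]]
        )
        expected = np.exp(scores) / np.exp(scores).sum()
        out = co(Tensor(v_q), Tensor(sents), np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(out.alpha.data[0], expected, atol=1e-10)


class TestAblations:
    def test_intersentence_off_bypasses_fusion(self, rng):
        config = tiny_config(intersentence=False)
        two_step = TwoStepAttention(config, rng)
        doc = make_doc(rng)
        fused, _ = two_step(doc, Tensor(rng.normal(size=(1, config.d_model))))
        np.testing.assert_array_equal(fused.hidden.data, doc.hidden.data)

    def test_coattention_off_gives_uniform_alpha_and_question_vector(self, rng):
        config = tiny_config(coattention=False)
        two_step = TwoStepAttention(config, rng)
        mask = np.array([[[True, True, True, True], [True, True, False, False]],
                         [[True, True, True, False], [False, False, False, False]]])
        doc = make_doc(rng, b=2, mask=mask)
        v_q = Tensor(rng.normal(size=(2, config.d_model)))
        _, co = two_step(doc, v_q)
        np.testing.assert_allclose(co.alpha[0], [0.5, 0.5])
        np.testing.assert_allclose(co.alpha[1], [1.0, 0.0])
        np.testing.assert_array_equal(co.fused.data, v_q.data)

    def test_sentence_vectors_are_masked_means(self, rng):
        config = tiny_config(intersentence=False)
        two_step = TwoStepAttention(config, rng)
        mask = np.array([[[True, True, False, False], [True, True, True, True]]])
        doc = make_doc(rng, mask=mask)
        fused, _ = two_step(doc, Tensor(rng.normal(size=(1, config.d_model))))
        expected = masked_mean(doc.hidden, mask, axis=2)
        np.testing.assert_allclose(fused.sentence_vectors.data, expected.data, atol=1e-12)
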