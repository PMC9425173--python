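"""Pointer views: copy distributions, vocabulary softmax, mixture gate."""

import numpy as np
import pytest

from qdsum.autodiff import Tensor
from qdsum.config import tiny_config
from qdsum.model import Summarizer
from qdsum.pointer_network import (
    document_copy_distribution,
    mix_distributions,
    question_copy_distribution,
    vocab_distribution,
)


class TestQuestionCopy:
    def test_scatter_add_merges_repeated_tokens(self):
        # token id 9 sits at question positions 2 and 5 with weights .3 / .2
        beta = np.zeros((1, 1, 1, 6))
        beta[0, 0, 0] = [0.1, 0.2, 0.3, 0.15, 0.05, 0.2]
        ids = np.array([[4, 5, 9, 6, 7, 9]])
        p_q = question_copy_distribution(Tensor(beta), ids, extended_size=12)
        np.testing.assert_allclose(p_q.data[0, 0, 9], 0.5, atol=1e-12)
        np.testing.assert_allclose(p_q.data.sum(-1), 1.0, atol=1e-12)

    def test_head_average_of_identical_heads_is_any_head(self):
        row = np.array([0.25, 0.25, 0.5])
        beta = np.tile(row, (1, 4, 1, 1))
        ids = np.array([[1, 2, 3]])
        p_q = question_copy_distribution(Tensor(beta), ids, extended_size=5)
        np.testing.assert_allclose(p_q.data[0, 0, [1, 2, 3]], row, atol=1e-12)

    def test_support_restricted_to_question_ids(self, rng):
        beta = rng.random((2, 4, 3, 5))
        beta /= beta.sum(-1, keepdims=True)
        ids = np.array([[1, 3, 3, 7, 2], [4, 4, 4, 1, 9]])
        p_q = question_copy_distribution(Tensor(beta), ids, extended_size=11)
        for b in range(2):
            off_support = np.setdiff1d(np.arange(11), ids[b])
            assert np.all(p_q.data[b][:, off_support] == 0)


class TestDocumentCopy:
    def test_global_times_local_product(self):
        # 2 sentences x 2 tokens, alpha=(.75,.25), local weights .5 each
        beta = np.full((1, 1, 1, 4), 0.5)
        alpha = Tensor(np.array([[0.75, 0.25]]))
        ids = np.array([[[5, 6], [7, 8]]])
        p_s = document_copy_distribution(Tensor(beta), alpha, ids, extended_size=10)
        np.testing.assert_allclose(
            p_s.data[0, 0, [5, 6, 7, 8]], [0.375, 0.375, 0.125, 0.125], atol=1e-12
        )

    def test_one_hot_alpha_annihilates_other_sentences(self, rng):
        beta = rng.random((1, 2, 3, 6))
        alpha = Tensor(np.array([[0.0, 1.0, 0.0]]))
        ids = np.array([[[3, 4], [5, 6], [7, 8]]])
        p_s = document_copy_distribution(Tensor(beta), alpha, ids, extended_size=10)
        assert np.all(p_s.data[0][:, [3, 4, 7, 8]] == 0)
        np.testing.assert_allclose(p_s.data.sum(-1), 1.0, atol=1e-12)

    def test_uniform_alpha_reduces_to_local_attention(self, rng):
        beta = rng.random((1, 3, 2, 4))
        local = beta.mean(axis=1)
        local /= local.sum(-1, keepdims=True)
        alpha = np.array([[0.5, 0.5]])  # ndarray form (coattention ablated)
        ids = np.array([[[2, 3], [4, 5]]])
        p_s = document_copy_distribution(Tensor(beta), alpha, ids, extended_size=6)
        np.testing.assert_allclose(
            p_s.data[0, :, [2, 3, 4, 5]].T, local[0], atol=1e-12
        )


class TestVocabularyView:
    def test_zero_output_gives_uniform_distribution(self, rng):
        table = Tensor(rng.normal(size=(7, 4)))
        p_v = vocab_distribution(Tensor(np.zeros((1, 2, 4))), table)
        np.testing.assert_allclose(p_v.data, 1 / 7, atol=1e-12)

    def test_scaling_embeddings_sharpens_distribution(self, rng):
        table = rng.normal(size=(9, 4))
        o = Tensor(rng.normal(size=(1, 1, 4)))
        entropies = []
        for scale in (1.0, 3.0):
            p = vocab_distribution(o, Tensor(table * scale)).data[0, 0]
            entropies.append(-(p * np.log(p)).sum())
        assert entropies[1] <= entropies[0] + 1e-12


class TestMixture:
    def _views(self, rng, v=6, n_oov=2):
        def norm(x):
            return x / x.sum(-1, keepdims=True)

        p_v = Tensor(norm(rng.random((1, 1, v))))
        p_q = Tensor(norm(rng.random((1, 1, v + n_oov))))
        p_s = Tensor(norm(rng.random((1, 1, v + n_oov))))
        return p_v, p_q, p_s

    def test_zero_gate_averages_three_views(self, rng):
        from qdsum.nn import Linear

        gate = Linear(4, 3, rng)
        gate.weight.data[:] = 0.0
        gate.bias.data[:] = 0.0
        p_v, p_q, p_s = self._views(rng)
        final, lam = mix_distributions(Tensor(rng.normal(size=(1, 1, 4))), p_v, p_q, p_s, gate)
        np.testing.assert_allclose(lam.data, 1 / 3, atol=1e-12)
        padded = np.concatenate([p_v.data, np.zeros((1, 1, 2))], axis=-1)
        np.testing.assert_allclose(
            final.data, (padded + p_q.data + p_s.data) / 3, atol=1e-12
        )

    def test_forced_vocabulary_gate_reduces_to_plain_softmax(self, rng):
        from qdsum.nn import Linear

        gate = Linear(4, 3, rng)
        gate.weight.data[:] = 0.0
        gate.bias.data[:] = np.array([50.0, 0.0, 0.0])  # lambda -> (1,0,0)
        p_v, p_q, p_s = self._views(rng)
        final, _ = mix_distributions(Tensor(np.zeros((1, 1, 4))), p_v, p_q, p_s, gate)
        np.testing.assert_allclose(final.data[..., :6], p_v.data, atol=1e-12)
        np.testing.assert_allclose(final.data[..., 6:], 0.0, atol=1e-12)


class TestModelLevel:
    def test_final_distribution_is_proper_and_convex(self, tiny_model, tiny_batch):
        dist = tiny_model(tiny_batch)
        for p in (dist.p_vocab, dist.p_question, dist.p_document, dist.final):
            np.testing.assert_allclose(p.data.sum(-1), 1.0, atol=1e-5)
        assert np.all(dist.mixture.data >= 0)
        np.testing.assert_allclose(dist.mixture.data.sum(-1), 1.0, atol=1e-8)
        v = tiny_model.vocab_size
        recomposed = (
            dist.mixture.data[..., 0:1]
            * np.concatenate(
                [dist.p_vocab.data, np.zeros(dist.p_vocab.data.shape[:-1] + (tiny_batch.n_oov,))],
                axis=-1,
            )
            + dist.mixture.data[..., 1:2] * dist.p_question.data
            + dist.mixture.data[..., 2:3] * dist.p_document.data
        )
        np.testing.assert_allclose(dist.final.data, recomposed, atol=1e-10)

    def test_copy_support_soundness(self, tiny_model, tiny_batch):
        """No probability mass on extended ids absent from this example's source."""
        dist = tiny_model(tiny_batch)
        v = tiny_model.vocab_size
        for b, ex in enumerate(tiny_batch.examples):
            present = set(ex.oov_map.values())
            for ext in range(v, v + tiny_batch.n_oov):
                if ext not in present:
                    assert np.all(dist.final.data[b, :, ext] == 0)

    def test_multiview_off_yields_vocabulary_only(self, tiny_vocab, tiny_batch):
        model = Summarizer(len(tiny_vocab), tiny_config(multiview_pointer=False), seed=2)
        dist = model(tiny_batch)
        np.testing.assert_allclose(dist.final.data[..., : len(tiny_vocab)], dist.p_vocab.data)
        assert np.all(dist.final.data[..., len(tiny_vocab):] == 0)
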