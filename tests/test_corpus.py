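"""BPE vocabulary, PubMedQA reading, and batch construction."""

import json
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdsum.corpus import (
    EOW,
    PAD,
    SPECIAL_TOKENS,
    UNK,
    Limits,
    RawExample,
    Vocabulary,
    build_vocabulary,
    make_batch,
    make_example,
    read_jsonl,
    read_pubmedqa,
    split_sentences,
    write_jsonl,
)


class TestBPE:
    def test_zero_merges_gives_character_vocab(self):
        vocab = build_vocabulary(["ab"], num_merges=0)
        assert vocab.id_to_token[: len(SPECIAL_TOKENS)] == SPECIAL_TOKENS
        assert set(vocab.id_to_token[len(SPECIAL_TOKENS):]) == {"a", "b" + EOW}

    def test_first_merge_matches_brute_force_pair_count(self):
        # brute-force oracle: count symbol pairs of "aaab" (freq 2) directly
        corpus = ["aaab aaab"]
        syms = ["a", "a", "a", "b" + EOW]
        pairs = Counter(zip(syms, syms[1:]))
        for p in pairs:
            pairs[p] *= 2
        expected = max(sorted(pairs), key=lambda p: pairs[p])
        vocab = build_vocabulary(corpus, num_merges=1)
        assert vocab.merges[0] == expected == ("a", "a")

    def test_merge_frequency_ties_break_lexicographically(self):
        # "ab" and "cd" each occur once; ("a","b"+EOW) < ("c","d"+EOW)
        vocab = build_vocabulary(["ab cd"], num_merges=1)
        assert vocab.merges[0] == ("a", "b" + EOW)

    def test_training_is_deterministic_and_serializable(self, tmp_path):
        texts = ["the cat sat on the mat", "the dog sat"]
        v1 = build_vocabulary(texts, num_merges=10)
        v2 = build_vocabulary(texts, num_merges=10)
        v1.save(tmp_path / "a")
        v2.save(tmp_path / "b")
        assert (tmp_path / "a/tokens.txt").read_bytes() == (tmp_path / "b/tokens.txt").read_bytes()
        assert (tmp_path / "a/merges.txt").read_bytes() == (tmp_path / "b/merges.txt").read_bytes()
        reloaded = Vocabulary.load(tmp_path / "a")
        assert reloaded.id_to_token == v1.id_to_token
        assert reloaded.merges == v1.merges

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary(["", "   "], num_merges=2)

    @given(st.lists(st.text(alphabet="abcd", min_size=1, max_size=6), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_encode_decode_identity_on_training_characters(self, words):
        text = " ".join(words)
        vocab = build_vocabulary([text], num_merges=5)
        assert vocab.decode(vocab.encode(text)) == text

    def test_ids_are_contiguous_and_inverse(self):
        vocab = build_vocabulary(["abc abd"], num_merges=3)
        assert [vocab.token_to_id[t] for t in vocab.id_to_token] == list(range(len(vocab)))
        ids = vocab.encode("abc")
        assert vocab.encode(vocab.decode(ids)) == ids


class TestPubMedQA:
    @pytest.fixture
    def pubmedqa_file(self, tmp_path):
        data = {
            "1": {
                "QUESTION": "Does it work?",
                "CONTEXTS": ["First claim. Second claim.", "Third claim."],
                "LONG_ANSWER": "Yes it works.",
                "final_decision": "yes",
            },
            "2": {
                "QUESTION": "Unclear?",
                "CONTEXTS": ["Some context."],
                "LONG_ANSWER": "Maybe.",
                "final_decision": "maybe",
            },
            "3": {
                "QUESTION": "Missing context?",
                "CONTEXTS": [],
                "LONG_ANSWER": "None.",
                "final_decision": "no",
            },
            "4": {"QUESTION": "No fields"},
        }
        path = tmp_path / "pqa.json"
        path.write_text(json.dumps(data))
        return path

    def test_sentence_splitting_and_filtering(self, pubmedqa_file, caplog):
        examples = read_pubmedqa(pubmedqa_file)
        assert len(examples) == 1  # maybe dropped; empty & malformed skipped
        ex = examples[0]
        assert ex.sentences == ["First claim.", "Second claim.", "Third claim."]
        assert ex.label == "yes"
        assert ex.summary == "Yes it works."

    def test_context_entries_are_a_lower_bound_on_sentences(self, tmp_path):
        contexts = [f"Claim {i} a. Claim {i} b." for i in range(9)]
        path = tmp_path / "pqa.json"
        path.write_text(json.dumps({"x": {
            "QUESTION": "Q?", "CONTEXTS": contexts, "LONG_ANSWER": "A.",
            "final_decision": "no"}}))
        (ex,) = read_pubmedqa(path)
        assert len(ex.sentences) >= 9

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("[1, 2, 3]")
        with pytest.raises(ValueError):
            read_pubmedqa(path)

    def test_split_sentences(self):
        assert split_sentences("One. Two? Three!  ") == ["One.", "Two?", "Three!"]


class TestBatching:
    def test_single_example_round_trips(self, tiny_vocab):
        raw = RawExample("w0001 w0002", ["w0003 w0004", "w0005"], "w0001 w0005", "yes")
        ex = make_example(raw, tiny_vocab)
        batch = make_batch([ex], tiny_vocab)
        assert batch.question[0].tolist() == ex.question
        assert batch.sentences[0, 1, 0] == ex.sentences[1][0]
        assert batch.summary_tgt[0, : len(ex.summary)].tolist() == ex.summary_ext

    def test_first_oov_gets_first_extended_slot(self, tiny_vocab):
        raw = RawExample("qoov w0001", ["w0002 soov", "w0003"], "qoov soov", None)
        ex = make_example(raw, tiny_vocab)
        v = len(tiny_vocab)
        assert ex.oov_map == {"qoov": v, "soov": v + 1}  # question scanned first
        assert ex.question[0] == UNK and ex.question_ext[0] == v
        assert ex.summary_ext == [v, v + 1]

    def test_padding_and_masks_partition_positions(self, tiny_vocab):
        a = RawExample("w0001 w0002 w0003", ["w0004"], "w0005", None)
        b = RawExample("w0001 w0002 w0003 w0004 w0005", ["w0006 w0007"], "w0008", None)
        batch = make_batch([a, b], tiny_vocab)
        assert batch.question.shape[1] == 5
        assert batch.question_mask.sum(axis=1).tolist() == [3, 5]
        assert np.all((batch.question != PAD) == batch.question_mask)
        assert np.all((batch.sentences_ext != PAD) == batch.token_mask)
        assert batch.sentence_mask.tolist() == [[True], [True]]

    def test_oov_map_injective_and_covers_source_only_tokens(self, tiny_corpus, tiny_vocab):
        for raw in tiny_corpus:
            ex = make_example(raw, tiny_vocab)
            ids = list(ex.oov_map.values())
            assert len(set(ids)) == len(ids)
            assert all(i >= len(tiny_vocab) for i in ids)
            source_tokens = set(raw.question.split()) | {
                t for s in raw.sentences for t in s.split()
            }
            expected = {t for t in source_tokens if t not in tiny_vocab.token_to_id}
            assert set(ex.oov_map) == expected

    def test_truncation_limits_apply(self, tiny_vocab):
        raw = RawExample(
            " ".join(["w0001"] * 100),
            [" ".join(["w0002"] * 150)] * 30,
            " ".join(["w0003"] * 150),
            None,
        )
        ex = make_example(raw, tiny_vocab, Limits(max_q=60, max_sent_len=100, max_sents=20, max_summary=100))
        assert len(ex.question) == 60
        assert len(ex.sentences) == 20
        assert len(ex.sentences[0]) == 100
        assert len(ex.summary) == 100

    def test_empty_batch_rejected(self, tiny_vocab):
        with pytest.raises(ValueError):
            make_batch([], tiny_vocab)


def test_jsonl_round_trip(tmp_path, tiny_corpus):
    path = tmp_path / "c.jsonl"
    write_jsonl(tiny_corpus, path)
    back = read_jsonl(path)
    assert back == tiny_corpus
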