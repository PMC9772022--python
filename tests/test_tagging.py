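"""BIO codec, feature extraction, and the averaged-perceptron span tagger."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurospan.corpus import Document, SpanAnnotation, tokenize
from neurospan.tagging import (
    LABELS,
    SpanTagger,
    bio_decode,
    bio_encode,
    extract_features,
    predict_spans,
    train_tagger,
)


def spans_of(text, *triples):
    return [SpanAnnotation(s, e, c) for s, e, c in triples]


class TestBioCodec:
    def test_single_token_span(self):
        tokens = tokenize("alexia")
        assert bio_encode(tokens, spans_of("alexia", (0, 6, "UNIGRAM"))) == ["B-UNIGRAM"]

    def test_interior_span(self):
        tokens = tokenize("has double vision")
        labels = bio_encode(tokens, spans_of("", (4, 17, "BIGRAM")))
        assert labels == ["O", "B-BIGRAM", "I-BIGRAM"]

    def test_no_spans_all_o(self):
        assert bio_encode(tokenize("gait was normal"), []) == ["O", "O", "O"]

    def test_overlap_rejected(self):
        tokens = tokenize("aaaa bbbb cccc")
        with pytest.raises(ValueError, match="overlap"):
            bio_encode(tokens, spans_of("", (0, 9, "BIGRAM"), (5, 14, "BIGRAM")))

    def test_misaligned_span_snaps_outward_with_warning(self):
        tokens = tokenize("hyperreflexia present")
        with pytest.warns(UserWarning, match="snapped"):
            labels = bio_encode(tokens, spans_of("", (2, 13, "UNIGRAM")))
        assert labels == ["B-UNIGRAM", "O"]

    def test_stray_inside_repaired_to_begin(self):
        tokens = tokenize("has double vision")
        spans = bio_decode(tokens, ["O", "I-BIGRAM", "I-BIGRAM"])
        assert spans == spans_of("", (4, 17, "BIGRAM"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="labels"):
            bio_decode(tokenize("one two"), ["O"])

    def test_all_o_decodes_empty(self):
        assert bio_decode(tokenize("gait was normal"), ["O", "O", "O"]) == []

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_round_trip_identity(self, data):
        n_tokens = data.draw(st.integers(1, 12))
        text = " ".join(f"tok{i}" for i in range(n_tokens))
        tokens = tokenize(text)
        # draw non-overlapping token-aligned spans
        spans = []
        i = 0
        while i < n_tokens:
            if data.draw(st.booleans()):
                j = min(n_tokens, i + data.draw(st.integers(1, 4)))
                category = data.draw(st.sampled_from(["UNIGRAM", "BIGRAM", "EXTENDED"]))
                spans.append(SpanAnnotation(tokens[i].start, tokens[j - 1].end, category))
                i = j
            else:
                i += 1
        assert bio_decode(tokens, bio_encode(tokens, spans)) == spans


class TestFeatures:
    def test_boundary_padding(self):
        feats = extract_features(tokenize("ataxia"), 0)
        assert sum(1 for f in feats if "=<PAD>" in f and "w[-" in f) == 4

    def test_grade_and_negation_cues(self):
        tokens = tokenize("denies clonus 4+")
        assert "is_negation_cue" in extract_features(tokens, 0)
        assert "is_grade" in extract_features(tokens, 2)
        assert "is_grade" not in extract_features(tokens, 1)

    def test_deterministic_and_bounds(self):
        tokens = tokenize("knee reflexes 4+")
        assert extract_features(tokens, 1) == extract_features(tokens, 1)
        with pytest.raises(IndexError):
            extract_features(tokens, 3)


class TestSpanTagger:
    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SpanTagger().fit([], [])

    def test_degenerate_corpus_memorization(self):
        # every positive span is the literal token "ataxia"
        docs, gold = [], []
        contexts = ["patient has {} today", "exam shows {}", "{} was observed", "note {} again"]
        for i, ctx in enumerate(contexts * 3):
            text = ctx.format("ataxia")
            start = text.index("ataxia")
            docs.append(Document(f"d{i}", text))
            gold.append([SpanAnnotation(start, start + 6, "UNIGRAM")])
        model = SpanTagger(epochs=5, seed=0).fit(docs, gold)
        pred = predict_spans(model, Document("held", "she has ataxia now"))
        assert pred == [SpanAnnotation(8, 14, "UNIGRAM")]
        # training-set memorization
        assert model.predict(docs) == gold

    def test_empty_document_predicts_nothing(self, fixture):
        from neurospan.synthesis import generate_corpus, style_profile

        corpus = generate_corpus(style_profile("omim"), fixture, 30, seed=3)
        model = train_tagger(corpus, epochs=2, seed=3)
        assert model.predict([Document("empty", " ")]) == [[]]

    def test_training_is_deterministic_and_serializes_bit_exactly(self, tmp_path, fixture):
        from neurospan.synthesis import generate_corpus, style_profile

        corpus = generate_corpus(style_profile("omim"), fixture, 40, seed=5)
        docs = [d for d, _ in corpus]
        gold = [s for _, s in corpus]
        paths = []
        for run in range(2):
            model = SpanTagger(epochs=3, seed=5).fit(docs, gold)
            path = tmp_path / f"model{run}.json"
            model.save(path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_serialization_round_trip_preserves_predictions(self, tmp_path, fixture):
        from neurospan.synthesis import generate_corpus, style_profile

        corpus = generate_corpus(style_profile("ehr"), fixture, 40, seed=6)
        held_out = generate_corpus(style_profile("ehr"), fixture, 10, seed=7)
        model = train_tagger(corpus, epochs=3, seed=6)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SpanTagger.load(path)
        docs = [d for d, _ in held_out]
        assert model.predict(docs) == loaded.predict(docs)

    def test_viterbi_never_emits_invalid_bio(self, fixture):
        from neurospan.synthesis import generate_corpus, style_profile

        corpus = generate_corpus(style_profile("ehr"), fixture, 50, seed=8)
        model = train_tagger(corpus, epochs=2, seed=8)
        check = generate_corpus(style_profile("ehr"), fixture, 50, seed=9)
        for doc, _ in check:
            tokens = tokenize(doc.text)
            fids = [
                np.asarray(
                    [
                        model.feature_index_[f]
                        for f in extract_features(tokens, t, model.window)
                        if f in model.feature_index_
                    ],
                    dtype=np.int64,
                )
                for t in range(len(tokens))
            ]
            path = model._viterbi(
                model._emissions(fids, model.feature_weights_),
                model.transition_weights_,
            )
            labels = [model.labels_[i] for i in path]
            prev = "O"
            for label in labels:
                if label.startswith("I-"):
                    assert prev != "O" and prev.split("-", 1)[1] == label.split("-", 1)[1]
                prev = label

    def test_sklearn_params_round_trip(self):
        tagger = SpanTagger(epochs=7, window=3, seed=2)
        params = tagger.get_params()
        assert params == {"epochs": 7, "window": 3, "seed": 2}
        clone = SpanTagger().set_params(**params)
        assert clone.get_params() == params


def test_label_inventory():
    assert LABELS[0] == "O"
    assert len(LABELS) == 15
    assert list(LABELS[1:]) == sorted(LABELS[1:])
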