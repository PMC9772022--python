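"""Phrase embedding, cosine scoring, and lookup-then-vector normalization."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurospan.normalize import (
    ConceptNormalizer,
    WordVectors,
    cosine_similarity,
    embed_phrase,
    make_hash_vectors,
    normalize_span,
)
from neurospan.ontology import LookupTable, normalize_phrase


@pytest.fixture()
def toy_vectors():
    v = WordVectors(2)
    v.add("masked", (1.0, 0.0))
    v.add("face", (0.0, 1.0))
    v.add("ataxia", (-1.0, 0.0))
    return v


class TestEmbedding:
    def test_single_token_is_own_unit_vector(self, toy_vectors):
        assert np.allclose(embed_phrase("masked", toy_vectors), [1.0, 0.0])

    def test_repeated_token_mean_identity(self, toy_vectors):
        assert np.allclose(
            embed_phrase("masked masked", toy_vectors), embed_phrase("masked", toy_vectors)
        )

    def test_two_token_normalized_mean(self, toy_vectors):
        vec = embed_phrase("masked face", toy_vectors)
        assert np.allclose(vec, [math.sqrt(0.5), math.sqrt(0.5)], atol=1e-4)

    def test_all_oov_embeds_to_zero(self, toy_vectors):
        assert not np.any(embed_phrase("lorem ipsum", toy_vectors))


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity(np.array([2.0, 1.0]), np.array([2.0, 1.0])) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 3.0])) == 0.0

    def test_hand_value(self):
        u = np.array([1.0, 0.0])
        v = np.array([1.0, 1.0]) / math.sqrt(2)
        assert cosine_similarity(u, v) == pytest.approx(0.7071, abs=1e-4)

    def test_negative_cosine_clamped_to_zero(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([-1.0, 0.0])) == 0.0

    def test_zero_vector_scores_zero(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            cosine_similarity(np.ones(2), np.ones(3))


class TestHashVectors:
    def test_reproducible_and_unit_norm(self):
        a = make_hash_vectors(["gait", "tremor"], d=16, seed=1)
        b = make_hash_vectors(["tremor", "gait"], d=16, seed=1)
        for token in ("gait", "tremor"):
            assert np.allclose(a.get(token), b.get(token))
            assert np.linalg.norm(a.get(token)) == pytest.approx(1.0, abs=1e-9)

    def test_vocabulary_size_and_dim_guard(self):
        vocab = [f"tok{i}" for i in range(100)]
        assert len(make_hash_vectors(vocab, d=16, seed=1)) == 100
        with pytest.raises(ValueError):
            make_hash_vectors(["a"], d=1, seed=0)

    def test_file_round_trip(self, tmp_path):
        vectors = make_hash_vectors(["gait", "tremor", "weak"], d=8, seed=3)
        path = tmp_path / "vectors.txt"
        vectors.save(path)
        loaded = WordVectors.load(path)
        for token in vectors.tokens():
            assert np.allclose(vectors.get(token), loaded.get(token))


class TestNormalization:
    def test_exact_match_shortcut(self):
        table = LookupTable({"hypomimia": "N1"})
        result = normalize_span("Hypomimia", table)
        assert result.cui == "N1"
        assert result.similarity == 1.0

    def test_vector_fallback_prefers_shared_token(self):
        table = LookupTable({"masked face": "N1", "ataxia": "N2"})
        vectors = make_hash_vectors(["masked", "face", "ataxia"], d=16, seed=0)
        result = normalize_span("masked facies", table, vectors=vectors, threshold=0.1)
        assert result.cui == "N1"
        assert 0.0 < result.similarity < 1.0

    def test_all_oov_below_threshold_is_no_match(self):
        table = LookupTable({"masked face": "N1"})
        vectors = make_hash_vectors(["masked", "face"], d=16, seed=0)
        result = normalize_span("lorem ipsum", table, vectors=vectors, threshold=0.5)
        assert not result.matched
        assert result.cui is None
        assert result.candidates  # best candidate attached

    def test_empty_span_and_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_span("  ", LookupTable({"a": "N1"}))
        with pytest.raises(ValueError, match="empty"):
            ConceptNormalizer().fit(LookupTable({}))

    def test_candidates_ranked_and_bounded(self, fixture):
        vocab = sorted({t for p in fixture.lookup_table.entries for t in p.split()})
        vectors = make_hash_vectors(vocab, d=16, seed=2)
        normalizer = ConceptNormalizer(threshold=0.0, n_candidates=5).fit(
            fixture.lookup_table, ontology=fixture.ontology, vectors=vectors
        )
        result = normalizer.normalize("facial weaknes")  # misspelled, no exact hit
        sims = [sim for _, _, sim in result.candidates]
        assert sims == sorted(sims, reverse=True)
        assert all(0.0 <= s <= 1.0 for s in sims)
        assert len(result.candidates) == 5

    def test_synonym_consistency(self, fixture):
        normalizer = ConceptNormalizer().fit(fixture.lookup_table, ontology=fixture.ontology)
        for concept in fixture.ontology.concepts.values():
            for name in concept.names:
                expected = fixture.lookup_table.entries[normalize_phrase(name)]
                result = normalizer.normalize(name)
                assert result.cui == expected
                assert result.similarity == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_small_oracle_equivalence(self, seed):
        """Top-1 matches a brute-force scan on a random 30-phrase table."""
        rng = np.random.default_rng(seed)
        alphabet = [f"w{i}" for i in range(20)]
        phrases = set()
        while len(phrases) < 30:
            k = int(rng.integers(1, 4))
            phrases.add(" ".join(rng.choice(alphabet, size=k, replace=False)))
        phrases = sorted(phrases)
        table = LookupTable({p: f"C{i:04d}" for i, p in enumerate(phrases)})
        vectors = make_hash_vectors(alphabet, d=16, seed=7)
        normalizer = ConceptNormalizer(threshold=0.0).fit(table, vectors=vectors)
        query = " ".join(rng.choice(alphabet, size=int(rng.integers(1, 4)), replace=False))
        if normalize_phrase(query) in table.entries:
            return  # exact path, trivially correct

        def brute_cosine(a, b):
            dot = sum(x * y for x, y in zip(a, b))
            na = math.sqrt(sum(x * x for x in a))
            nb = math.sqrt(sum(x * x for x in b))
            if na == 0 or nb == 0:
                return 0.0
            return min(1.0, max(0.0, dot / (na * nb)))

        def brute_embed(phrase):
            rows = [vectors.get(tok) for tok in phrase.split()]
            rows = [r for r in rows if r is not None]
            if not rows:
                return [0.0] * 16
            return [sum(col) / len(rows) for col in zip(*rows)]

        q = brute_embed(query)
        scored = sorted(
            ((brute_cosine(q, brute_embed(p)), p, table.entries[p]) for p in phrases),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        result = normalizer.normalize(query)
        assert result.similarity == pytest.approx(scored[0][0], abs=1e-9)
        tied = {cui for sim, _, cui in scored if sim >= scored[0][0] - 1e-9}
        assert result.cui in tied
        if len(tied) == 1:
            assert result.cui == scored[0][2]
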