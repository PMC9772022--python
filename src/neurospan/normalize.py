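"""Concept normalization: map recognized spans to ontology CUIs.

Normalization is two-stage. A span whose normalized surface is an exact key
of the phrase lookup table maps directly to its CUI with similarity 1.0.
Otherwise the span is embedded as the renormalized mean of the unit word
vectors of its in-vocabulary tokens and compared by cosine similarity against
every lookup phrase; the best-scoring phrase above a configurable threshold
wins. Scores are clamped into [0, 1] (0 least similar, 1 most similar).

Ties are broken deterministically: highest similarity, then lexicographically
smallest phrase, then smallest CUI.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import tokenize, _WORDCHAR_RE
from .ontology import LookupTable, NeuroOntology, normalize_phrase

__all__ = [
    "WordVectors",
    "NormalizationResult",
    "ConceptNormalizer",
    "make_hash_vectors",
    "embed_phrase",
    "cosine_similarity",
    "normalize_span",
]


class WordVectors:
    """Case-folded token → unit vector map (zero vectors mark missing mass)."""

    def __init__(self, dimension: int):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension
        self._vectors: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, token: str) -> bool:
        return token.casefold() in self._vectors

    def add(self, token: str, vector: Sequence[float]) -> None:
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.dimension,):
            raise ValueError(f"vector for {token!r} has shape {v.shape}")
        norm = float(np.linalg.norm(v))
        self._vectors[token.casefold()] = v / norm if norm > 0 else np.zeros(self.dimension)

    def get(self, token: str) -> np.ndarray | None:
        return self._vectors.get(token.casefold())

    def tokens(self) -> list[str]:
        return sorted(self._vectors)

    # Plain-text word2vec format: header "count dim", then "token v1 ... vd".
    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dimension}\n")
            for token in sorted(self._vectors):
                values = " ".join(repr(float(x)) for x in self._vectors[token])
                fh.write(f"{token} {values}\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordVectors":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("word-vector file must start with 'count dim'")
            count, dim = int(header[0]), int(header[1])
            vectors = cls(dim)
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"malformed vector line for {parts[0]!r}")
                vectors.add(parts[0], [float(x) for x in parts[1:]])
        if len(vectors) != count:
            raise ValueError(f"header declared {count} vectors, found {len(vectors)}")
        return vectors


def make_hash_vectors(vocabulary: Iterable[str], d: int = 32, seed: int = 0) -> WordVectors:
    """Deterministic pseudo-random unit vectors keyed by token content.

    Each token's vector is drawn from a generator seeded by a stable hash of
    (seed, token), so identical tokens always receive identical vectors,
    independent of vocabulary order or process. Intended as a reproducible
    vector provider for tests and synthetic experiments; real embedding
    tables load through :meth:`WordVectors.load`.
    """
    if d < 2:
        raise ValueError("dimension must be >= 2")
    vectors = WordVectors(d)
    for token in vocabulary:
        digest = hashlib.blake2b(
            f"{seed}:{token.casefold()}".encode("utf-8"), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        vectors.add(token, rng.standard_normal(d))
    return vectors


def _phrase_tokens(phrase: str) -> list[str]:
    return [
        t.surface.casefold() for t in tokenize(phrase) if _WORDCHAR_RE.search(t.surface)
    ]


def embed_phrase(phrase: str, vectors: WordVectors) -> np.ndarray:
    """Mean of the unit vectors of in-vocabulary tokens, renormalized.

    A phrase with no in-vocabulary token embeds as the zero vector (and will
    score 0 against everything).
    """
    rows = [vectors.get(tok) for tok in _phrase_tokens(phrase)]
    rows = [r for r in rows if r is not None and np.any(r)]
    if not rows:
        return np.zeros(vectors.dimension)
    mean = np.mean(rows, axis=0)
    norm = float(np.linalg.norm(mean))
    return mean / norm if norm > 0 else np.zeros(vectors.dimension)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity clamped below at 0, so the score lies in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return min(1.0, max(0.0, float(np.dot(u, v) / (nu * nv))))


@dataclass
class NormalizationResult:
    """Outcome of normalizing one span; ``cui`` is None below threshold."""

    span_text: str
    matched_phrase: str | None
    cui: str | None
    concept_name: str | None
    similarity: float
    candidates: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return self.cui is not None


class ConceptNormalizer(BaseEstimator):
    """Lookup-then-cosine span normalizer.

    Parameters
    ----------
    threshold:
        Minimum similarity for a vector-search match (default 0.5); below it
        the result is a no-match with the best candidate attached.
    n_candidates:
        Length of the ranked candidate list returned with each result.
    """

    def __init__(self, threshold: float = 0.5, n_candidates: int = 5):
        self.threshold = threshold
        self.n_candidates = n_candidates

    def fit(
        self,
        table: LookupTable,
        ontology: NeuroOntology | None = None,
        vectors: WordVectors | None = None,
    ):
        """Index the lookup table (and embed every phrase if vectors given)."""
        if len(table) == 0:
            raise ValueError("lookup table is empty")
        self.table_ = table
        self.ontology_ = ontology
        self.vectors_ = vectors
        self.phrases_ = sorted(table.entries)
        self.cuis_ = [table.entries[p] for p in self.phrases_]
        if vectors is not None:
            self.matrix_ = np.stack([embed_phrase(p, vectors) for p in self.phrases_])
        else:
            self.matrix_ = None
        return self

    def _concept_name(self, cui: str | None) -> str | None:
        if cui is None or self.ontology_ is None:
            return None
        concept = self.ontology_.get(cui)
        return concept.preferred_name if concept else None

    def normalize(self, span_text: str) -> NormalizationResult:
        """Normalize one span to a concept (exact lookup, then cosine search)."""
        if not hasattr(self, "table_"):
            raise ValueError("ConceptNormalizer is not fitted")
        if not span_text or not span_text.strip():
            raise ValueError("cannot normalize an empty span")
        key = normalize_phrase(span_text)
        exact = self.table_.entries.get(key)
        if exact is not None:
            return NormalizationResult(
                span_text=span_text,
                matched_phrase=key,
                cui=exact,
                concept_name=self._concept_name(exact),
                similarity=1.0,
                candidates=[(key, exact, 1.0)],
            )
        if self.matrix_ is None or self.vectors_ is None:
            return NormalizationResult(span_text, None, None, None, 0.0, [])
        query = embed_phrase(span_text, self.vectors_)
        sims = np.clip(self.matrix_ @ query, 0.0, 1.0)
        order = sorted(
            range(len(self.phrases_)),
            key=lambda i: (-sims[i], self.phrases_[i], self.cuis_[i]),
        )
        candidates = [
            (self.phrases_[i], self.cuis_[i], float(sims[i]))
            for i in order[: self.n_candidates]
        ]
        best_phrase, best_cui, best_sim = candidates[0]
        if best_sim < self.threshold:
            return NormalizationResult(span_text, None, None, None, best_sim, candidates)
        return NormalizationResult(
            span_text=span_text,
            matched_phrase=best_phrase,
            cui=best_cui,
            concept_name=self._concept_name(best_cui),
            similarity=best_sim,
            candidates=candidates,
        )

    def transform(self, span_texts: Sequence[str]) -> list[NormalizationResult]:
        """Normalize a batch of span surfaces."""
        return [self.normalize(s) for s in span_texts]


def normalize_span(
    span_text: str,
    table: LookupTable,
    ontology: NeuroOntology | None = None,
    vectors: WordVectors | None = None,
    threshold: float = 0.5,
) -> NormalizationResult:
    """One-shot functional form of :class:`ConceptNormalizer`."""
    normalizer = ConceptNormalizer(threshold=threshold).fit(
        table, ontology=ontology, vectors=vectors
    )
    return normalizer.normalize(span_text)
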