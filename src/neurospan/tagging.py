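"""Trainable span recognizer: BIO sequence labeling over the seven-category taxonomy.

The reference backend is an averaged structured perceptron with a
Viterbi decoder whose transition mask enforces BIO validity (``I-X`` may only
follow ``B-X`` or ``I-X``). It is deterministic given (corpus order, epochs,
seed), trains on a single CPU, and serializes to versioned JSON that
round-trips bit-exactly.

The feature design mirrors a fixed context window: the lowercased surfaces of
the four tokens on either side of the current token, plus word shape,
prefixes/suffixes, and cue features for digits, reflex/strength grades,
brackets, and negation cues. Hyperparameters of external neural backends
(e.g. a transformer fine-tuned with Adam at learning rate 5e-5, beta1 0.9,
beta2 0.99, 500 warm-up steps, 20,000 steps) are documented in
:class:`BackendConfig` as adapter defaults only; such backends plug in behind
the same train/predict/serialize contract.
"""
from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import CATEGORIES, Document, SpanAnnotation, Token, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "NEGATION_CUES",
    "BackendConfig",
    "SpanTagger",
    "bio_encode",
    "bio_decode",
    "extract_features",
    "train_tagger",
    "predict_spans",
]

#: BIO label inventory: O first, then B-/I- labels in lexicographic order.
#: The ordering doubles as the deterministic tie-break in Viterbi decoding
#: (prefer O, then the lexicographically smaller label).
LABELS: tuple[str, ...] = ("O",) + tuple(
    sorted(f"{p}-{c}" for c in CATEGORIES for p in ("B", "I"))
)

#: Cue words signalling a negated (absent) finding.
NEGATION_CUES: frozenset[str] = frozenset(
    {"no", "not", "denies", "denied", "absent", "without", "negative"}
)

_GRADE_RE = re.compile(r"\d+\+?$")


@dataclass(frozen=True)
class BackendConfig:
    """Documented defaults for pluggable tagger backends.

    The built-in linear sequence labeler ignores the optimizer fields; they
    are recorded so that an external transformer adapter implementing the
    same contract has a canonical configuration.
    """

    backend: str = "perceptron"
    learning_rate: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.99
    warmup_steps: int = 500
    total_steps: int = 20_000


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------


def bio_encode(tokens: Sequence[Token], spans: Sequence[SpanAnnotation]) -> list[str]:
    """Encode character spans as one BIO label per token.

    Span boundaries that fall inside a token are snapped outward to token
    boundaries with a warning. Overlapping spans are rejected.
    """
    labels = ["O"] * len(tokens)
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping spans [{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )
    for span in ordered:
        idxs = [
            i for i, t in enumerate(tokens) if t.end > span.start and t.start < span.end
        ]
        if not idxs:
            warnings.warn(
                f"span [{span.start},{span.end}) covers no tokens; dropped", stacklevel=2
            )
            continue
        if tokens[idxs[0]].start != span.start or tokens[idxs[-1]].end != span.end:
            warnings.warn(
                f"span [{span.start},{span.end}) not token-aligned; snapped outward",
                stacklevel=2,
            )
        if any(labels[i] != "O" for i in idxs):
            raise ValueError("spans overlap after snapping to token boundaries")
        labels[idxs[0]] = f"B-{span.category}"
        for i in idxs[1:]:
            labels[i] = f"I-{span.category}"
    return labels


def bio_decode(tokens: Sequence[Token], labels: Sequence[str]) -> list[SpanAnnotation]:
    """Decode a BIO label sequence back to character spans.

    A stray ``I-X`` without a preceding ``B-X``/``I-X`` is repaired to
    ``B-X``, so any label sequence decodes to a valid span set.
    """
    if len(tokens) != len(labels):
        raise ValueError(f"{len(labels)} labels for {len(tokens)} tokens")
    spans: list[SpanAnnotation] = []
    start_idx: int | None = None
    cat: str | None = None

    def flush(end_idx: int) -> None:
        nonlocal start_idx, cat
        if start_idx is not None and cat is not None:
            spans.append(
                SpanAnnotation(tokens[start_idx].start, tokens[end_idx].end, cat)
            )
        start_idx = cat = None

    for i, label in enumerate(labels):
        if label == "O":
            flush(i - 1)
            continue
        prefix, category = label.split("-", 1)
        if prefix == "I" and cat == category:
            continue
        flush(i - 1)  # stray I-X begins a new span (repair rule)
        start_idx, cat = i, category
    flush(len(labels) - 1)
    return spans


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def _word_shape(surface: str) -> str:
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("d")
        else:
            out.append(ch)
    return "".join(out[:8])


def extract_features(
    tokens: Sequence[Token], index: int, window: int = 4
) -> list[str]:
    """Deterministic feature set for the token at ``index``.

    Includes the lowercased surfaces at offsets -window..+window (padded at
    document boundaries), word shape, 3/4-character prefixes and suffixes,
    and indicator features for digits, grades ("4+"), brackets, and negation
    cues.
    """
    if not 0 <= index < len(tokens):
        raise IndexError(f"token index {index} out of range")
    feats = ["bias"]
    for off in range(-window, window + 1):
        j = index + off
        surf = tokens[j].surface.lower() if 0 <= j < len(tokens) else "<PAD>"
        feats.append(f"w[{off}]={surf}")
    surface = tokens[index].surface
    feats.append(f"shape={_word_shape(surface)}")
    if len(surface) >= 3:
        feats.append(f"pre3={surface[:3].lower()}")
        feats.append(f"suf3={surface[-3:].lower()}")
    if len(surface) >= 4:
        feats.append(f"pre4={surface[:4].lower()}")
        feats.append(f"suf4={surface[-4:].lower()}")
    if surface.isdigit():
        feats.append("is_digit")
    if _GRADE_RE.fullmatch(surface):
        feats.append("is_grade")
    if surface in "[]()":
        feats.append("is_bracket")
    if surface.lower() in NEGATION_CUES:
        feats.append("is_negation_cue")
    return feats


# ---------------------------------------------------------------------------
# Averaged structured perceptron
# ---------------------------------------------------------------------------

_NEG = -1e12


def _transition_mask(labels: Sequence[str]) -> np.ndarray:
    """Boolean (L+1, L) mask of allowed transitions; row L is sequence start."""
    L = len(labels)
    mask = np.zeros((L + 1, L), dtype=bool)
    for j, to_label in enumerate(labels):
        if to_label == "O" or to_label.startswith("B-"):
            mask[:, j] = True  # reachable from anything, incl. start
        else:  # I-X only after B-X or I-X
            category = to_label.split("-", 1)[1]
            for i, from_label in enumerate(labels):
                if from_label != "O" and from_label.split("-", 1)[1] == category:
                    mask[i, j] = True
    return mask


class SpanTagger(BaseEstimator):
    """Averaged-perceptron BIO tagger over the seven span categories.

    Parameters
    ----------
    epochs:
        Training passes over the corpus.
    window:
        Context radius in tokens for surface features (default 4: the model
        looks at four words on either side of each token).
    seed:
        Seed for the document shuffling between epochs; the only source of
        randomness in training.

    Fitted attributes (trailing underscore) hold the label inventory, the
    feature index, and the averaged emission/transition weights.
    """

    def __init__(self, epochs: int = 10, window: int = 4, seed: int = 0):
        self.epochs = epochs
        self.window = window
        self.seed = seed

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _as_document(x: Document | str, i: int) -> Document:
        if isinstance(x, Document):
            return x
        return Document(doc_id=f"doc{i}", text=x)

    def _viterbi(self, emissions: np.ndarray, trans: np.ndarray) -> list[int]:
        T, L = emissions.shape
        if T == 0:
            return []
        penalty = np.where(self._mask_, 0.0, _NEG)
        delta = emissions[0] + trans[L] + penalty[L]
        back = np.zeros((T, L), dtype=np.int32)
        for t in range(1, T):
            cand = delta[:, None] + trans[:L] + penalty[:L]
            back[t] = np.argmax(cand, axis=0)
            delta = emissions[t] + cand[back[t], np.arange(L)]
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]

    def _emissions(self, fids: list[np.ndarray], W: np.ndarray) -> np.ndarray:
        L = W.shape[1]
        out = np.zeros((len(fids), L))
        for t, ids in enumerate(fids):
            if ids.size:
                out[t] = W[ids].sum(axis=0)
        return out

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: Sequence[Document | str], y: Sequence[Sequence[SpanAnnotation]]):
        """Train on documents ``X`` with gold span annotations ``y``."""
        if len(X) == 0:
            raise ValueError("cannot train on an empty corpus")
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        self.labels_ = list(LABELS)
        L = len(self.labels_)
        label_index = {lab: i for i, lab in enumerate(self.labels_)}
        self._mask_ = _transition_mask(self.labels_)

        feat_index: dict[str, int] = {}
        doc_fids: list[list[np.ndarray]] = []
        doc_gold: list[np.ndarray] = []
        for i, x in enumerate(X):
            doc = self._as_document(x, i)
            tokens = tokenize(doc.text)
            gold = bio_encode(tokens, list(y[i]))
            fids_per_tok = []
            for t in range(len(tokens)):
                ids = []
                for feat in extract_features(tokens, t, self.window):
                    fid = feat_index.setdefault(feat, len(feat_index))
                    ids.append(fid)
                fids_per_tok.append(np.asarray(ids, dtype=np.int64))
            doc_fids.append(fids_per_tok)
            doc_gold.append(np.asarray([label_index[g] for g in gold], dtype=np.int64))

        F = len(feat_index)
        W = np.zeros((F, L))
        U = np.zeros((F, L))  # step-weighted update sums for averaging
        trans = np.zeros((L + 1, L))
        trans_u = np.zeros((L + 1, L))

        rng = np.random.default_rng(self.seed)
        step = 0
        n_docs = len(doc_fids)
        for epoch in range(self.epochs):
            order = rng.permutation(n_docs)
            tok_total = tok_correct = 0
            for di in order:
                step += 1
                fids = doc_fids[di]
                gold = doc_gold[di]
                T = len(fids)
                if T == 0:
                    continue
                pred = np.asarray(self._viterbi(self._emissions(fids, W), trans))
                tok_total += T
                tok_correct += int((pred == gold).sum())
                if np.array_equal(pred, gold):
                    continue
                for t in range(T):
                    if pred[t] != gold[t]:
                        W[fids[t], gold[t]] += 1.0
                        W[fids[t], pred[t]] -= 1.0
                        U[fids[t], gold[t]] += step
                        U[fids[t], pred[t]] -= step
                    gprev = gold[t - 1] if t else L
                    pprev = pred[t - 1] if t else L
                    if gprev != pprev or gold[t] != pred[t]:
                        trans[gprev, gold[t]] += 1.0
                        trans[pprev, pred[t]] -= 1.0
                        trans_u[gprev, gold[t]] += step
                        trans_u[pprev, pred[t]] -= step
            logger.info(
                "epoch %d/%d: training token accuracy %.3f",
                epoch + 1,
                self.epochs,
                tok_correct / max(tok_total, 1),
            )

        total = max(step, 1)
        self.feature_index_ = feat_index
        self.feature_weights_ = W - U / total
        self.transition_weights_ = trans - trans_u / total
        self.n_features_in_ = F
        return self

    def _predict_doc(self, doc: Document) -> list[SpanAnnotation]:
        tokens = tokenize(doc.text)
        if not tokens:
            return []
        fids = []
        for t in range(len(tokens)):
            ids = [
                self.feature_index_[f]
                for f in extract_features(tokens, t, self.window)
                if f in self.feature_index_
            ]
            fids.append(np.asarray(ids, dtype=np.int64))
        path = self._viterbi(
            self._emissions(fids, self.feature_weights_), self.transition_weights_
        )
        return bio_decode(tokens, [self.labels_[i] for i in path])

    def predict(self, X: Sequence[Document | str]) -> list[list[SpanAnnotation]]:
        """Predict span annotations for each document."""
        if not hasattr(self, "feature_weights_"):
            raise ValueError("SpanTagger is not fitted")
        return [self._predict_doc(self._as_document(x, i)) for i, x in enumerate(X)]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to versioned JSON (bit-exact round trip)."""
        if not hasattr(self, "feature_weights_"):
            raise ValueError("SpanTagger is not fitted")
        obj = {
            "format_version": 1,
            "labels": self.labels_,
            "meta": {"epochs": self.epochs, "window": self.window, "seed": self.seed},
            "features": {
                feat: [float(w) for w in self.feature_weights_[fid]]
                for feat, fid in sorted(self.feature_index_.items())
            },
            "transitions": [[float(w) for w in row] for row in self.transition_weights_],
        }
        Path(path).write_text(
            json.dumps(obj, ensure_ascii=False, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpanTagger":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        if obj.get("format_version") != 1:
            raise ValueError(f"unsupported model format {obj.get('format_version')!r}")
        meta = obj["meta"]
        model = cls(epochs=meta["epochs"], window=meta["window"], seed=meta["seed"])
        model.labels_ = list(obj["labels"])
        model._mask_ = _transition_mask(model.labels_)
        feats = obj["features"]
        model.feature_index_ = {feat: i for i, feat in enumerate(sorted(feats))}
        L = len(model.labels_)
        W = np.zeros((len(feats), L))
        for feat, fid in model.feature_index_.items():
            W[fid] = feats[feat]
        model.feature_weights_ = W
        model.transition_weights_ = np.asarray(obj["transitions"])
        model.n_features_in_ = len(feats)
        return model


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def train_tagger(
    corpus: Sequence[tuple[Document, Sequence[SpanAnnotation]]],
    epochs: int = 10,
    seed: int = 0,
    window: int = 4,
) -> SpanTagger:
    """Train a :class:`SpanTagger` on an annotated corpus."""
    docs = [doc for doc, _ in corpus]
    spans = [list(s) for _, s in corpus]
    return SpanTagger(epochs=epochs, window=window, seed=seed).fit(docs, spans)


def predict_spans(model: SpanTagger, doc: Document | str) -> list[SpanAnnotation]:
    """Predict the sign/symptom spans of one document."""
    return model.predict([doc])[0]
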