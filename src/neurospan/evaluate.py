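"""Span-level evaluation, inter-annotator agreement, and corpus style statistics.

Span matching is exact by default ("strict": a predicted span counts as a
true positive only when start, end, and category all agree with a gold span);
"boundary" mode ignores the category. Precision, recall, and F are reported
on the percent scale with half-up rounding to one decimal for display, per
category and micro-averaged over summed counts.

Agreement between two annotators is measured at the token level (in-span vs
outside) with the observed agreement rate and Cohen's kappa,
kappa = (p_o - p_e) / (1 - p_e).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Mapping, Sequence

from .corpus import (
    CATEGORIES,
    Document,
    SpanAnnotation,
    content_word_count,
    tokenize,
)

__all__ = [
    "MatchCounts",
    "EvalRow",
    "EvalReport",
    "AgreementReport",
    "StyleStats",
    "round1",
    "f_from_pr",
    "match_spans",
    "precision_recall_f",
    "evaluate_by_category",
    "cohen_kappa",
    "corpus_style_stats",
]


def round1(x: float) -> float:
    """Half-up rounding to one decimal on the percent scale (display rule)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean F = 2PR/(P+R); 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchCounts:
    """True/false positive and false negative counts, per category and overall."""

    tp: Counter = field(default_factory=Counter)
    fp: Counter = field(default_factory=Counter)
    fn: Counter = field(default_factory=Counter)

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def total_tp(self) -> int:
        return sum(self.tp.values())

    @property
    def total_fp(self) -> int:
        return sum(self.fp.values())

    @property
    def total_fn(self) -> int:
        return sum(self.fn.values())


def _assert_no_overlap(spans: Sequence[SpanAnnotation], side: str) -> None:
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(f"{side} spans overlap: {prev} and {cur}")


def match_spans(
    gold: Sequence[SpanAnnotation],
    pred: Sequence[SpanAnnotation],
    mode: str = "strict",
) -> MatchCounts:
    """Match predicted against gold spans within one document.

    strict: a match requires identical (start, end, category).
    boundary: identical (start, end); the category is ignored for matching
    but counts are attributed to the gold span's category.
    """
    if mode not in ("strict", "boundary"):
        raise ValueError(f"unknown matching mode {mode!r}")
    _assert_no_overlap(gold, "gold")
    _assert_no_overlap(pred, "predicted")
    counts = MatchCounts()

    def key(span: SpanAnnotation):
        if mode == "strict":
            return (span.start, span.end, span.category)
        return (span.start, span.end)

    gold_by_key = {key(s): s for s in gold}
    matched_keys = set()
    for p in pred:
        g = gold_by_key.get(key(p))
        if g is not None and key(p) not in matched_keys:
            matched_keys.add(key(p))
            counts.tp[g.category] += 1
        else:
            counts.fp[p.category] += 1
    for g in gold:
        if key(g) not in matched_keys:
            counts.fn[g.category] += 1
    return counts


# ---------------------------------------------------------------------------
# Precision / recall / F
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalRow:
    """P, R, F on the percent scale plus support (gold span count)."""

    precision: float
    recall: float
    f: float
    support: int

    def rounded(self) -> tuple[float, float, float]:
        return round1(self.precision), round1(self.recall), round1(self.f)


def _row(tp: int, fp: int, fn: int) -> EvalRow:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return EvalRow(p, r, f_from_pr(p, r), support=tp + fn)


@dataclass
class EvalReport:
    """Per-category rows and the micro-average over summed counts."""

    per_category: dict[str, EvalRow]
    micro: EvalRow

    def to_json_dict(self) -> dict:
        def rowdict(row: EvalRow) -> dict:
            p, r, f = row.rounded()
            return {"P": p, "R": r, "F": f, "support": row.support}

        return {
            "per_category": {c: rowdict(r) for c, r in self.per_category.items()},
            "micro": rowdict(self.micro),
        }

    def to_csv_rows(self) -> list[list]:
        rows = [["category", "P", "R", "F", "support"]]
        for cat in CATEGORIES:
            if cat in self.per_category:
                row = self.per_category[cat]
                rows.append([cat, *row.rounded(), row.support])
        rows.append(["micro", *self.micro.rounded(), self.micro.support])
        return rows

    def pretty(self) -> str:
        lines = []
        for row in self.to_csv_rows():
            lines.append("{:<10} {:>6} {:>6} {:>6} {:>8}".format(*row))
        return "\n".join(lines)


def precision_recall_f(counts: MatchCounts) -> EvalReport:
    """Compute the evaluation report from match counts.

    P = 100 tp/(tp+fp), R = 100 tp/(tp+fn), F = 2PR/(P+R); a zero denominator
    yields 0 by convention.
    """
    categories = sorted(
        set(counts.tp) | set(counts.fp) | set(counts.fn),
        key=lambda c: CATEGORIES.index(c) if c in CATEGORIES else len(CATEGORIES),
    )
    per_category = {
        c: _row(counts.tp[c], counts.fp[c], counts.fn[c]) for c in categories
    }
    micro = _row(counts.total_tp, counts.total_fp, counts.total_fn)
    return EvalReport(per_category=per_category, micro=micro)


def evaluate_by_category(
    gold_docs: Sequence[tuple[Document, Sequence[SpanAnnotation]]],
    pred_docs: Sequence[tuple[Document, Sequence[SpanAnnotation]]],
    mode: str = "strict",
) -> EvalReport:
    """Evaluate a document collection, aligning gold and predictions by doc_id."""
    pred_by_id: dict[str, Sequence[SpanAnnotation]] = {}
    for doc, spans in pred_docs:
        pred_by_id[doc.doc_id] = spans
    gold_ids = {doc.doc_id for doc, _ in gold_docs}
    unmatched = set(pred_by_id) - gold_ids
    if unmatched:
        raise ValueError(f"predicted doc_ids without gold: {sorted(unmatched)[:5]}")
    total = MatchCounts()
    for doc, gold in gold_docs:
        if doc.doc_id not in pred_by_id:
            raise ValueError(f"no predictions for doc_id {doc.doc_id!r}")
        total = total + match_spans(list(gold), list(pred_by_id[doc.doc_id]), mode)
    return precision_recall_f(total)


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    observed_agreement: float
    expected_agreement: float
    kappa: float


def cohen_kappa(
    labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]
) -> AgreementReport:
    """Chance-corrected agreement between two aligned label sequences.

    The intended unit is token-level binary in-span indicators, but any
    hashable labels work. The degenerate case p_e = 1 (both raters constant
    and identical marginals) defines kappa as 1 if agreement is perfect,
    else 0.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"length mismatch: {len(labels_a)} vs {len(labels_b)} labels"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("cannot compute agreement on empty sequences")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    marg_a = Counter(labels_a)
    marg_b = Counter(labels_b)
    p_e = sum(marg_a[l] / n * marg_b[l] / n for l in set(marg_a) | set(marg_b))
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(observed_agreement=p_o, expected_agreement=p_e, kappa=kappa)


def in_span_indicators(
    text: str, spans: Sequence[SpanAnnotation]
) -> list[int]:
    """Token-level binary indicators (1 = token inside any span) for kappa."""
    tokens = tokenize(text)
    return [
        int(any(t.end > s.start and t.start < s.end for s in spans)) for t in tokens
    ]


# ---------------------------------------------------------------------------
# Corpus style statistics
# ---------------------------------------------------------------------------


@dataclass
class StyleStats:
    """Category proportions, span word-length histogram, and mean span length."""

    category_proportions: Mapping[str, float]
    span_length_histogram: Counter
    mean_span_length: float
    n_spans: int

    @property
    def unigram_bigram_proportion(self) -> float:
        return (
            self.category_proportions["UNIGRAM"] + self.category_proportions["BIGRAM"]
        )


def corpus_style_stats(
    corpus: Sequence[tuple[Document, Sequence[SpanAnnotation]]]
) -> StyleStats:
    """Writing-style summary of an annotated corpus.

    Span length is measured in content words of the annotated surface, so
    detached punctuation (including tabular brackets) does not count.
    """
    cat_counts: Counter = Counter()
    length_hist: Counter = Counter()
    total_len = 0
    n_spans = 0
    for doc, spans in corpus:
        for span in spans:
            words = content_word_count(tokenize(doc.text[span.start : span.end]))
            cat_counts[span.category] += 1
            length_hist[words] += 1
            total_len += words
            n_spans += 1
    if n_spans == 0:
        raise ValueError("corpus contains no spans")
    proportions = {c: cat_counts[c] / n_spans for c in CATEGORIES}
    return StyleStats(
        category_proportions=proportions,
        span_length_histogram=length_hist,
        mean_span_length=total_len / n_spans,
        n_spans=n_spans,
    )
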