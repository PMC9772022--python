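"""Clinical-text preprocessing, tokenization, span taxonomy, and JSONL annotation I/O.

The unit of annotation is a character-offset text span over a plain-text
document, labeled with one of seven taxonomy categories: length-based
categories (UNIGRAM through TETRAGRAM, and EXTENDED for spans longer than
four words), COMPOUND for spans combining several distinct findings, and
TABULAR for exam findings written as an anatomic phrase followed by paired
right/left grade values (e.g. ``[biceps strength 3 3]``).

Offsets are 0-based, half-open, into the document text exactly as stored;
``text[start:end]`` always equals the annotated surface.
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CATEGORIES",
    "STYLES",
    "Token",
    "SpanAnnotation",
    "Document",
    "CorpusError",
    "clean_text",
    "tokenize",
    "content_word_count",
    "categorize_span",
    "detect_tabular_spans",
    "read_annotations",
    "write_annotations",
]

#: The closed set of span taxonomy categories, in canonical (length) order.
CATEGORIES: tuple[str, ...] = (
    "UNIGRAM",
    "BIGRAM",
    "TRIGRAM",
    "TETRAGRAM",
    "EXTENDED",
    "COMPOUND",
    "TABULAR",
)

#: Corpus writing styles: physician EHR notes, textbook case histories,
#: genetic-database clinical synopses, or unknown provenance.
STYLES: tuple[str, ...] = ("ehr", "textbook", "omim", "unknown")


class CorpusError(ValueError):
    """Raised for malformed documents, spans, or annotation files."""


@dataclass(frozen=True)
class Token:
    """A surface string with its half-open character offsets."""

    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class SpanAnnotation:
    """A labeled sign/symptom span; ``cui`` links it to an ontology concept."""

    start: int
    end: int
    category: str
    cui: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid span offsets [{self.start}, {self.end})"
            )
        if self.category not in CATEGORIES:
            raise CorpusError(f"unknown span category {self.category!r}")


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    style: str = "unknown"

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise CorpusError(f"unknown document style {self.style!r}")


# ---------------------------------------------------------------------------
# Text cleaning
# ---------------------------------------------------------------------------

#: Contractions expanded during preprocessing. Abbreviations are never edited.
CONTRACTIONS: dict[str, str] = {
    "can't": "cannot",
    "won't": "will not",
    "don't": "do not",
    "doesn't": "does not",
    "didn't": "did not",
    "isn't": "is not",
    "aren't": "are not",
    "wasn't": "was not",
    "weren't": "were not",
    "hasn't": "has not",
    "haven't": "have not",
    "hadn't": "had not",
    "couldn't": "could not",
    "shouldn't": "should not",
    "wouldn't": "would not",
    "mustn't": "must not",
    "needn't": "need not",
    "it's": "it is",
    "he's": "he is",
    "she's": "she is",
    "that's": "that is",
    "there's": "there is",
    "what's": "what is",
    "who's": "who is",
    "let's": "let us",
    "i'm": "i am",
    "i've": "i have",
    "i'd": "i would",
    "i'll": "i will",
    "you're": "you are",
    "you've": "you have",
    "they're": "they are",
    "they've": "they have",
    "we're": "we are",
    "we've": "we have",
    "she'll": "she will",
    "he'll": "he will",
}

_HTML_RE = re.compile(r"<[^<>]+>")
_URL_RE = re.compile(r"\bhttps?://\S+|\bwww\.\S+", re.IGNORECASE)
_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+(?:\.[\w-]+)+")
# Characters permitted after cleaning: word characters, whitespace, and the
# punctuation that carries clinical meaning (grades, brackets, sentence marks).
_DISALLOWED_RE = re.compile(r"[^A-Za-z0-9\s.,;:!?()\[\]'\"+/\-]")
_WS_RE = re.compile(r"\s+")
_CONTRACTION_RE = re.compile(
    r"\b(" + "|".join(sorted((re.escape(k) for k in CONTRACTIONS), key=len, reverse=True)) + r")\b",
    re.IGNORECASE,
)


def _expand_contraction(match: re.Match[str]) -> str:
    surface = match.group(0)
    expansion = CONTRACTIONS[surface.lower()]
    if surface[0].isupper():
        expansion = expansion[0].upper() + expansion[1:]
    return expansion


def clean_text(raw: str) -> str:
    """Preprocess raw clinical text for annotation.

    Removes HTML tags, URLs, email addresses, and special characters outside
    a clinical whitelist; expands contractions from the packaged map; and
    collapses runs of whitespace. Abbreviations are left untouched, and no
    automatic spelling correction is attempted. Idempotent.
    """
    text = _HTML_RE.sub(" ", raw)
    text = _URL_RE.sub(" ", text)
    text = _EMAIL_RE.sub(" ", text)
    text = _CONTRACTION_RE.sub(_expand_contraction, text)
    text = _DISALLOWED_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Reflex/strength grades like "4+" are kept as single tokens; all other
# punctuation is detached. Apostrophes stay inside words ("patient's").
_TOKEN_RE = re.compile(r"\d+\+|\w+(?:'\w+)*|[^\w\s]")
_WORDCHAR_RE = re.compile(r"\w")


def tokenize(text: str) -> list[Token]:
    """Deterministic whitespace/punctuation tokenizer with exact offsets."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def content_word_count(tokens: Sequence[Token | str]) -> int:
    """Number of content tokens (those containing a word character)."""
    count = 0
    for tok in tokens:
        surface = tok if isinstance(tok, str) else tok.surface
        if _WORDCHAR_RE.search(surface):
            count += 1
    return count


def categorize_span(
    tokens_in_span: Sequence[Token | str],
    compound: bool = False,
    tabular: bool = False,
) -> str:
    """Assign the taxonomy category of a span from its tokens.

    TABULAR and COMPOUND take precedence (they are annotation types, not
    lengths); otherwise the category is the content-word count of the span,
    with anything above four words EXTENDED.
    """
    if not tokens_in_span:
        raise CorpusError("cannot categorize an empty token list")
    if tabular:
        return "TABULAR"
    if compound:
        return "COMPOUND"
    n = content_word_count(tokens_in_span)
    if n <= 0:
        raise CorpusError("span contains no content tokens")
    if n >= 5:
        return "EXTENDED"
    return CATEGORIES[n - 1]


# ---------------------------------------------------------------------------
# Tabular findings
# ---------------------------------------------------------------------------

_GRADE = r"(?:\d+\+?|[-−])"
_TAB_BRACKET_RE = re.compile(
    r"\[[A-Za-z][A-Za-z ]*[A-Za-z]\s+" + _GRADE + r"\s+" + _GRADE + r"\]"
)
_TAB_LINE_RE = re.compile(
    r"^[A-Za-z][A-Za-z ]*[A-Za-z]\s+" + _GRADE + r"\s+" + _GRADE + r"(?=\s*$)",
    re.MULTILINE,
)


def detect_tabular_spans(text: str) -> list[SpanAnnotation]:
    """Find tabular exam findings: an anatomic phrase plus two grade tokens.

    Matches bracketed constructs like ``[knee reflexes 4+ 4+]`` anywhere, and
    unbracketed phrase-plus-grades occupying a whole line. Grades are digits
    optionally suffixed ``+``, or a minus sign for an absent response.
    """
    spans: list[SpanAnnotation] = []
    taken: list[tuple[int, int]] = []
    for pattern in (_TAB_BRACKET_RE, _TAB_LINE_RE):
        for m in pattern.finditer(text):
            if any(m.start() < e and s < m.end() for s, e in taken):
                continue
            taken.append((m.start(), m.end()))
            spans.append(SpanAnnotation(m.start(), m.end(), "TABULAR"))
    return sorted(spans, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# JSONL annotation I/O
# ---------------------------------------------------------------------------


def _check_spans(text: str, spans: Sequence[SpanAnnotation], where: str) -> None:
    for span in spans:
        if span.end > len(text):
            raise CorpusError(
                f"{where}: span [{span.start}, {span.end}) exceeds text length {len(text)}"
            )
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise CorpusError(
                f"{where}: overlapping spans [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end})"
            )


def read_annotations(path: str | Path) -> list[tuple[Document, list[SpanAnnotation]]]:
    """Read a JSONL annotation file (one document object per line)."""
    out: list[tuple[Document, list[SpanAnnotation]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            if "text" not in obj:
                raise CorpusError(f"line {lineno}: missing 'text' field")
            doc = Document(
                doc_id=str(obj.get("doc_id", f"doc{lineno}")),
                text=obj["text"],
                style=obj.get("style", "unknown"),
            )
            spans = []
            for raw in obj.get("spans", []):
                try:
                    spans.append(
                        SpanAnnotation(
                            start=int(raw["start"]),
                            end=int(raw["end"]),
                            category=raw["label"],
                            cui=raw.get("cui"),
                        )
                    )
                except (KeyError, CorpusError, TypeError, ValueError) as exc:
                    raise CorpusError(f"line {lineno}: invalid span {raw!r}: {exc}") from exc
            _check_spans(doc.text, spans, f"line {lineno}")
            out.append((doc, sorted(spans, key=lambda s: s.start)))
    return out


def write_annotations(
    docs: Iterable[tuple[Document, Sequence[SpanAnnotation]]],
    path: str | Path,
) -> None:
    """Write annotated documents as canonical JSONL (bit-exact round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc, spans in docs:
            _check_spans(doc.text, spans, doc.doc_id)
            obj = {
                "doc_id": doc.doc_id,
                "text": doc.text,
                "style": doc.style,
                "spans": [
                    {"start": s.start, "end": s.end, "label": s.category, "cui": s.cui}
                    for s in sorted(spans, key=lambda s: s.start)
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
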