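"""Seeded generator of gold-annotated synthetic corpora in three writing styles.

The real corpora behind this kind of pipeline — physician EHR notes, textbook
case histories, and genetic-database clinical synopses — are private, so the
generator emulates their documented style contrasts instead:

* ``omim``: terse list-like sentences, dominated by one- and two-word
  concept names, no writing noise, no tabular findings.
* ``textbook``: didactic prose with a high share of extended (>4 word)
  descriptive spans, professionally edited (no noise).
* ``ehr``: short irregular sentences with misspellings, irregular
  abbreviations (e.g. "relative afferent pupil defect" -> "RAPD"), negated
  mentions, and tabular findings like ``[biceps strength 3 3]``.

Every emitted span is gold-annotated with exact character offsets, a taxonomy
category that agrees with :func:`neurospan.corpus.categorize_span` on its
tokens, and (except for COMPOUND spans, which combine several concepts) the
CUI of its source concept in the generated mini-ontology. Negated mentions
are emitted UNANNOTATED: an absent finding is not a finding, and the tagger
must learn to skip it from context.

Generation is reproducible: one seed per corpus, with an independent
substream per document, so corpora are byte-identical across runs and
document order does not perturb content.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import (
    CATEGORIES,
    Document,
    SpanAnnotation,
    categorize_span,
    tokenize,
)
from .ontology import (
    Concept,
    LookupTable,
    NeuroOntology,
    build_lookup_table,
    write_lookup_table,
    write_ontology,
)

__all__ = [
    "StyleProfile",
    "MiniOntologyFixture",
    "ABBREVIATIONS",
    "style_profile",
    "make_fixture",
    "generate_corpus",
    "inject_noise",
]


# ---------------------------------------------------------------------------
# Style profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StyleProfile:
    """Distributional fingerprint of one corpus writing style."""

    name: str
    category_proportions: dict[str, float]
    misspelling_rate: float
    abbreviation_rate: float
    negation_rate: float
    continuation_rate: float
    spans_per_doc: tuple[int, int]

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if set(self.category_proportions) != set(CATEGORIES):
            raise ValueError("proportions must cover all seven categories")

    @property
    def tabular_rate(self) -> float:
        return self.category_proportions["TABULAR"]


_PROFILES: dict[str, StyleProfile] = {
    # Ordered as CATEGORIES: UNIGRAM, BIGRAM, TRIGRAM, TETRAGRAM, EXTENDED,
    # COMPOUND, TABULAR.
    "omim": StyleProfile(
        name="omim",
        category_proportions=dict(zip(CATEGORIES, (0.45, 0.30, 0.13, 0.07, 0.05, 0.0, 0.0))),
        misspelling_rate=0.0,
        abbreviation_rate=0.0,
        negation_rate=0.0,
        continuation_rate=0.0,
        spans_per_doc=(4, 8),
    ),
    "textbook": StyleProfile(
        name="textbook",
        category_proportions=dict(zip(CATEGORIES, (0.14, 0.20, 0.16, 0.15, 0.30, 0.05, 0.0))),
        misspelling_rate=0.0,
        abbreviation_rate=0.0,
        negation_rate=0.0,
        continuation_rate=0.15,
        spans_per_doc=(3, 6),
    ),
    "ehr": StyleProfile(
        name="ehr",
        category_proportions=dict(zip(CATEGORIES, (0.20, 0.20, 0.12, 0.10, 0.20, 0.08, 0.10))),
        misspelling_rate=0.10,
        abbreviation_rate=0.4,
        negation_rate=0.25,
        continuation_rate=0.3,
        spans_per_doc=(3, 7),
    ),
}


def style_profile(name: str) -> StyleProfile:
    """Return the packaged profile for ``omim``, ``textbook``, or ``ehr``."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown style profile {name!r}") from None


# ---------------------------------------------------------------------------
# Mini-ontology fixture
# ---------------------------------------------------------------------------

# (name, synonyms, exam category) for the generated concepts.
_CONCEPT_ROWS: list[tuple[str, list[str], str]] = [
    ("alexia", ["word blindness"], "mental status"),
    ("aphasia", ["language impairment"], "mental status"),
    ("agraphia", [], "mental status"),
    ("acalculia", [], "mental status"),
    ("apraxia", [], "mental status"),
    ("confusion", ["confusional state"], "mental status"),
    ("disorientation", [], "mental status"),
    ("memory loss", ["amnesia", "poor memory"], "mental status"),
    ("diplopia", ["double vision"], "cranial nerves"),
    ("ptosis", ["droopy eyelid"], "cranial nerves"),
    ("anisocoria", [], "cranial nerves"),
    ("miosis", [], "cranial nerves"),
    ("nystagmus", [], "cranial nerves"),
    ("dysarthria", ["slurred speech"], "cranial nerves"),
    ("dysphagia", ["difficulty swallowing"], "cranial nerves"),
    ("facial weakness", ["facial droop"], "cranial nerves"),
    ("optic disk pallor", [], "cranial nerves"),
    ("relative afferent pupil defect", ["rapd"], "cranial nerves"),
    ("bradykinesia", [], "motor"),
    ("hypomimia", ["masked face", "masked facies"], "motor"),
    ("tremor", [], "motor"),
    ("spasticity", [], "motor"),
    ("rigidity", [], "motor"),
    ("atrophy", ["muscle wasting"], "motor"),
    ("ataxia", ["incoordination"], "motor"),
    ("biceps weakness", [], "motor"),
    ("triceps weakness", [], "motor"),
    ("hand weakness", ["weak hand grip"], "motor"),
    ("leg weakness", [], "motor"),
    ("gait ataxia", ["ataxic gait"], "motor"),
    ("poor balance", ["imbalance"], "motor"),
    ("numbness", [], "sensory"),
    ("paresthesia", ["tingling"], "sensory"),
    ("hypoesthesia", ["decreased sensation"], "sensory"),
    ("allodynia", [], "sensory"),
    ("facial numbness", [], "sensory"),
    ("hand numbness", [], "sensory"),
    ("decreased vibratory sensation", ["impaired vibration sense"], "sensory"),
    ("sensory loss", [], "sensory"),
    ("hyperreflexia", ["brisk reflexes"], "reflexes"),
    ("hyporeflexia", ["diminished reflexes"], "reflexes"),
    ("areflexia", ["absent reflexes"], "reflexes"),
    ("absent ankle reflex", [], "reflexes"),
    ("babinski sign", ["extensor plantar response"], "reflexes"),
    ("hoffman sign", [], "reflexes"),
    ("knee hyperreflexia", ["brisk knee reflexes"], "reflexes"),
    ("ankle hyporeflexia", [], "reflexes"),
    ("ankle clonus", [], "reflexes"),
    ("headache", [], "symptoms"),
    ("dizziness", [], "symptoms"),
    ("vertigo", [], "symptoms"),
    ("nausea", ["queasiness"], "symptoms"),
    ("fatigue", [], "symptoms"),
    ("insomnia", [], "symptoms"),
    ("neck pain", [], "symptoms"),
    ("back pain", [], "symptoms"),
    ("blurred vision", [], "symptoms"),
]

_ROOT_NAMES = {
    "mental status": "mental status finding",
    "cranial nerves": "cranial nerve finding",
    "motor": "motor finding",
    "sensory": "sensory finding",
    "reflexes": "reflex finding",
    "symptoms": "neurological symptom",
}

# Filler sets for extended (>4 word) descriptive renderings; every
# combination is enumerated into the lookup table so the noise-free exact
# match path always resolves.
_EXT_ADVERBS = ("quite", "very", "rather", "notably")
_EXT_ADJECTIVES = ("severe", "marked", "prominent", "troublesome")
_EXT_TAILS = (
    "today",
    "on examination",
    "at rest",
    "throughout the visit",
    "since last week",
    "at times",
)

# Unannotated continuation phrases appended after some spans; they share
# vocabulary with the extended-span tails, so the end boundary of a long
# descriptive span is genuinely ambiguous from context alone (emulating the
# variable extent of free-text descriptions).
_CONTINUATIONS = _EXT_TAILS + ("per spouse", "per chart")

_NEGATION_TEMPLATES = ("no {}", "denies {}", "{} absent", "without {}")

# Tabular finding templates: (anatomic phrase, admissible grade tokens,
# concept the finding documents).
_TABULAR_SITES: list[tuple[str, tuple[str, ...], str]] = [
    ("biceps strength", ("0", "1", "2", "3", "4", "5"), "biceps weakness"),
    ("triceps strength", ("0", "1", "2", "3", "4", "5"), "triceps weakness"),
    ("hand grip", ("0", "1", "2", "3", "4", "5"), "hand weakness"),
    ("knee reflexes", ("0", "1", "2", "3", "2+", "3+", "4+"), "knee hyperreflexia"),
    ("ankle reflexes", ("0", "1", "2", "3", "2+", "3+", "4+"), "ankle hyporeflexia"),
]

#: Irregular clinical abbreviations applied as EHR writing noise.
ABBREVIATIONS: dict[str, str] = {
    "relative afferent pupil defect": "RAPD",
    "decreased sensation": "dec sensation",
    "double vision": "dbl vision",
    "blurred vision": "blurry vision",
    "headache": "HA",
}


@dataclass
class MiniOntologyFixture:
    """Generated ontology, lookup table, and per-concept surface renderings.

    ``renderings[cui][category]`` lists every surface form of the concept in
    that taxonomy category; all of them (and every tabular surface) are keys
    of the lookup table, so noise-free corpora normalize perfectly through
    the exact-match path. ``negated[cui]`` lists negated renderings, used for
    unannotated absent-finding mentions.
    """

    ontology: NeuroOntology
    lookup_table: LookupTable
    renderings: dict[str, dict[str, list[str]]]
    negated: dict[str, list[str]]
    by_category: dict[str, list[str]]
    tabular_sites: list[tuple[str, tuple[str, ...], str]]  # phrase, grades, cui

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ontology(self.ontology, outdir / "ontology.csv")
        write_lookup_table(self.lookup_table, outdir / "lookup.csv")


def _concept_renderings(names: tuple[str, ...]) -> dict[str, list[str]]:
    """All surface forms of a concept, bucketed by taxonomy category."""
    buckets: dict[str, list[str]] = {}

    def add(surface: str) -> None:
        category = categorize_span(tokenize(surface))
        buckets.setdefault(category, []).append(surface)

    for name in names:
        add(name)
        add(f"mild {name}")
        add(f"severe {name}")
        add(f"{name} was present")
        add(f"{name} was noted")
        add(f"{name} was clearly present")
        for adv in _EXT_ADVERBS:
            for adj in _EXT_ADJECTIVES:
                for tail in _EXT_TAILS:
                    add(f"{name} was {adv} {adj} {tail}")
                # Tail-less descriptive variant (still >4 words for multi-word
                # names): its extent is indistinguishable in context from a
                # tailed variant followed by a continuation phrase, emulating
                # the variable extent of free-text description annotations.
                if len(name.split()) >= 2:
                    add(f"{name} was {adv} {adj}")
    return buckets


def make_fixture() -> MiniOntologyFixture:
    """Build the deterministic mini-ontology fixture (>=50 concepts, 6 roots)."""
    concepts: list[Concept] = []
    root_cuis: dict[str, str] = {}
    for i, (category, root_name) in enumerate(_ROOT_NAMES.items(), start=1):
        cui = f"C{i:07d}"
        root_cuis[category] = cui
        concepts.append(Concept(cui=cui, preferred_name=root_name, exam_category=category))
    name_to_cui: dict[str, str] = {}
    for i, (name, synonyms, category) in enumerate(_CONCEPT_ROWS, start=1):
        cui = f"C{100 + i:07d}"
        name_to_cui[name] = cui
        concepts.append(
            Concept(
                cui=cui,
                preferred_name=name,
                synonyms=tuple(synonyms),
                parent_cui=root_cuis[category],
                exam_category=category,
            )
        )
    ontology = NeuroOntology(concepts)

    table = build_lookup_table(ontology)
    renderings: dict[str, dict[str, list[str]]] = {}
    negated: dict[str, list[str]] = {}
    by_category: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for name, synonyms, _category in _CONCEPT_ROWS:
        cui = name_to_cui[name]
        buckets = _concept_renderings((name, *synonyms))
        renderings[cui] = buckets
        negated[cui] = [t.format(v) for v in (name, *synonyms) for t in _NEGATION_TEMPLATES]
        for category, surfaces in buckets.items():
            by_category[category].append(cui)
            for surface in surfaces:
                table.add(surface, cui)
    tabular_sites = [
        (phrase, grades, name_to_cui[concept]) for phrase, grades, concept in _TABULAR_SITES
    ]
    for phrase, grades, cui in tabular_sites:
        for g1 in grades:
            for g2 in grades:
                table.add(f"{phrase} {g1} {g2}", cui)
    return MiniOntologyFixture(
        ontology=ontology,
        lookup_table=table,
        renderings=renderings,
        negated=negated,
        by_category=by_category,
        tabular_sites=tabular_sites,
    )


# ---------------------------------------------------------------------------
# Text assembly
# ---------------------------------------------------------------------------

_OMIM_PREFIXES = (
    "The patient had ",
    "Examination showed ",
    "Clinical features included ",
    "The phenotype included ",
)
_TEXTBOOK_TEMPLATES = (
    "On examination, the patient was noted to have {}.",
    "Neurological assessment revealed {}.",
    "Over the following months the patient developed {}.",
    "The examiner documented {} during the visit.",
    "Careful testing demonstrated {}.",
)
_EHR_TEMPLATES = (
    "Pt with {}.",
    "Exam notable for {}.",
    "{} noted.",
    "Assessment: {}.",
    "Pt seen today with {}.",
    "Neuro: {}.",
)
_EHR_TABULAR_TEMPLATES = ("Motor: {}.", "Reflexes: {}.", "{}")
_NEGATION_SENTENCE_TEMPLATES = ("{}.", "Pt reports {}.", "ROS: {}.")


def _pick(rng: np.random.Generator, items) -> object:
    return items[int(rng.integers(len(items)))]


def _sample_category(rng: np.random.Generator, profile: StyleProfile) -> str:
    u = float(rng.random())
    acc = 0.0
    for category in CATEGORIES:
        acc += profile.category_proportions[category]
        if u < acc:
            return category
    return CATEGORIES[-1]


def _realize(
    category: str, fixture: MiniOntologyFixture, rng: np.random.Generator
) -> tuple[str, str, str | None]:
    """Return (surface, gold category, cui) for one span of ``category``."""
    if category == "TABULAR":
        phrase, grades, cui = _pick(rng, fixture.tabular_sites)
        g1 = _pick(rng, grades)
        g2 = _pick(rng, grades)
        return f"[{phrase} {g1} {g2}]", "TABULAR", cui
    if category == "COMPOUND":
        cuis = fixture.by_category["UNIGRAM"] + fixture.by_category["BIGRAM"]
        chosen = sorted(rng.choice(len(cuis), size=3, replace=False))
        names = [
            fixture.ontology.concepts[cuis[int(i)]].preferred_name for i in chosen
        ]
        return f"{names[0]}, {names[1]}, and {names[2]}", "COMPOUND", None
    cui = _pick(rng, fixture.by_category[category])
    surface = _pick(rng, fixture.renderings[cui][category])
    return surface, category, cui


def _generate_document(
    profile: StyleProfile,
    fixture: MiniOntologyFixture,
    rng: np.random.Generator,
    doc_id: str,
) -> tuple[Document, list[SpanAnnotation]]:
    lo, hi = profile.spans_per_doc
    n_spans = int(rng.integers(lo, hi + 1))
    parts: list[str] = []
    spans: list[SpanAnnotation] = []
    offset = 0

    def emit(text: str) -> None:
        nonlocal offset
        parts.append(text)
        offset += len(text)

    def emit_span(category: str) -> None:
        surface, gold_cat, cui = _realize(category, fixture, rng)
        spans.append(SpanAnnotation(offset, offset + len(surface), gold_cat, cui))
        emit(surface)
        if profile.continuation_rate > 0 and float(rng.random()) < profile.continuation_rate:
            emit(" " + str(_pick(rng, _CONTINUATIONS)))

    remaining = n_spans
    while remaining > 0:
        if parts:
            emit(" ")
        if profile.name == "omim":
            k = min(remaining, 1 + int(rng.integers(3)))
            emit(str(_pick(rng, _OMIM_PREFIXES)))
            categories = [_sample_category(rng, profile) for _ in range(k)]
            for j, category in enumerate(categories):
                if j > 0:
                    emit(", " if j < k - 1 else (" and " if k == 2 else ", and "))
                emit_span(category)
            emit(".")
            remaining -= k
        else:
            category = _sample_category(rng, profile)
            if category == "TABULAR":
                template = str(_pick(rng, _EHR_TABULAR_TEMPLATES))
            elif profile.name == "textbook":
                template = str(_pick(rng, _TEXTBOOK_TEMPLATES))
            else:
                template = str(_pick(rng, _EHR_TEMPLATES))
            before, after = template.split("{}")
            emit(before)
            emit_span(category)
            emit(after)
            remaining -= 1
        if profile.negation_rate > 0 and float(rng.random()) < profile.negation_rate:
            cuis = sorted(fixture.negated)
            cui = str(_pick(rng, cuis))
            mention = str(_pick(rng, fixture.negated[cui]))
            template = str(_pick(rng, _NEGATION_SENTENCE_TEMPLATES))
            emit(" " + template.format(mention))

    doc = Document(doc_id=doc_id, text="".join(parts), style=profile.name)
    return doc, spans


# ---------------------------------------------------------------------------
# Writing noise
# ---------------------------------------------------------------------------


def _splice(
    text: str,
    spans: list[SpanAnnotation],
    start: int,
    end: int,
    replacement: str,
) -> tuple[str, list[SpanAnnotation]] | None:
    """Replace text[start:end]; shift/stretch spans. None if a span straddles."""
    for span in spans:
        inside = span.start <= start and end <= span.end
        outside = span.end <= start or end <= span.start
        if not (inside or outside):
            return None
    delta = len(replacement) - (end - start)
    new_text = text[:start] + replacement + text[end:]
    new_spans: list[SpanAnnotation] = []
    for span in spans:
        if span.end <= start:
            new_spans.append(span)
        elif span.start >= end:
            new_spans.append(
                SpanAnnotation(span.start + delta, span.end + delta, span.category, span.cui)
            )
        else:
            new_spans.append(
                SpanAnnotation(span.start, span.end + delta, span.category, span.cui)
            )
    return new_text, new_spans


def _misspell(word: str, rng: np.random.Generator) -> str:
    """Typographical corruption: swap, drop, substitute, or double a character."""
    if len(word) < 4:
        return word
    op = int(rng.integers(4))
    i = 1 + int(rng.integers(len(word) - 2))
    if op == 0:  # swap adjacent interior characters
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    if op == 1:  # drop one interior character
        return word[:i] + word[i + 1 :]
    if op == 2:  # substitute a random letter
        letter = "abcdefghijklmnopqrstuvwxyz"[int(rng.integers(26))]
        return word[:i] + letter + word[i + 1 :]
    return word[:i] + word[i] + word[i:]  # double a character


def _relabel(text: str, spans: list[SpanAnnotation]) -> list[SpanAnnotation]:
    """Recompute length-based categories after noise changed word counts."""
    out = []
    for span in spans:
        if span.category in ("COMPOUND", "TABULAR"):
            out.append(span)
            continue
        category = categorize_span(tokenize(text[span.start : span.end]))
        out.append(SpanAnnotation(span.start, span.end, category, span.cui))
    return out


def inject_noise(
    doc: Document,
    spans: list[SpanAnnotation],
    misspelling_rate: float = 0.0,
    abbreviation_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Document, list[SpanAnnotation]]:
    """Apply EHR-style writing noise, keeping every span offset exact.

    Misspellings (adjacent-character swap or character drop) hit alphabetic
    words of four or more characters at ``misspelling_rate`` per word;
    abbreviations substitute phrases from the packaged map at
    ``abbreviation_rate`` per occurrence. All span offsets are recomputed and
    length-based categories relabeled where the word count changed. With
    both rates 0 the input is returned unchanged.
    """
    if misspelling_rate == 0.0 and abbreviation_rate == 0.0:
        return doc, spans
    if rng is None:
        rng = np.random.default_rng(0)
    text = doc.text
    spans = list(spans)

    # Abbreviations first (they change word counts); draw decisions
    # left-to-right, apply right-to-left so offsets stay valid.
    edits: list[tuple[int, int, str]] = []
    lowered = text.lower()
    for phrase in sorted(ABBREVIATIONS, key=len, reverse=True):
        pos = 0
        while True:
            idx = lowered.find(phrase, pos)
            if idx == -1:
                break
            pos = idx + 1
            boundary_ok = (idx == 0 or not lowered[idx - 1].isalnum()) and (
                idx + len(phrase) == len(lowered)
                or not lowered[idx + len(phrase)].isalnum()
            )
            if boundary_ok and float(rng.random()) < abbreviation_rate:
                edits.append((idx, idx + len(phrase), ABBREVIATIONS[phrase]))
    for start, end, replacement in sorted(edits, reverse=True):
        result = _splice(text, spans, start, end, replacement)
        if result is not None:
            text, spans = result

    if misspelling_rate > 0.0:
        word_edits: list[tuple[int, int, str]] = []
        for tok in tokenize(text):
            if tok.surface.isalpha() and len(tok.surface) >= 4:
                if float(rng.random()) < misspelling_rate:
                    word_edits.append((tok.start, tok.end, _misspell(tok.surface, rng)))
        for start, end, replacement in sorted(word_edits, reverse=True):
            result = _splice(text, spans, start, end, replacement)
            if result is not None:
                text, spans = result

    new_doc = Document(doc_id=doc.doc_id, text=text, style=doc.style)
    return new_doc, _relabel(text, spans)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(
    profile: StyleProfile,
    fixture: MiniOntologyFixture,
    n_docs: int,
    seed: int,
) -> list[tuple[Document, list[SpanAnnotation]]]:
    """Generate ``n_docs`` gold-annotated documents in the given style.

    Reproducible: document ``i`` draws from substream ``(seed, i)``, so the
    corpus is byte-identical across runs and independent of generation order.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    corpus: list[tuple[Document, list[SpanAnnotation]]] = []
    for i in range(n_docs):
        rng = np.random.default_rng([seed, i])
        doc, spans = _generate_document(
            profile, fixture, rng, doc_id=f"{profile.name}-{seed}-{i:04d}"
        )
        doc, spans = inject_noise(
            doc,
            spans,
            misspelling_rate=profile.misspelling_rate,
            abbreviation_rate=profile.abbreviation_rate,
            rng=rng,
        )
        for span in spans:  # offset integrity guard
            if not doc.text[span.start : span.end].strip():
                raise AssertionError(f"empty span surface in {doc.doc_id}")
        corpus.append((doc, spans))
    return corpus
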