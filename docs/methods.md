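# Methods

## Problem and pipeline

The package addresses sign/symptom extraction for neurology: locate the text
spans of a clinical document that assert a neurological sign or symptom,
classify each span into a seven-category annotation taxonomy, and normalize
it to a concept in a hierarchical neuro-ontology keyed by UMLS-style CUIs.
The pipeline stages are preprocessing → tokenization → sequence labeling →
normalization → stratified evaluation, and an experiment runner composes
them behind a single seeded configuration.

## Span taxonomy

Categories UNIGRAM, BIGRAM, TRIGRAM, TETRAGRAM count the content words of a
span (detached punctuation excluded); EXTENDED covers anything longer than
four words. COMPOUND (several findings in one span) and TABULAR (anatomic
phrase plus paired right/left grades, e.g. `[biceps strength 3 3]`) are
annotation *types*, not lengths, and take precedence over the word count.
Offsets are 0-based half-open character positions, the JSONL convention of
common annotation tools; `text[start:end]` always equals the annotated
surface, and spans within a document may not overlap. Hyphenated terms count
as the number of post-tokenization content tokens.

## Preprocessing and tokenization

`clean_text` removes HTML tags, URLs, e-mail addresses, and characters
outside a clinical whitelist (letters, digits, whitespace, and the
punctuation that carries clinical meaning: grades, brackets, sentence
marks), expands contractions from a packaged fixed map, and collapses
whitespace. It is idempotent. Abbreviations are deliberately left untouched,
and no automatic spelling correction is attempted — misspellings are treated
as a property of the data, not a preprocessing target. The tokenizer splits
on whitespace, detaches punctuation into single-character tokens, keeps
apostrophes inside words, and keeps reflex/strength grades such as `4+`
intact; token offsets always slice back to their surfaces.

## Sequence labeler

Spans are encoded as one BIO label per token over the seven categories plus
O (15 labels). The reference backend is an **averaged structured
perceptron**: emission scores are sums of binary feature weights, transition
scores are learned label-bigram weights, and decoding is Viterbi with a hard
mask that forbids `I-X` after O, sequence start, or a different category —
so every decoded sequence is structurally valid BIO. Features for a token
are the lowercased surfaces at offsets −4…+4 (boundary-padded) — a context
window of four words on either side — plus word shape, 3/4-character
prefixes and suffixes, and indicators for digits, grade tokens, brackets,
and negation cues (*no, not, denies, denied, absent, without, negative*).

Numerical and determinism choices:

* Ties in Viterbi resolve to O first, then the lexicographically smaller
  label (the label inventory is ordered that way, and arg-max takes the
  first maximum), making decoding fully deterministic.
* Training shuffles documents once per epoch from a generator seeded only
  by the `seed` parameter; given (corpus order, epochs, seed) two runs
  produce byte-identical serialized models (versioned JSON with sorted
  keys).
* Gold spans that are not token-aligned are snapped outward to token
  boundaries with a warning; a stray `I-X` in a label sequence decodes as
  `B-X` (repair rule), so decoding is total.
* Labels are predicted jointly (`B-`/`I-` per category) rather than as a
  separate boundary-then-classify step; the joint scheme lets the
  transition matrix veto category switches mid-span.

Optimizer hyperparameters of external neural backends (learning rate 5e-5,
β₁ = 0.9, β₂ = 0.99, 500 warm-up steps, 20,000 steps) are recorded in
`BackendConfig` as adapter defaults only; the built-in labeler does not use
them. Such backends are out of scope here and plug in behind the same
train/predict/serialize contract.

## Normalization

Normalization tries an exact match first: the span surface is case-folded,
whitespace-collapsed, and stripped of edge punctuation, and looked up in the
phrase→CUI table. The exact path guarantees that every table phrase (hence
every ontology synonym) normalizes to its own concept with similarity 1.0.
Otherwise the span is embedded as the renormalized mean of the unit vectors
of its in-vocabulary tokens and scored by cosine similarity against every
table phrase. Choices:

* Raw cosine may be negative for arbitrary vectors; scores are clamped at 0
  so the similarity scale is [0, 1] (0 least similar, 1 most similar).
* A phrase with no in-vocabulary token embeds as the zero vector and scores
  0 everywhere.
* Ties break by highest similarity, then lexicographically smallest phrase,
  then smallest CUI.
* Below the no-match threshold (default 0.5, configurable; there is no
  canonical value for this quantity) the result carries no CUI but keeps
  the ranked candidate list.
* COMPOUND and TABULAR spans may denote several concepts; the normalizer
  returns its ranked candidates and leaves multi-concept resolution to the
  caller.

Word vectors are pluggable: plain-text word2vec-format tables can be loaded,
and `make_hash_vectors` provides deterministic pseudo-random unit vectors
(each token's vector is seeded by a stable hash of the token and a seed) for
tests and synthetic experiments. Hash vectors carry no distributional
semantics; with them, vector-search accuracy reflects token overlap only,
which is exactly what the synthetic experiments need and nothing more.

## Evaluation

Span matching is strict by default — a true positive requires exact
(start, end, category) — because that is the standard span-level NER
convention; `boundary` mode (exact offsets, category ignored) is provided
for analyses that separate localization from classification. P, R, and F are
reported on the percent scale; a zero denominator yields 0 by convention.
Display rounding is half-up to one decimal, computed on the percent scale.
Per-category rows come from per-category counts; the micro average comes
from summed counts. Agreement between two annotations of the same text is
computed at the token level on binary in-span indicators, reporting observed
agreement p_o, expected agreement p_e from the marginal label frequencies,
and κ = (p_o − p_e)/(1 − p_e); the degenerate case p_e = 1 defines κ = 1 if
agreement is perfect and 0 otherwise.

## Synthetic corpus generator

The generator is first-class, tested code: it defines the study conditions
under which every pipeline property is demonstrated. Each style profile
fixes category proportions over the seven span types, a spans-per-document
range, and noise rates:

| profile  | unigram+bigram | extended | tabular | misspell/word | abbrev/occurrence | negation/sentence | continuation/span |
|----------|---------------:|---------:|--------:|--------------:|------------------:|------------------:|------------------:|
| omim     | 0.75           | 0.05     | 0       | 0             | 0                 | 0                 | 0                 |
| textbook | 0.34           | 0.30     | 0       | 0             | 0                 | 0                 | 0.15              |
| ehr      | 0.40           | 0.20     | 0.10    | 0.10          | 0.4               | 0.25              | 0.3               |

The proportions realize the documented contrasts between the three corpus
styles — clinical-synopsis writing is dominated by one- and two-word concept
names with the shortest annotations, textbook writing is descriptive with
many extended spans, EHR writing is noisy and is the only style containing
tabular findings — without reproducing any particular measured histogram,
which is not available. Noise rates for the EHR profile were chosen so that
the generated corpora exhibit the documented difficulty ordering (EHR
hardest, clinical synopses easiest); they are fixtures, not estimates of
real note statistics.

Mechanics worth knowing:

* The mini-ontology fixture holds 57 concepts under the six exam-category
  roots, each with a set of surface renderings per span category (direct
  names and synonyms, adjective/auxiliary expansions, and enumerated
  descriptive variants). Every rendering and every tabular surface is a key
  of the generated lookup table, so noise-free corpora are perfectly
  normalizable through the exact-match path. COMPOUND spans combine three
  concept names and carry no single CUI.
* Negated mentions ("denies tremor", "without headache") are emitted
  **unannotated**: an absent finding is not a finding, and the recognizer
  must learn from context to skip it. The true prevalence of negated
  mentions in real notes is unknown; the rate is configurable.
* Extended descriptive spans come in tailed ("ataxia was quite severe
  today") and tail-less multi-word variants, and an unannotated
  continuation phrase drawn from the same vocabulary as the tails may
  follow any span. The end boundary of a long descriptive span is therefore
  genuinely ambiguous from context — emulating the variable extent of
  free-text description annotations — which is what makes F decline with
  span length in the generated data, as it does in real corpora.
* Misspellings (adjacent swap, drop, random substitution, doubling of a
  character, on words of ≥4 letters) and abbreviation substitutions (a
  packaged map, e.g. *relative afferent pupil defect* → *RAPD*) are applied
  with exact offset recomputation, and length-based categories are
  relabeled where an edit changed the word count.
* Document *i* of a corpus draws from the independent substream
  `(seed, i)`, so corpora are byte-identical across runs and document order
  does not perturb content.

What passing tests on these corpora do **not** show: performance on real
clinical language. The generator has a closed vocabulary, templated syntax,
no anaphora, no section structure, and no genuinely novel descriptions, so
absolute scores are far above what any real corpus yields; only the
relative patterns (degradation with span length, style separation,
difficulty ordering) are meaningful, and those are the properties the test
suite asserts.

## Experiment runner

`run_experiment` executes generate/load → 80/20 split → train → predict →
normalize → evaluate and writes the report (CSV and JSON), a per-span
normalization CSV, and a run log recording the full configuration. The
split is by document, seeded (train size = round(fraction·n)); splitting by
annotation instance would leak document context between train and test.
Outputs are a pure function of config + seed. The problem sizes used by the
test suite and the acceptance script (300–500 documents, 8–10 epochs,
3–5 seeds) were chosen as the smallest at which the measured properties are
stable across seeds.

## Known limitations

* The reference labeler is linear; it demonstrates the pipeline's
  contracts and qualitative behavior but is not a state-of-the-art
  recognizer for real notes.
* Sentence splitting, spelling correction, word-sense disambiguation, and
  multi-CUI decomposition of compound spans are out of scope.
* Hash vectors ignore distributional similarity; real embedding tables
  should be loaded for any application beyond the synthetic experiments.
* Overlapping gold spans are rejected rather than resolved.
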