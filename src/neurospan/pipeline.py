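"""End-to-end experiment runner: preprocess, split, train, predict, normalize, evaluate.

An experiment is fully described by an :class:`ExperimentConfig` (a seeded
corpus source, an 80/20 document-level split, tagger epochs, a normalization
threshold, and an evaluation mode). Given the same config and seed, two runs
produce byte-identical outputs: an evaluation report (CSV + JSON), a per-span
normalization CSV, and a plain-text run log.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .corpus import Document, SpanAnnotation, read_annotations
from .evaluate import EvalReport, evaluate_by_category
from .normalize import ConceptNormalizer, make_hash_vectors
from .ontology import load_lookup_table, load_ontology
from .synthesis import generate_corpus, make_fixture, style_profile
from .tagging import SpanTagger

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "split_corpus", "run_experiment"]

Corpus = list[tuple[Document, list[SpanAnnotation]]]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    style: str | None = None  # generate a synthetic corpus of this style...
    corpus_path: str | None = None  # ...or load an annotated JSONL corpus
    ontology_path: str | None = None
    lookup_path: str | None = None
    n_docs: int = 500
    split_fraction: float = 0.8
    seed: int = 0
    epochs: int = 10
    threshold: float = 0.5
    eval_mode: str = "strict"
    vector_dim: int = 32
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie strictly between 0 and 1")
        if self.style is None and self.corpus_path is None:
            raise ValueError("config needs either a style or a corpus path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(**data)


def split_corpus(
    corpus: Corpus, fraction: float = 0.8, seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Seeded document-level shuffle-and-split; train size = round(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie strictly between 0 and 1")
    n = len(corpus)
    if n < 2:
        raise ValueError("corpus must contain at least 2 documents to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [corpus[int(i)] for i in order[:n_train]]
    test = [corpus[int(i)] for i in order[n_train:]]
    return train, test


def _write_normalization_csv(
    path: Path,
    pred_docs: Corpus,
    normalizer: ConceptNormalizer,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["doc_id", "start", "end", "span_text", "cui", "concept_name", "similarity"]
        )
        for doc, spans in pred_docs:
            for span in spans:
                surface = doc.text[span.start : span.end]
                result = normalizer.normalize(surface)
                writer.writerow(
                    [
                        doc.doc_id,
                        span.start,
                        span.end,
                        surface,
                        result.cui or "",
                        result.concept_name or "",
                        f"{result.similarity:.4f}",
                    ]
                )


def run_experiment(config: ExperimentConfig) -> EvalReport:
    """Run the full pipeline and write report, normalization CSV, and run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "corpus"
    try:
        if config.style is not None:
            fixture = make_fixture()
            corpus = generate_corpus(
                style_profile(config.style), fixture, config.n_docs, config.seed
            )
            ontology, table = fixture.ontology, fixture.lookup_table
        else:
            corpus = read_annotations(config.corpus_path)
            ontology = (
                load_ontology(config.ontology_path) if config.ontology_path else None
            )
            table = (
                load_lookup_table(config.lookup_path, ontology)
                if config.lookup_path
                else None
            )

        stage = "split"
        train, test = split_corpus(corpus, config.split_fraction, config.seed)

        stage = "train"
        tagger = SpanTagger(epochs=config.epochs, seed=config.seed)
        tagger.fit([doc for doc, _ in train], [spans for _, spans in train])

        stage = "predict"
        predictions = tagger.predict([doc for doc, _ in test])
        pred_docs: Corpus = [
            (doc, spans) for (doc, _), spans in zip(test, predictions)
        ]

        stage = "normalize"
        if table is not None:
            vocabulary = sorted(
                {tok for phrase in table.entries for tok in phrase.split()}
            )
            vectors = make_hash_vectors(vocabulary, d=config.vector_dim, seed=config.seed)
            normalizer = ConceptNormalizer(threshold=config.threshold).fit(
                table, ontology=ontology, vectors=vectors
            )
            _write_normalization_csv(outdir / "normalization.csv", pred_docs, normalizer)

        stage = "evaluate"
        report = evaluate_by_category(test, pred_docs, mode=config.eval_mode)
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "report.csv", "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerows(report.to_csv_rows())
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    log_lines = ["neurospan run"] + [
        f"{key} = {value}" for key, value in sorted(asdict(config).items())
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("experiment complete: micro F = %.1f", report.micro.f)
    return report
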