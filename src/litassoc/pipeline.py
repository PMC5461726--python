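"""End-to-end orchestration: parse -> annotate -> abbreviation filter ->
extract -> document-level filters -> aggregate -> score -> rank.

The stage order is fixed; the run report records input/output counts per
stage and the batch boosting-up factor, so two runs with identical config
and input produce byte-identical evidence output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import abbrev, associations, ner, scoring
from .associations import DEFAULT_RESEARCH_TYPES
from .docmodel import Document
from .lexicon import Lexicon
from .scoring import DocumentScore, WeightConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    target_lexicon: Lexicon
    disease_lexicon: Lexicon
    weights: WeightConfig = field(default_factory=WeightConfig)
    research_types: frozenset[str] | set[str] = DEFAULT_RESEARCH_TYPES
    enzyme_terms: frozenset[str] | set[str] = frozenset()
    disease_keywords: frozenset[str] | set[str] = abbrev.DEFAULT_DISEASE_KEYWORDS
    target_keywords: frozenset[str] | set[str] = abbrev.DEFAULT_TARGET_KEYWORDS
    context_keywords: frozenset[str] | set[str] = abbrev.DEFAULT_CONTEXT_KEYWORDS
    apply_min_occurrence: bool = True
    cutoff: int = 25


@dataclass
class PipelineResult:
    scores: list[DocumentScore]
    records: list[associations.AssociationRecord]
    boosting_up_factor: float
    report: dict

    def evidence_lines(self) -> list[str]:
        """Evidence JSON lines: one object per scored (doc, target, disease)."""
        return [
            json.dumps({
                "doc_id": s.doc_id, "target_id": s.target_id,
                "disease_id": s.disease_id, "formula": s.formula_used.value,
                "s1": s.s1, "s2": s.s2, "boost": self.boosting_up_factor,
                "confidence": s.confidence,
            }, sort_keys=True)
            for s in self.scores
        ]


def run_pipeline(config: PipelineConfig, documents: Iterable[Document]) -> PipelineResult:
    """Run every stage over ``documents`` and return scored associations."""
    docs = list(documents)
    report: dict = {"stages": []}

    def _stage(name: str, n_in: int, n_out: int) -> None:
        report["stages"].append({"stage": name, "in": n_in, "out": n_out})
        logger.info("stage %-18s %6d -> %d", name, n_in, n_out)

    research = associations.filter_article_type(docs, config.research_types)
    _stage("article_type", len(docs), len(research))
    doc_map = {d.doc_id: d for d in research}

    mentions: list[ner.Mention] = []
    for doc in research:
        try:
            mentions.extend(ner.annotate(doc, config.target_lexicon,
                                         config.disease_lexicon))
        except Exception as exc:  # pragma: no cover - defensive per-doc guard
            logger.error("annotate failed for document %s: %s", doc.doc_id, exc)
            raise
    _stage("annotate", len(research), len(mentions))

    filtered_mentions: list[ner.Mention] = []
    n_decisions = 0
    for doc in research:
        kept, decisions = abbrev.filter_document_mentions(
            doc, mentions, config.target_lexicon, config.disease_lexicon,
            enzyme_terms=config.enzyme_terms,
            disease_keywords=config.disease_keywords,
            target_keywords=config.target_keywords,
            context_keywords=config.context_keywords)
        filtered_mentions.extend(kept)
        n_decisions += len(decisions)
    _stage("abbrev_filter", len(mentions), len(filtered_mentions))
    report["abbrev_decisions"] = n_decisions

    events = associations.extract_events(filtered_mentions, doc_map)
    _stage("extract_events", len(filtered_mentions), len(events))

    kept_events = associations.filter_excluded_sections(events)
    _stage("excluded_sections", len(events), len(kept_events))

    records = associations.aggregate(kept_events, filtered_mentions, doc_map)
    _stage("aggregate", len(kept_events), len(records))

    if config.apply_min_occurrence:
        records_final = associations.filter_min_occurrence(records)
    else:
        records_final = records
    _stage("min_occurrence", len(records), len(records_final))

    scores, boost = scoring.score_records(records_final, config.weights)
    _stage("score", len(records_final), len(scores))
    report["boosting_up_factor"] = boost
    return PipelineResult(scores=scores, records=records_final,
                          boosting_up_factor=boost, report=report)


def rankings_by_pair(scores: Sequence[DocumentScore]) -> dict[tuple[str, str], list[str]]:
    """Ranked doc-id lists per (target, disease) pair, for evaluation."""
    pairs = sorted({(s.target_id, s.disease_id) for s in scores})
    return {
        pair: [s.doc_id for s in scoring.rank_documents(scores, *pair)]
        for pair in pairs
    }
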