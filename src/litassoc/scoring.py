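"""Document confidence scoring and ranking for target-disease associations.

Each (document, target, disease) triple receives a confidence score that
weights where in the document the pair co-occurs:

* S1 (abstracts): sentence-location-weighted co-occurrence counts plus a
  small bonus of 0.2 per target mention in the abstract,
      S1 = Σ_loc w_loc · #assoc_loc + 0.2 · #gene-in-abstract,
  with default location weights first/second = 2, last = 5, other = 3.
* S2 (full-text body): section-weighted counts,
      S2 = Σ_sec w_sec · #assoc_sec,
  with default section weights title = 10; results/figure/table = 5;
  discussion/conclusion = 2; introduction/case study/appendix/other = 1.
  The abstract is excluded from S2 (it is scored by S1).
* CS2 = S1 + S2 scores full-text articles.
* CS1 = w_title · #assoc_title + S1 + boosting-up factor scores
  abstract-only records, where the boosting-up factor — the median of all
  open-access full-text body scores (S2) in the batch — lifts abstract
  scores onto the full-text scale.

Documents are ranked per association by descending confidence, ties broken
by ascending document id.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .docmodel import AbstractLocation, EXCLUDED_ZONES, ZoneLabel
from .associations import AssociationRecord


def _default_sentence_location_weights() -> dict[AbstractLocation, float]:
    return {
        AbstractLocation.FIRST_OR_SECOND: 2.0,
        AbstractLocation.LAST: 5.0,
        AbstractLocation.OTHER: 3.0,
    }


def _default_section_weights() -> dict[ZoneLabel, float]:
    return {
        ZoneLabel.TITLE: 10.0,
        ZoneLabel.RESULTS: 5.0,
        ZoneLabel.FIGURE: 5.0,
        ZoneLabel.TABLE: 5.0,
        ZoneLabel.DISCUSSION: 2.0,
        ZoneLabel.CONCLUSION: 2.0,
        ZoneLabel.INTRODUCTION: 1.0,
        ZoneLabel.CASE_STUDY: 1.0,
        ZoneLabel.APPENDIX: 1.0,
        ZoneLabel.OTHER: 1.0,
    }


@dataclass
class WeightConfig:
    """Scoring weights; defaults are the published heuristic values."""

    sentence_location_weights: dict[AbstractLocation, float] = field(
        default_factory=_default_sentence_location_weights)
    section_weights: dict[ZoneLabel, float] = field(
        default_factory=_default_section_weights)
    gene_abstract_coefficient: float = 0.2

    def section_weight(self, label: ZoneLabel) -> float:
        # unknown non-excluded zones fall back to the catch-all weight
        return self.section_weights.get(label, self.section_weights[ZoneLabel.OTHER])


class Formula(str, Enum):
    CS1 = "CS1"
    CS2 = "CS2"


@dataclass(frozen=True)
class DocumentScore:
    doc_id: str
    target_id: str
    disease_id: str
    s1: float
    s2: float
    boosting_up_factor: float
    confidence: float
    formula_used: Formula


def score_s1(record: AssociationRecord, weights: WeightConfig | None = None) -> float:
    """Abstract score: location-weighted counts plus the gene-in-abstract bonus."""
    w = weights or WeightConfig()
    total = sum(
        w.sentence_location_weights[loc] * n
        for loc, n in record.count_by_abstract_location.items()
    )
    return total + record.gene_abstract_mention_count * w.gene_abstract_coefficient


def score_s2(record: AssociationRecord, weights: WeightConfig | None = None) -> float:
    """Body score: section-weighted counts over all non-abstract zones.

    The title is scored here (weight 10) for full-text documents; zones
    excluded by the section filter contribute nothing by construction.
    """
    w = weights or WeightConfig()
    return sum(
        w.section_weight(zone) * n
        for zone, n in record.count_by_zone.items()
        if zone != ZoneLabel.ABSTRACT and zone not in EXCLUDED_ZONES
    )


def boosting_up_factor(body_scores: Sequence[float]) -> float:
    """Median of the batch's open-access full-text body (S2) scores; 0 when
    the batch has none."""
    if not body_scores:
        return 0.0
    return float(statistics.median(body_scores))


def score_cs1(record: AssociationRecord, weights: WeightConfig | None = None,
              boost: float = 0.0) -> DocumentScore:
    """Confidence for an abstract-only record:
    w_title · title pairs + S1 + boosting-up factor."""
    if record.is_fulltext:
        raise ValueError("CS1 applies to abstract-only records")
    if record.is_fulltext is None and record.body_count > 0:
        raise ValueError("CS1 applies to abstract-only records (body counts present)")
    w = weights or WeightConfig()
    s1 = score_s1(record, w)
    title_term = w.section_weight(ZoneLabel.TITLE) * record.title_pair_count
    return DocumentScore(
        doc_id=record.doc_id, target_id=record.target_id, disease_id=record.disease_id,
        s1=s1, s2=0.0, boosting_up_factor=boost,
        confidence=title_term + s1 + boost, formula_used=Formula.CS1,
    )


def score_cs2(record: AssociationRecord, weights: WeightConfig | None = None) -> DocumentScore:
    """Confidence for a full-text record: S1 + S2."""
    if record.is_fulltext is False:
        raise ValueError("CS2 applies to full-text records")
    w = weights or WeightConfig()
    s1 = score_s1(record, w)
    s2 = score_s2(record, w)
    return DocumentScore(
        doc_id=record.doc_id, target_id=record.target_id, disease_id=record.disease_id,
        s1=s1, s2=s2, boosting_up_factor=0.0,
        confidence=s1 + s2, formula_used=Formula.CS2,
    )


def score_records(
    records: Sequence[AssociationRecord],
    weights: WeightConfig | None = None,
) -> tuple[list[DocumentScore], float]:
    """Score a batch: CS2 for full-text records, CS1 (with the batch
    boosting-up factor) for abstract-only records. Returns (scores, boost)."""
    w = weights or WeightConfig()
    fulltext = [r for r in records if r.is_fulltext or (r.is_fulltext is None and r.body_count > 0)]
    fulltext_ids = {id(r) for r in fulltext}
    abstracts = [r for r in records if id(r) not in fulltext_ids]
    boost = boosting_up_factor([score_s2(r, w) for r in fulltext])
    scores = [score_cs2(r, w) for r in fulltext]
    scores += [score_cs1(r, w, boost) for r in abstracts]
    scores.sort(key=lambda s: (s.target_id, s.disease_id, s.doc_id))
    return scores, boost


def rank_documents(
    scores: Sequence[DocumentScore],
    target_id: str,
    disease_id: str,
) -> list[DocumentScore]:
    """Rank one association's documents by descending confidence; ties broken
    by ascending doc_id. Output is a permutation of the pair's input scores."""
    pair_scores = [s for s in scores
                   if s.target_id == target_id and s.disease_id == disease_id]
    return sorted(pair_scores, key=lambda s: (-s.confidence, s.doc_id))
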