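"""Sentence-level target-disease co-occurrence extraction and filtering.

A co-occurrence event is one sentence containing at least one mention of a
target and one of a disease. Three document-level filters reduce the noise
inherent to co-occurrence extraction, applied in a fixed order:

  1. article type — only research articles survive (reviews and case
     reports restate prior knowledge);
  2. excluded sections — events in methods, references, acknowledgements,
     competing interests, author contributions and supplementary material
     are discarded;
  3. minimum occurrence — a pair seen exactly once in the body and never in
     the title or abstract is discarded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .docmodel import (AbstractLocation, Document, EXCLUDED_ZONES, ZoneLabel,
                       abstract_location)
from .lexicon import EntityKind
from .ner import Mention

logger = logging.getLogger(__name__)

DEFAULT_RESEARCH_TYPES = frozenset({"research-article", "research"})


@dataclass(frozen=True)
class CooccurrenceEvent:
    doc_id: str
    target_id: str
    disease_id: str
    zone_label: ZoneLabel
    sentence_index: int
    abstract_location_class: AbstractLocation | None = None


@dataclass
class AssociationRecord:
    """Per-document aggregate of co-occurrence counts for one pair."""

    doc_id: str
    target_id: str
    disease_id: str
    count_by_zone: dict[ZoneLabel, int] = field(default_factory=dict)
    count_by_abstract_location: dict[AbstractLocation, int] = field(default_factory=dict)
    gene_abstract_mention_count: int = 0
    title_pair_count: int = 0
    is_fulltext: bool | None = None

    @property
    def abstract_count(self) -> int:
        return self.count_by_zone.get(ZoneLabel.ABSTRACT, 0)

    @property
    def body_count(self) -> int:
        """Events outside the title and abstract (captions included)."""
        return sum(n for z, n in self.count_by_zone.items()
                   if z not in (ZoneLabel.TITLE, ZoneLabel.ABSTRACT))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.target_id, self.disease_id)


def extract_events(
    mentions: list[Mention],
    documents: Mapping[str, Document] | None = None,
) -> list[CooccurrenceEvent]:
    """One event per sentence per distinct (target_id, disease_id) pair.

    Mention multiplicity inside a sentence does not multiply events.
    ``documents`` (doc_id -> Document) supplies abstract lengths so abstract
    events carry their sentence-location class.
    """
    by_sentence: dict[tuple[str, ZoneLabel, int], tuple[set[str], set[str]]] = {}
    for m in mentions:
        key = (m.doc_id, m.zone_label, m.sentence_index)
        targets, diseases = by_sentence.setdefault(key, (set(), set()))
        (targets if m.entity_kind == EntityKind.TARGET else diseases).add(m.identifier)

    events: list[CooccurrenceEvent] = []
    for (doc_id, zone_label, sent_idx) in sorted(by_sentence,
                                                 key=lambda k: (k[0], k[1].value, k[2])):
        targets, diseases = by_sentence[(doc_id, zone_label, sent_idx)]
        if not targets or not diseases:
            continue
        loc = None
        if zone_label == ZoneLabel.ABSTRACT:
            n = None
            if documents is not None and doc_id in documents:
                zone = documents[doc_id].zone(ZoneLabel.ABSTRACT)
                n = len(zone.sentences) if zone else None
            loc = abstract_location(sent_idx, n) if n else AbstractLocation.OTHER
        for t in sorted(targets):
            for d in sorted(diseases):
                events.append(CooccurrenceEvent(doc_id, t, d, zone_label, sent_idx, loc))
    return events


def filter_article_type(
    documents: Iterable[Document],
    research_types: frozenset[str] | set[str] = DEFAULT_RESEARCH_TYPES,
) -> list[Document]:
    """Keep research articles only; documents with no article type are dropped."""
    allowed = {t.lower() for t in research_types}
    kept: list[Document] = []
    for doc in documents:
        if not doc.article_type:
            logger.warning("document %s has no article_type; dropped", doc.doc_id)
            continue
        if doc.article_type.lower() in allowed:
            kept.append(doc)
        else:
            logger.debug("document %s dropped by article-type filter (%s)",
                         doc.doc_id, doc.article_type)
    return kept


def filter_excluded_sections(events: list[CooccurrenceEvent]) -> list[CooccurrenceEvent]:
    """Drop events occurring in excluded zones (methods, references, ...)."""
    return [e for e in events if e.zone_label not in EXCLUDED_ZONES]


def aggregate(
    events: list[CooccurrenceEvent],
    mentions: list[Mention],
    documents: Mapping[str, Document] | None = None,
) -> list[AssociationRecord]:
    """Aggregate events into per-(document, pair) association records.

    ``gene_abstract_mention_count`` counts target-kind abstract mentions of
    the record's target (mention-level, not sentence-level); the full-text
    flag is taken from ``documents`` when available.
    """
    grouped: dict[tuple[str, str, str], list[CooccurrenceEvent]] = {}
    for e in events:
        grouped.setdefault((e.doc_id, e.target_id, e.disease_id), []).append(e)

    gene_abs: Counter[tuple[str, str]] = Counter()
    for m in mentions:
        if m.entity_kind == EntityKind.TARGET and m.zone_label == ZoneLabel.ABSTRACT:
            gene_abs[(m.doc_id, m.identifier)] += 1

    records: list[AssociationRecord] = []
    for (doc_id, target_id, disease_id) in sorted(grouped):
        evs = grouped[(doc_id, target_id, disease_id)]
        count_by_zone: dict[ZoneLabel, int] = Counter()
        count_by_loc: dict[AbstractLocation, int] = Counter()
        for e in evs:
            count_by_zone[e.zone_label] += 1
            if e.zone_label == ZoneLabel.ABSTRACT and e.abstract_location_class:
                count_by_loc[e.abstract_location_class] += 1
        is_fulltext = None
        if documents is not None and doc_id in documents:
            is_fulltext = documents[doc_id].is_open_access_fulltext
        records.append(AssociationRecord(
            doc_id=doc_id, target_id=target_id, disease_id=disease_id,
            count_by_zone=dict(count_by_zone),
            count_by_abstract_location=dict(count_by_loc),
            gene_abstract_mention_count=gene_abs[(doc_id, target_id)],
            title_pair_count=count_by_zone.get(ZoneLabel.TITLE, 0),
            is_fulltext=is_fulltext,
        ))
    return records


def filter_min_occurrence(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Drop records whose pair occurs exactly once in the body and nowhere in
    the title or abstract; abstract-only records always pass."""
    kept = []
    for r in records:
        if r.body_count == 1 and r.title_pair_count == 0 and r.abstract_count == 0:
            logger.debug("record (%s, %s, %s) dropped by min-occurrence filter",
                         r.doc_id, r.target_id, r.disease_id)
            continue
        kept.append(r)
    return kept
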