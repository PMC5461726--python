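"""False-positive abbreviation filtering for annotated mentions.

Short gene symbols and disease acronyms are highly ambiguous: "ALS" may be
amyotrophic lateral sclerosis or advanced life support. Candidates are
harvested from the classic short-form pattern "X... Y... Z... (XYZ)" — an
all-uppercase parenthesized token shorter than 6 characters that the
annotator tagged as a target or disease — and each candidate is kept only
if a keep rule fires; a dropped candidate suppresses every same-surface,
same-kind mention in its document.

Keep rules for disease candidates:
  D1  another lexicon surface of the same identifier occurs in the document;
  D2  the extracted long form contains a disease-describing keyword.

Keep rules for gene/protein candidates:
  G1  the short form occurs more than 3 times in the document body
      (open-access full text only);
  G2  the long form matches a known target surface or enzyme name;
  G3  the long form ends in -ase/-ases or contains a target-describing keyword;
  G4  enough sentences (3 in full text, 2 in abstracts) contain the short
      form together with a context keyword and a disease mention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .docmodel import Document, ZoneLabel
from .lexicon import EntityKind, Lexicon
from .ner import Mention

logger = logging.getLogger(__name__)

MAX_SHORT_FORM_LEN = 5  # "length < 6"

#: Keywords that describe a disease, checked against the extracted long form.
DEFAULT_DISEASE_KEYWORDS = frozenset({
    "disease", "disorder", "syndrome", "defect", "deficiency",
    "cancer", "carcinoma", "tumor", "tumour", "infection",
})

#: Keywords that describe a target name, checked against the long form.
DEFAULT_TARGET_KEYWORDS = frozenset({
    "factor", "receptor", "gene", "protein", "enzyme",
    "kinase", "antigen", "ligand",
})

#: Context keywords for the sentence-evidence rule (G4).
DEFAULT_CONTEXT_KEYWORDS = frozenset({
    "mutation", "SNP", "variation", "gene", "inhibit", "variant",
    "polymorphism", "mutant", "isoform", "protein", "enzyme", "activate",
    "antibody", "transcription", "tumor suppressor", "express",
    "overexpress", "regulator", "receptor", "oncogene",
})

_SHORT_FORM_RE = re.compile(r"\(([^()\s]{1,10})\)")


@dataclass(frozen=True)
class AbbrevCandidate:
    short_form: str
    long_form: str
    entity_kind: EntityKind
    doc_id: str
    zone_label: ZoneLabel
    sentence_index: int


@dataclass(frozen=True)
class FilterDecision:
    candidate: AbbrevCandidate
    kept: bool
    rule_fired: str  # "D1","D2","G1".."G4" or "none"


def _is_short_form(token: str) -> bool:
    if not (1 <= len(token) <= MAX_SHORT_FORM_LEN):
        return False
    if not any(c.isupper() for c in token):
        return False
    return not any(c.islower() for c in token)


def _align_long_form(window_words: list[str], short_form: str) -> list[str] | None:
    """Schwartz–Hearst-style alignment: shortest window suffix whose words
    contain the short-form characters in order, the first character at a
    word start. Returns None when no alignment exists."""
    letters = [c.lower() for c in short_form if c.isalnum()]
    if not letters:
        return None
    for start in range(len(window_words) - 1, -1, -1):
        cand = window_words[start:]
        text = " ".join(cand).lower()
        if not cand[0] or cand[0][0].lower() != letters[0]:
            continue
        pos = 0
        ok = True
        for ch in letters:
            found = text.find(ch, pos)
            if found < 0:
                ok = False
                break
            pos = found + 1
        if ok:
            return cand
    return None


def extract_long_form(sentence_text: str, paren_open: int, short_form: str) -> str:
    """Long form preceding "(", from a window of up to len(short)+1 words."""
    before = sentence_text[:paren_open].strip()
    words = before.split()
    window = words[-(len(short_form) + 1):]
    aligned = _align_long_form(window, short_form)
    chosen = aligned if aligned is not None else window
    return " ".join(chosen).strip(" ,;:")


def find_candidates(document: Document, mentions: list[Mention]) -> list[AbbrevCandidate]:
    """Harvest short-form/long-form abbreviation candidates from a document.

    A parenthesized all-uppercase token of length < 6 that carries a target
    or disease mention at that position yields one candidate per annotated
    kind; the long form is extracted from the words before the parenthesis.
    """
    by_sentence: dict[tuple[ZoneLabel, int], list[Mention]] = {}
    for m in mentions:
        if m.doc_id == document.doc_id:
            by_sentence.setdefault((m.zone_label, m.sentence_index), []).append(m)

    candidates: list[AbbrevCandidate] = []
    seen: set[tuple[str, EntityKind]] = set()
    for zone in document.zones:
        for sent in zone.sentences:
            for match in _SHORT_FORM_RE.finditer(sent.text):
                token = match.group(1)
                if not _is_short_form(token):
                    continue
                span = (match.start(1), match.end(1))
                kinds = {
                    m.entity_kind
                    for m in by_sentence.get((zone.label, sent.index_in_zone), [])
                    if m.char_span == span and m.surface == token
                }
                if not kinds:
                    continue
                long_form = extract_long_form(sent.text, match.start(), token)
                for kind in sorted(kinds, key=lambda k: k.value):
                    key = (token, kind)
                    if key in seen:  # first occurrence defines the candidate
                        continue
                    seen.add(key)
                    candidates.append(AbbrevCandidate(
                        short_form=token, long_form=long_form, entity_kind=kind,
                        doc_id=document.doc_id, zone_label=zone.label,
                        sentence_index=sent.index_in_zone))
    return candidates


def _word_occurrences(text: str, word: str) -> int:
    return len(re.findall(rf"(?<![0-9A-Za-z]){re.escape(word)}(?![0-9A-Za-z])", text))


def filter_disease_candidate(
    candidate: AbbrevCandidate,
    document: Document,
    disease_lexicon: Lexicon,
    disease_keywords: frozenset[str] | set[str] = DEFAULT_DISEASE_KEYWORDS,
) -> FilterDecision:
    """Keep a disease abbreviation if a lexicon long form of the same
    identifier occurs in the document (D1) or the extracted long form
    contains a disease keyword (D2)."""
    if candidate.entity_kind != EntityKind.DISEASE:
        raise ValueError("candidate is not a disease abbreviation")
    doc_text = document.text.lower()
    # D1: any other surface sharing the candidate's identifier(s) in the document
    for ident in sorted(disease_lexicon.identifiers_for(candidate.short_form)):
        for surface in disease_lexicon.surfaces_for(ident):
            if surface.lower() != candidate.short_form.lower() and surface.lower() in doc_text:
                return FilterDecision(candidate, True, "D1")
    # D2: long form carries a disease-describing keyword
    long_lower = candidate.long_form.lower()
    if any(k.lower() in long_lower for k in disease_keywords):
        return FilterDecision(candidate, True, "D2")
    return FilterDecision(candidate, False, "none")


def filter_gene_candidate(
    candidate: AbbrevCandidate,
    document: Document,
    target_lexicon: Lexicon,
    enzyme_terms: frozenset[str] | set[str] = frozenset(),
    target_keywords: frozenset[str] | set[str] = DEFAULT_TARGET_KEYWORDS,
    context_keywords: frozenset[str] | set[str] = DEFAULT_CONTEXT_KEYWORDS,
    mentions: list[Mention] | None = None,
) -> FilterDecision:
    """Keep a gene/protein abbreviation if any of rules G1-G4 fires (checked
    in order; the first firing rule is recorded).

    ``mentions`` (post-annotation, same document) locate disease mentions for
    rule G4; with no mentions supplied G4 cannot fire.
    """
    if candidate.entity_kind != EntityKind.TARGET:
        raise ValueError("candidate is not a target abbreviation")
    short = candidate.short_form

    # G1: short form more than 3 times in the body, OA full text only
    if document.is_open_access_fulltext:
        body_count = sum(_word_occurrences(z.text, short) for z in document.body_zones)
        if body_count > 3:
            return FilterDecision(candidate, True, "G1")

    # G2: long form is a known target surface or enzyme name
    long_lower = candidate.long_form.lower()
    target_surfaces = {s.lower() for s in target_lexicon.match_index}
    if long_lower in target_surfaces or long_lower in {t.lower() for t in enzyme_terms}:
        return FilterDecision(candidate, True, "G2")

    # G3: -ase/-ases suffix, or a target-describing keyword in the long form
    last_word = long_lower.split()[-1] if long_lower.split() else ""
    if last_word.endswith("ase") or last_word.endswith("ases") or \
            any(k.lower() in long_lower for k in target_keywords):
        return FilterDecision(candidate, True, "G3")

    # G4: sentence-level co-evidence with context keywords and a disease name
    threshold = 3 if document.is_open_access_fulltext else 2
    disease_sentences: set[tuple[ZoneLabel, int]] = set()
    if mentions:
        disease_sentences = {
            (m.zone_label, m.sentence_index) for m in mentions
            if m.doc_id == document.doc_id and m.entity_kind == EntityKind.DISEASE
        }
    n_evidence = 0
    for zone in document.zones:
        for sent in zone.sentences:
            if (zone.label, sent.index_in_zone) not in disease_sentences:
                continue
            if _word_occurrences(sent.text, short) == 0:
                continue
            low = sent.text.lower()
            if any(k.lower() in low for k in context_keywords):
                n_evidence += 1
    if n_evidence >= threshold:
        return FilterDecision(candidate, True, "G4")

    return FilterDecision(candidate, False, "none")


def apply_decisions(mentions: list[Mention], decisions: list[FilterDecision]) -> list[Mention]:
    """Remove all mentions suppressed by dropped abbreviation candidates.

    A dropped candidate removes every mention in its document whose surface
    equals the short form and whose kind equals the candidate's kind; kept
    candidates change nothing. Decisions are per (doc, short form, kind);
    conflicting duplicates raise.
    """
    decided: dict[tuple[str, str, EntityKind], FilterDecision] = {}
    for d in decisions:
        key = (d.candidate.doc_id, d.candidate.short_form, d.candidate.entity_kind)
        if key in decided and decided[key].kept != d.kept:
            raise ValueError(f"conflicting abbreviation decisions for {key}")
        decided[key] = d
    dropped = {k for k, d in decided.items() if not d.kept}
    if dropped:
        logger.info("abbreviation filter suppressing %d short forms", len(dropped))
    return [
        m for m in mentions
        if (m.doc_id, m.surface, m.entity_kind) not in dropped
    ]


def filter_document_mentions(
    document: Document,
    mentions: list[Mention],
    target_lexicon: Lexicon,
    disease_lexicon: Lexicon,
    enzyme_terms: frozenset[str] | set[str] = frozenset(),
    disease_keywords: frozenset[str] | set[str] = DEFAULT_DISEASE_KEYWORDS,
    target_keywords: frozenset[str] | set[str] = DEFAULT_TARGET_KEYWORDS,
    context_keywords: frozenset[str] | set[str] = DEFAULT_CONTEXT_KEYWORDS,
) -> tuple[list[Mention], list[FilterDecision]]:
    """End-to-end abbreviation filtering for one document's mentions."""
    doc_mentions = [m for m in mentions if m.doc_id == document.doc_id]
    decisions: list[FilterDecision] = []
    for cand in find_candidates(document, doc_mentions):
        if cand.entity_kind == EntityKind.DISEASE:
            decisions.append(filter_disease_candidate(
                cand, document, disease_lexicon, disease_keywords))
        else:
            decisions.append(filter_gene_candidate(
                cand, document, target_lexicon, enzyme_terms,
                target_keywords, context_keywords, mentions=doc_mentions))
    return apply_decisions(doc_mentions, decisions), decisions
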