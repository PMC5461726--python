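"""Dictionary-based annotation of target and disease mentions.

Matching is longest-match, left-to-right, and word-boundary anchored over a
simple tokenization (alphanumeric runs, internal hyphens, Greek symbols).
Short all-uppercase lexicon surfaces (gene-symbol style, length <= 5) match
case-sensitively; every other surface matches case-insensitively. A surface
ambiguous across identifiers yields one mention per identifier — ambiguity
is resolved downstream by the abbreviation filter, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .docmodel import Document, Sentence, ZoneLabel
from .lexicon import EntityKind, Lexicon

#: Case-sensitive matching applies to all-uppercase surfaces up to this length.
CASE_SENSITIVE_MAX_LEN = 5

# word characters: ASCII alphanumerics plus Greek letters; hyphens join tokens
_TOKEN_RE = re.compile(r"[0-9A-Za-zͰ-Ͽ]+(?:-[0-9A-Za-zͰ-Ͽ]+)*")


@dataclass(frozen=True)
class Mention:
    """One annotated entity occurrence, located by zone/sentence/char span."""

    doc_id: str
    zone_label: ZoneLabel
    sentence_index: int
    char_span: tuple[int, int]
    entity_kind: EntityKind
    identifier: str
    surface: str


def _is_case_sensitive(surface: str) -> bool:
    return len(surface) <= CASE_SENSITIVE_MAX_LEN and surface.isupper()


class _MatchIndex:
    """Surface lookup split into case-sensitive and case-insensitive maps."""

    def __init__(self, lexicon: Lexicon):
        self.exact: dict[str, set[str]] = {}
        self.folded: dict[str, set[str]] = {}
        max_words = 1
        for surface, ids in lexicon.match_index.items():
            if _is_case_sensitive(surface):
                self.exact.setdefault(surface, set()).update(ids)
            else:
                self.folded.setdefault(surface.lower(), set()).update(ids)
            max_words = max(max_words, len(_TOKEN_RE.findall(surface)))
        self.max_words = max_words

    def lookup(self, text: str) -> set[str]:
        ids: set[str] = set()
        ids |= self.exact.get(text, set())
        ids |= self.folded.get(text.lower(), set())
        return ids


def token_spans(text: str) -> list[tuple[int, int]]:
    """Word-boundary anchor points: spans of alphanumeric/hyphenated runs."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _annotate_sentence(
    doc_id: str,
    zone_label: ZoneLabel,
    sentence: Sentence,
    index: _MatchIndex,
    kind: EntityKind,
) -> list[Mention]:
    text = sentence.text
    toks = token_spans(text)
    mentions: list[Mention] = []
    i = 0
    while i < len(toks):
        matched_end_token = None
        # longest candidate first
        for j in range(min(i + index.max_words, len(toks)) - 1, i - 1, -1):
            span = (toks[i][0], toks[j][1])
            ids = index.lookup(text[span[0]:span[1]])
            if ids:
                for ident in sorted(ids):
                    mentions.append(Mention(
                        doc_id=doc_id, zone_label=zone_label,
                        sentence_index=sentence.index_in_zone,
                        char_span=span, entity_kind=kind,
                        identifier=ident, surface=text[span[0]:span[1]],
                    ))
                matched_end_token = j
                break
        # advancing past the match suppresses nested shorter same-kind matches
        i = (matched_end_token + 1) if matched_end_token is not None else i + 1
    return mentions


def annotate(
    document: Document,
    target_lexicon: Lexicon,
    disease_lexicon: Lexicon,
) -> list[Mention]:
    """Annotate every zone of ``document`` with target and disease mentions.

    Target and disease matching run independently, so a target match and a
    disease match over the same span coexist (one mention per kind per
    identifier). Output order is deterministic: zone order, then sentence,
    then span, then kind, then identifier.
    """
    if target_lexicon.entity_kind != EntityKind.TARGET:
        raise ValueError("target_lexicon must have entity_kind=target")
    if disease_lexicon.entity_kind != EntityKind.DISEASE:
        raise ValueError("disease_lexicon must have entity_kind=disease")

    indexes = [
        (EntityKind.TARGET, _MatchIndex(target_lexicon)),
        (EntityKind.DISEASE, _MatchIndex(disease_lexicon)),
    ]
    mentions: list[Mention] = []
    for zone in document.zones:
        for sentence in zone.sentences:
            per_sentence: list[Mention] = []
            for kind, index in indexes:
                per_sentence.extend(_annotate_sentence(
                    document.doc_id, zone.label, sentence, index, kind))
            per_sentence.sort(key=lambda m: (m.char_span, m.entity_kind.value, m.identifier))
            mentions.extend(per_sentence)
    return mentions


def mentions_to_tsv_rows(mentions: list[Mention]) -> list[str]:
    """Render mentions as TSV rows (doc, zone, sentence, start, end, kind, id, surface)."""
    return [
        "\t".join([m.doc_id, m.zone_label.value, str(m.sentence_index),
                   str(m.char_span[0]), str(m.char_span[1]),
                   m.entity_kind.value, m.identifier, m.surface])
        for m in mentions
    ]
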