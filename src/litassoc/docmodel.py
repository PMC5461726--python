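"""Canonical sectioned, sentence-split document model.

Two input dialects are parsed into the same model: JSON-lines abstract /
full-text records and a minimal JATS-like XML. Body section headings are
classified into a fixed zone-label set by a deterministic keyword table
(a lightweight stand-in for a full section tagger), and zone text is split
into sentences with character offsets (0-based, half-open throughout).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Iterator

from lxml import etree

logger = logging.getLogger(__name__)


class ZoneLabel(str, Enum):
    TITLE = "title"
    ABSTRACT = "abstract"
    INTRODUCTION = "introduction"
    METHODS = "methods"
    RESULTS = "results"
    FIGURE = "figure"
    TABLE = "table"
    DISCUSSION = "discussion"
    CONCLUSION = "conclusion"
    CASE_STUDY = "case_study"
    APPENDIX = "appendix"
    REFERENCES = "references"
    ACKNOWLEDGEMENT_FUNDING = "acknowledgement_funding"
    COMPETING_INTERESTS = "competing_interests"
    AUTHOR_CONTRIBUTION = "author_contribution"
    SUPPLEMENTARY = "supplementary"
    OTHER = "other"


#: Zones whose co-occurrences are discarded during association extraction:
#: boilerplate and methodology sections rarely assert a studied association.
EXCLUDED_ZONES: frozenset[ZoneLabel] = frozenset({
    ZoneLabel.METHODS,
    ZoneLabel.REFERENCES,
    ZoneLabel.ACKNOWLEDGEMENT_FUNDING,
    ZoneLabel.COMPETING_INTERESTS,
    ZoneLabel.AUTHOR_CONTRIBUTION,
    ZoneLabel.SUPPLEMENTARY,
})


class AbstractLocation(str, Enum):
    """Location class of a sentence within an abstract.

    The last sentence of an abstract typically states the result, while the
    first one or two are background; these classes drive the abstract
    sentence-location weights.
    """

    FIRST_OR_SECOND = "first_or_second"
    LAST = "last"
    OTHER = "other"


def abstract_location(sentence_index: int, n_sentences: int) -> AbstractLocation:
    """Classify an abstract sentence index; "last" wins ties with "first_or_second"."""
    if n_sentences <= 0 or sentence_index >= n_sentences:
        raise ValueError("sentence_index out of range")
    if sentence_index == n_sentences - 1:
        return AbstractLocation.LAST
    if sentence_index in (0, 1):
        return AbstractLocation.FIRST_OR_SECOND
    return AbstractLocation.OTHER


@dataclass(frozen=True)
class Sentence:
    text: str
    index_in_zone: int
    char_start: int


@dataclass
class Zone:
    label: ZoneLabel
    original_heading: str
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def is_excluded(self) -> bool:
        return self.label in EXCLUDED_ZONES

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)


@dataclass
class Document:
    doc_id: str
    article_type: str
    is_open_access_fulltext: bool
    zones: list[Zone] = field(default_factory=list)

    def zone(self, label: ZoneLabel) -> Zone | None:
        for z in self.zones:
            if z.label == label:
                return z
        return None

    @property
    def body_zones(self) -> list[Zone]:
        """All zones other than title and abstract (captions included)."""
        return [z for z in self.zones
                if z.label not in (ZoneLabel.TITLE, ZoneLabel.ABSTRACT)]

    @property
    def text(self) -> str:
        return " ".join(z.text for z in self.zones)


# ---------------------------------------------------------------------------
# Section tagging

# First match in this order wins; multi-topic headings such as
# "Results and Discussion" therefore resolve to results.
_SECTION_KEYWORDS: list[tuple[ZoneLabel, tuple[str, ...]]] = [
    (ZoneLabel.RESULTS, ("result", "finding")),
    (ZoneLabel.DISCUSSION, ("discussion",)),
    (ZoneLabel.CONCLUSION, ("conclusion", "concluding", "summary")),
    (ZoneLabel.METHODS, ("method", "materials", "experimental procedure",
                         "study design", "patients and", "subjects and")),
    (ZoneLabel.INTRODUCTION, ("introduction", "background")),
    (ZoneLabel.CASE_STUDY, ("case study", "case report", "case presentation")),
    (ZoneLabel.APPENDIX, ("appendix",)),
    (ZoneLabel.REFERENCES, ("reference", "bibliography", "literature cited")),
    (ZoneLabel.ACKNOWLEDGEMENT_FUNDING, ("acknowledg", "funding")),
    (ZoneLabel.COMPETING_INTERESTS, ("competing interest", "conflict of interest",
                                     "conflicts of interest", "disclosure")),
    (ZoneLabel.AUTHOR_CONTRIBUTION, ("author contribution", "authors' contribution",
                                     "contribution of author")),
    (ZoneLabel.SUPPLEMENTARY, ("supplementary", "supplemental", "supporting information",
                               "additional file")),
]


def tag_section(heading: str) -> ZoneLabel:
    """Classify a body-section heading into a zone label.

    Total and deterministic: case-insensitive substring keywords checked in a
    fixed precedence order; anything unrecognized (including the empty
    heading) maps to ``other``.
    """
    h = (heading or "").lower()
    for label, keywords in _SECTION_KEYWORDS:
        if any(k in h for k in keywords):
            return label
    return ZoneLabel.OTHER


# ---------------------------------------------------------------------------
# Sentence splitting

#: Tokens that end with a period but do not terminate a sentence.
_NON_TERMINAL_ABBREVS = {
    "fig", "figs", "al", "e.g", "i.e", "cf", "vs", "etc", "no", "ca",
    "approx", "ref", "refs", "dr", "prof", "st", "inc", "spp", "sp",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def split_sentences(zone_text: str) -> list[Sentence]:
    """Split zone text into ordered sentences with character offsets.

    Splits at sentence-final punctuation followed by whitespace and an
    uppercase letter, digit or opening bracket; periods attached to common
    abbreviations ("Fig.", "et al.", "e.g.") do not split. Offsets are into
    ``zone_text``; concatenating the spans recovers the original content.
    """
    if not zone_text or not zone_text.strip():
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(zone_text):
        end = m.end()
        if end >= len(zone_text):
            continue
        # token immediately before the punctuation
        before = zone_text[:m.start()]
        tok = re.split(r"[\s(]+", before)[-1].lower().rstrip(".")
        if tok in _NON_TERMINAL_ABBREVS:
            continue
        rest = zone_text[end:].lstrip()
        if rest and not (rest[0].isupper() or rest[0].isdigit() or rest[0] in "([\"'“"):
            continue
        breaks.append(end)
    spans = []
    start = 0
    for b in breaks:
        spans.append((start, b))
        start = b
    spans.append((start, len(zone_text)))

    sentences: list[Sentence] = []
    idx = 0
    for s, e in spans:
        raw = zone_text[s:e]
        stripped = raw.strip()
        if not stripped:
            continue
        offset = s + (len(raw) - len(raw.lstrip()))
        sentences.append(Sentence(text=stripped, index_in_zone=idx, char_start=offset))
        idx += 1
    return sentences


def _make_zone(label: ZoneLabel, heading: str, text: str) -> Zone:
    return Zone(label=label, original_heading=heading, sentences=split_sentences(text or ""))


# ---------------------------------------------------------------------------
# Parsing

class ParseError(ValueError):
    """A record could not be converted into a Document."""


def _document_from_record(rec: dict) -> Document:
    doc_id = rec.get("doc_id")
    if not doc_id:
        raise ParseError("record missing doc_id")
    sections = rec.get("sections") or []
    captions = rec.get("captions") or []
    is_fulltext = bool(rec.get("open_access", False)) and bool(sections or captions)
    zones = [
        _make_zone(ZoneLabel.TITLE, "", rec.get("title", "")),
        _make_zone(ZoneLabel.ABSTRACT, "", rec.get("abstract", "")),
    ]
    for sec in sections:
        heading = sec.get("heading", "")
        zones.append(_make_zone(tag_section(heading), heading, sec.get("text", "")))
    for cap in captions:
        kind = cap.get("kind", "figure")
        label = ZoneLabel.TABLE if kind == "table" else ZoneLabel.FIGURE
        zones.append(_make_zone(label, kind, cap.get("text", "")))
    return Document(
        doc_id=str(doc_id),
        article_type=rec.get("article_type", ""),
        is_open_access_fulltext=is_fulltext,
        zones=zones,
    )


def document_to_record(doc: Document) -> dict:
    """Serialize a Document back to the JSON-lines dialect (round-trippable)."""
    title = doc.zone(ZoneLabel.TITLE)
    abstract = doc.zone(ZoneLabel.ABSTRACT)
    sections = []
    captions = []
    for z in doc.body_zones:
        if z.label in (ZoneLabel.FIGURE, ZoneLabel.TABLE):
            captions.append({"kind": z.label.value, "text": z.text})
        else:
            sections.append({"heading": z.original_heading, "text": z.text})
    return {
        "doc_id": doc.doc_id,
        "article_type": doc.article_type,
        "open_access": doc.is_open_access_fulltext,
        "title": title.text if title else "",
        "abstract": abstract.text if abstract else "",
        "sections": sections,
        "captions": captions,
    }


def _parse_jsonl(lines: Iterable[str], errors: list[str]) -> list[Document]:
    docs = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
            docs.append(_document_from_record(rec))
        except (json.JSONDecodeError, ParseError) as exc:
            msg = f"record {i}: {exc}"
            errors.append(msg)
            logger.warning("skipping unparseable %s", msg)
    return docs


def _parse_xml(data: str | bytes, errors: list[str]) -> list[Document]:
    root = etree.fromstring(data.encode() if isinstance(data, str) else data)
    articles = root.iter("article") if root.tag != "article" else [root]
    docs = []
    for i, art in enumerate(articles):
        try:
            docs.append(_document_from_xml(art))
        except ParseError as exc:
            msg = f"record {i}: {exc}"
            errors.append(msg)
            logger.warning("skipping unparseable %s", msg)
    return docs


def _text(el) -> str:
    return "".join(el.itertext()).strip() if el is not None else ""


def _document_from_xml(art) -> Document:
    doc_id = _text(art.find("article-id"))
    if not doc_id:
        raise ParseError("record missing doc_id")
    rec = {
        "doc_id": doc_id,
        "article_type": art.get("article-type", ""),
        "open_access": art.get("open-access", "").lower() in ("yes", "true", "1"),
        "title": _text(art.find("title")),
        "abstract": _text(art.find("abstract")),
        "sections": [
            {"heading": _text(sec.find("title")),
             "text": " ".join(_text(p) for p in sec.findall("p"))}
            for sec in art.findall("sec")
        ],
        "captions": (
            [{"kind": "figure", "text": _text(f.find("caption"))} for f in art.findall("fig")]
            + [{"kind": "table", "text": _text(t.find("caption"))} for t in art.findall("table-wrap")]
        ),
    }
    return _document_from_record(rec)


def parse_documents(
    source: str | Path | IO[str] | Iterable[str],
    dialect: str = "auto",
    errors: list[str] | None = None,
) -> list[Document]:
    """Parse a JSON-lines or minimal-XML document stream.

    ``source`` may be a path, an open text file, a string, or an iterable of
    lines. Per-record parse failures are logged and appended to ``errors``
    (when given) without aborting the batch; only an unrecognizable dialect
    raises.
    """
    def _is_path(s: str) -> bool:
        if "\n" in s or len(s) > 4096:
            return False
        try:
            return Path(s).exists()
        except OSError:
            return False

    errs = errors if errors is not None else []
    if isinstance(source, Path) or (isinstance(source, str) and _is_path(source)):
        data = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        data = source
    elif hasattr(source, "read"):
        data = source.read()
    else:
        data = "\n".join(source)

    stripped = data.lstrip()
    if dialect == "auto":
        dialect = "xml" if stripped.startswith("<") else "jsonl"
    if dialect == "xml":
        return _parse_xml(data, errs)
    if dialect == "jsonl":
        return _parse_jsonl(StringIO(data), errs)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_documents_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_record(doc), ensure_ascii=False) + "\n")
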