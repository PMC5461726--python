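"""Target and disease lexicon construction and refinement.

Raw term lists (surface, identifier) are refined before any text matching:
very short surfaces (< 3 characters) and surfaces colliding with common
English words are removed, because they would flood the annotator with
false positives ("A" is a gene name; "Large" is a protein name). Spelled
Greek letters in surviving surfaces generate symbol variants and vice
versa ("TNF alpha" also matchable as "TNF α").
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

MIN_SURFACE_LENGTH = 3

#: Spelled Greek-letter names mapped to their symbols, alpha through omega.
#: The refinement step applies this map in both directions, whole words only.
GREEK_LETTERS: dict[str, str] = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ",
    "epsilon": "ε", "zeta": "ζ", "eta": "η", "theta": "θ",
    "iota": "ι", "kappa": "κ", "lambda": "λ", "mu": "μ",
    "nu": "ν", "xi": "ξ", "omicron": "ο", "pi": "π",
    "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
}


def default_greek_map() -> dict[str, str]:
    """Bidirectional Greek map: spelled name -> symbol and symbol -> name."""
    out = dict(GREEK_LETTERS)
    out.update({sym: name for name, sym in GREEK_LETTERS.items()})
    return out


class EntityKind(str, Enum):
    TARGET = "target"
    DISEASE = "disease"


class TermSource(str, Enum):
    RAW = "raw"
    GREEK_VARIANT = "greek_variant"


@dataclass(frozen=True)
class TermEntry:
    """One matchable surface bound to an accession/ontology identifier."""

    surface: str
    identifier: str
    entity_kind: EntityKind
    variant_of: str | None = None
    source: TermSource = TermSource.RAW


@dataclass
class Lexicon:
    """A refined term dictionary for one entity kind.

    ``match_index`` maps each surface (verbatim) to the set of identifiers it
    denotes; one surface may be ambiguous across identifiers and the ambiguity
    is preserved for downstream filtering.
    """

    entity_kind: EntityKind
    entries: list[TermEntry] = field(default_factory=list)
    match_index: dict[str, set[str]] = field(default_factory=dict)
    removal_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.match_index and self.entries:
            self._rebuild_index()

    def _rebuild_index(self) -> None:
        self.match_index = {}
        for e in self.entries:
            self.match_index.setdefault(e.surface, set()).add(e.identifier)

    def surfaces_for(self, identifier: str) -> list[str]:
        return [e.surface for e in self.entries if e.identifier == identifier]

    def identifiers_for(self, surface: str) -> set[str]:
        return self.match_index.get(surface, set())

    def __len__(self) -> int:
        return len(self.entries)


def _word_spans(text: str) -> list[tuple[int, int, str]]:
    return [(m.start(), m.end(), m.group()) for m in re.finditer(r"\S+", text)]


def generate_greek_variants(surface: str, greek_map: Mapping[str, str] | None = None) -> list[str]:
    """All variants of ``surface`` obtainable by swapping whole-word Greek tokens.

    Each whitespace-delimited word equal to a key of ``greek_map`` (spelled
    name or symbol; names compared case-insensitively) can independently be
    replaced by its image, and every non-empty combination of replacements is
    returned. The input surface itself is never returned.
    """
    if not surface:
        raise ValueError("surface must be non-empty")
    gmap = default_greek_map() if greek_map is None else dict(greek_map)
    lower_map = {k.lower(): v for k, v in gmap.items()}

    words = surface.split(" ")
    choices: list[list[str]] = []
    replaceable = 0
    for w in words:
        repl = lower_map.get(w.lower())
        if repl is not None:
            choices.append([w, repl])
            replaceable += 1
        else:
            choices.append([w])
    if replaceable == 0 or replaceable > 8:  # cap combinatorial blowup
        if replaceable > 8:
            logger.warning("surface %r has %d Greek tokens; variants skipped", surface, replaceable)
        return []
    variants = []
    for combo in itertools.product(*choices):
        cand = " ".join(combo)
        if cand != surface:
            variants.append(cand)
    return variants


def refine_lexicon(
    raw_terms: Sequence[tuple[str, str]],
    entity_kind: EntityKind | str,
    stoplist: Iterable[str] = (),
    greek_map: Mapping[str, str] | None = None,
) -> Lexicon:
    """Refine a raw (surface, identifier) term list into a matchable lexicon.

    Removal rules, applied to raw surfaces and inherited by generated Greek
    variants:

    * length: surfaces shorter than 3 Unicode characters are dropped;
    * stoplist: surfaces equal (case-insensitively) to a configured common
      English word are dropped.

    Surviving surfaces additionally contribute Greek-letter variants.
    Removed terms are recorded in ``Lexicon.removal_log`` as (surface, rule).
    """
    if not raw_terms:
        raise ValueError("raw_terms must be non-empty")
    kind = EntityKind(entity_kind)
    stop = {s.lower() for s in stoplist}

    entries: list[TermEntry] = []
    seen: set[tuple[str, str]] = set()
    removal_log: list[tuple[str, str]] = []

    def _passes(surface: str) -> str | None:
        if len(surface) < MIN_SURFACE_LENGTH:
            return "length<3"
        if surface.lower() in stop:
            return "stoplist"
        return None

    def _add(entry: TermEntry) -> None:
        key = (entry.surface, entry.identifier)
        if key not in seen:
            seen.add(key)
            entries.append(entry)

    for i, row in enumerate(raw_terms):
        try:
            surface, identifier = row
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed lexicon row {i}: {row!r}") from exc
        if not isinstance(surface, str) or not isinstance(identifier, str) or not surface or not identifier:
            raise ValueError(f"malformed lexicon row {i}: {row!r}")
        rule = _passes(surface)
        if rule is not None:
            removal_log.append((surface, rule))
            continue
        _add(TermEntry(surface, identifier, kind))
        for variant in generate_greek_variants(surface, greek_map):
            vrule = _passes(variant)
            if vrule is not None:
                removal_log.append((variant, vrule))
                continue
            _add(TermEntry(variant, identifier, kind, variant_of=surface,
                           source=TermSource.GREEK_VARIANT))

    lex = Lexicon(entity_kind=kind, entries=entries, removal_log=removal_log)
    logger.info("refined %s lexicon: %d entries kept, %d surfaces removed",
                kind.value, len(entries), len(removal_log))
    return lex


# ---------------------------------------------------------------------------
# TSV I/O

def read_terms_tsv(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read a two-column (surface TAB identifier) UTF-8 TSV."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if header and i == 0:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed lexicon row {i} in {path}: {line!r}")
            rows.append((parts[0], parts[1]))
    return rows


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path,
                      removal_log_path: str | Path | None = None) -> None:
    """Write the refined lexicon (and optionally its removal log) as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in lexicon.entries:
            fh.write(f"{e.surface}\t{e.identifier}\n")
    if removal_log_path is not None:
        with open(removal_log_path, "w", encoding="utf-8") as fh:
            for surface, rule in lexicon.removal_log:
                fh.write(f"{surface}\t{rule}\n")
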