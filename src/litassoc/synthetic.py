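"""Deterministic synthetic corpora with planted target-disease associations.

The generator emulates the two input dialects end to end: refined target and
disease lexicons, abstract-only and open-access full-text research articles
with planted sentence-level co-occurrences at chosen zones and abstract
sentence locations, distractor documents that each document-level filter
must remove (wrong article type, excluded-section-only pairs,
single-body-occurrence pairs), and ambiguous-abbreviation documents whose
short form must be suppressed by the abbreviation filter. Sentence text is
template-based ("<GENE> is associated with <DISEASE> ...") so sentence
splitting and dictionary matching are exact, which lets the generator also
emit the ground-truth association record each planted document must yield
after the full pipeline.

It does not model real scientific language: no anaphora, no nested entity
names, no OCR noise, and mention surfaces are unambiguous by construction
unless explicitly planted otherwise.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Literal

from .associations import AssociationRecord
from .docmodel import (AbstractLocation, Document, EXCLUDED_ZONES, ZoneLabel,
                       parse_documents)
from .evaluation import RelevanceJudgment
from .lexicon import EntityKind, Lexicon, refine_lexicon

_GREEK_NAMES = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta",
                "theta", "iota", "kappa", "lambda", "mu", "nu", "xi",
                "omicron", "pi", "rho", "sigma", "tau", "upsilon", "phi",
                "chi", "psi", "omega"]

_FILLERS = [
    "The cohort was recruited over several seasons.",
    "Samples were stored following standard practice.",
    "Environmental covariates were recorded daily.",
    "The follow-up interval spanned many months.",
    "Study logistics were coordinated centrally.",
]

_HEADINGS: dict[ZoneLabel, str] = {
    ZoneLabel.INTRODUCTION: "Introduction",
    ZoneLabel.METHODS: "Materials and Methods",
    ZoneLabel.RESULTS: "Results",
    ZoneLabel.DISCUSSION: "Discussion",
    ZoneLabel.CONCLUSION: "Conclusions",
    ZoneLabel.CASE_STUDY: "Case Study",
    ZoneLabel.APPENDIX: "Appendix",
    ZoneLabel.REFERENCES: "References",
    ZoneLabel.ACKNOWLEDGEMENT_FUNDING: "Acknowledgements and Funding",
    ZoneLabel.COMPETING_INTERESTS: "Competing Interests",
    ZoneLabel.AUTHOR_CONTRIBUTION: "Author Contributions",
    ZoneLabel.SUPPLEMENTARY: "Supplementary Material",
    ZoneLabel.OTHER: "Miscellany",
}

# "other" alone names the abstract sentence-location class; the catch-all
# body zone is addressed as "other_section" to keep plan keys unambiguous.
_BODY_ZONE_KEYS = {z.value: z for z in _HEADINGS if z != ZoneLabel.OTHER} | {
    "figure": ZoneLabel.FIGURE, "table": ZoneLabel.TABLE,
    "other_section": ZoneLabel.OTHER,
}
_LOCATION_KEYS = {loc.value: loc for loc in AbstractLocation}


@dataclass
class DocPlan:
    """Mention layout for one planted document.

    ``counts`` keys are body zone labels ("title", "introduction", "results",
    "figure", ...) and, for the abstract, sentence-location classes
    ("first_or_second", "last", "other"). ``gene_only_abstract`` adds that
    many abstract sentences mentioning the target alone (no disease).
    """

    doc_type: Literal["abstract", "fulltext"] = "fulltext"
    counts: dict[str, int] = field(default_factory=dict)
    gene_only_abstract: int = 0
    article_type: str = "research-article"

    def validate(self) -> None:
        for key in self.counts:
            if key not in _BODY_ZONE_KEYS and key not in _LOCATION_KEYS and key != "title":
                raise ValueError(f"doc plan references unknown zone {key!r}")
        if self.counts.get("title", 0) > 1:
            raise ValueError("a title holds at most one co-occurrence sentence")
        if self.counts.get("first_or_second", 0) > 2:
            raise ValueError("at most two first_or_second sentences exist")
        if self.counts.get("last", 0) > 1:
            raise ValueError("at most one last sentence exists")
        if self.doc_type == "abstract":
            if any(k in _BODY_ZONE_KEYS for k in self.counts):
                raise ValueError("abstract-only plan cannot place body zone counts")


@dataclass
class Plant:
    target_id: str
    disease_id: str
    plan: DocPlan


@dataclass
class CorpusSpec:
    """Generation parameters; a fixed seed yields a byte-identical corpus."""

    n_abstracts: int = 40
    n_fulltexts: int = 40
    planted: list[Plant] = field(default_factory=list)
    distractor_rate: float = 0.2
    ambiguous_abbrevs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    records_jsonl: str
    target_lexicon: Lexicon
    disease_lexicon: Lexicon
    ground_truth: list[AssociationRecord]
    judgments: list[RelevanceJudgment]


def _base26(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("A") + i % 26) + out
        i //= 26
        if i == 0:
            return out


def target_surface(idx: int) -> str:
    """Gene-symbol-style surface for the idx-th synthetic target (e.g. GZA)."""
    return "GZ" + _base26(idx)


def disease_surface(idx: int) -> str:
    """Multi-word disease surface for the idx-th synthetic disease."""
    return f"pathosis {_GREEK_NAMES[idx % 24]} {idx // 24}" if idx >= 24 \
        else f"pathosis {_GREEK_NAMES[idx]}"


def _cooc_sentence(gene: str, disease: str) -> str:
    return f"{gene} is associated with {disease} in this cohort."


def _gene_sentence(gene: str) -> str:
    return f"Expression of {gene} was profiled separately."


def _filler(rng: random.Random) -> str:
    return rng.choice(_FILLERS)


def _abstract_sentences(plan: DocPlan, gene: str, disease: str,
                        rng: random.Random) -> list[str]:
    c12 = plan.counts.get("first_or_second", 0)
    cot = plan.counts.get("other", 0)
    cla = plan.counts.get("last", 0)
    head = [_cooc_sentence(gene, disease) if i < c12 else _filler(rng) for i in range(2)]
    middle = [_cooc_sentence(gene, disease)] * cot
    middle += [_gene_sentence(gene)] * plan.gene_only_abstract
    if not middle:
        middle = [_filler(rng)]
    tail = [_cooc_sentence(gene, disease) if cla else _filler(rng)]
    return head + middle + tail


def _expected_record(plant: Plant, doc_id: str, is_fulltext: bool) -> AssociationRecord | None:
    """Ground-truth association record after all document-level filters."""
    plan = plant.plan
    if plan.article_type.lower() not in ("research-article", "research"):
        return None
    zone_counts: dict[ZoneLabel, int] = {}
    loc_counts: dict[AbstractLocation, int] = {}
    for key, n in plan.counts.items():
        if n <= 0:
            continue
        if key == "title":
            zone_counts[ZoneLabel.TITLE] = zone_counts.get(ZoneLabel.TITLE, 0) + n
        elif key in _LOCATION_KEYS:
            loc = _LOCATION_KEYS[key]
            loc_counts[loc] = loc_counts.get(loc, 0) + n
            zone_counts[ZoneLabel.ABSTRACT] = zone_counts.get(ZoneLabel.ABSTRACT, 0) + n
        else:
            zone = _BODY_ZONE_KEYS[key]
            if zone in EXCLUDED_ZONES:
                continue  # removed by the section filter
            zone_counts[zone] = zone_counts.get(zone, 0) + n
    abstract_n = zone_counts.get(ZoneLabel.ABSTRACT, 0)
    title_n = zone_counts.get(ZoneLabel.TITLE, 0)
    body_n = sum(n for z, n in zone_counts.items()
                 if z not in (ZoneLabel.TITLE, ZoneLabel.ABSTRACT))
    if not zone_counts:
        return None
    if body_n == 1 and title_n == 0 and abstract_n == 0:
        return None  # removed by the min-occurrence filter
    return AssociationRecord(
        doc_id=doc_id, target_id=plant.target_id, disease_id=plant.disease_id,
        count_by_zone=zone_counts, count_by_abstract_location=loc_counts,
        gene_abstract_mention_count=abstract_n + plan.gene_only_abstract,
        title_pair_count=title_n, is_fulltext=is_fulltext,
    )


def generate(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate documents, lexicons, ground truth and judgments from ``spec``."""
    rng = random.Random(spec.seed)

    # --- entity pools ------------------------------------------------------
    target_ids = sorted({p.target_id for p in spec.planted}) or ["T000"]
    disease_ids = sorted({p.disease_id for p in spec.planted}) or ["D000"]
    tgt_surface = {tid: target_surface(i) for i, tid in enumerate(target_ids)}
    dis_surface = {did: disease_surface(i) for i, did in enumerate(disease_ids)}

    raw_targets = [(s, tid) for tid, s in tgt_surface.items()]
    raw_diseases = [(s, did) for did, s in dis_surface.items()]
    for i, (short, _misleading) in enumerate(spec.ambiguous_abbrevs):
        amb_id = f"DAMB{i:03d}"
        raw_diseases.append((short, amb_id))
        raw_diseases.append((f"veritable {short.lower()} pathosis", amb_id))

    target_lexicon = refine_lexicon(raw_targets, EntityKind.TARGET)
    disease_lexicon = refine_lexicon(raw_diseases, EntityKind.DISEASE)

    records: list[dict] = []
    ground_truth: list[AssociationRecord] = []
    judgments: list[RelevanceJudgment] = []

    # --- planted documents -------------------------------------------------
    for i, plant in enumerate(spec.planted):
        plan = plant.plan
        plan.validate()
        doc_id = f"PLT{i:04d}"
        gene = tgt_surface[plant.target_id]
        disease = dis_surface[plant.disease_id]
        is_fulltext = plan.doc_type == "fulltext"

        title = (_cooc_sentence(gene, disease)[:-1] if plan.counts.get("title") else
                 f"A longitudinal survey of cohort {i}")
        abstract = " ".join(_abstract_sentences(plan, gene, disease, rng))
        sections: list[dict] = []
        captions: list[dict] = []
        if is_fulltext:
            body_zones = {k: v for k, v in plan.counts.items()
                          if k in _BODY_ZONE_KEYS and v > 0}
            for key in sorted(body_zones):
                zone = _BODY_ZONE_KEYS[key]
                text = " ".join([_cooc_sentence(gene, disease)] * body_zones[key]
                                + [_filler(rng)])
                if zone in (ZoneLabel.FIGURE, ZoneLabel.TABLE):
                    captions.append({"kind": zone.value, "text": text})
                else:
                    sections.append({"heading": _HEADINGS[zone], "text": text})
            if not any(s["heading"] == "Introduction" for s in sections):
                sections.insert(0, {"heading": "Introduction", "text": _filler(rng)})
        records.append({
            "doc_id": doc_id, "article_type": plan.article_type,
            "open_access": is_fulltext, "title": title, "abstract": abstract,
            "sections": sections, "captions": captions,
        })
        expected = _expected_record(plant, doc_id, is_fulltext)
        if expected is not None:
            ground_truth.append(expected)
            judgments.append(RelevanceJudgment(doc_id, plant.target_id,
                                               plant.disease_id, True))

    # --- distractor documents (each defeats one filter) --------------------
    n_distract = round(spec.distractor_rate * (spec.n_abstracts + spec.n_fulltexts))
    for i in range(n_distract):
        doc_id = f"DIS{i:04d}"
        plant = spec.planted[i % len(spec.planted)] if spec.planted else None
        gene = tgt_surface[plant.target_id] if plant else target_surface(0)
        disease = dis_surface[plant.disease_id] if plant else disease_surface(0)
        kind = i % 3
        if kind == 0:  # wrong article type
            records.append({
                "doc_id": doc_id, "article_type": "review", "open_access": False,
                "title": f"A review of theme {i}",
                "abstract": _cooc_sentence(gene, disease) + " " + _filler(rng),
                "sections": [], "captions": [],
            })
        elif kind == 1:  # pair only in an excluded section
            records.append({
                "doc_id": doc_id, "article_type": "research-article",
                "open_access": True, "title": f"A protocol study {i}",
                "abstract": _filler(rng),
                "sections": [
                    {"heading": "Introduction", "text": _filler(rng)},
                    {"heading": "Materials and Methods",
                     "text": " ".join([_cooc_sentence(gene, disease)] * 2)},
                ], "captions": [],
            })
        else:  # single body occurrence, absent from title/abstract
            records.append({
                "doc_id": doc_id, "article_type": "research-article",
                "open_access": True, "title": f"An incidental observation {i}",
                "abstract": _filler(rng),
                "sections": [
                    {"heading": "Discussion",
                     "text": _cooc_sentence(gene, disease) + " " + _filler(rng)},
                ], "captions": [],
            })
        if plant is not None:
            judgments.append(RelevanceJudgment(doc_id, plant.target_id,
                                               plant.disease_id, False))

    # --- ambiguous-abbreviation documents ----------------------------------
    for i, (short, misleading) in enumerate(spec.ambiguous_abbrevs):
        records.append({
            "doc_id": f"AMB{i:04d}", "article_type": "research-article",
            "open_access": False, "title": f"Operational practice report {i}",
            "abstract": (f"The team delivered {misleading} ({short}) "
                         f"throughout the trial. {short} procedures were audited. "
                         + _filler(rng)),
            "sections": [], "captions": [],
        })

    # --- background filler documents ---------------------------------------
    for i in range(spec.n_abstracts):
        records.append({
            "doc_id": f"BGA{i:04d}", "article_type": "research-article",
            "open_access": False, "title": f"Background abstract study {i}",
            "abstract": " ".join(_filler(rng) for _ in range(3)),
            "sections": [], "captions": [],
        })
    for i in range(spec.n_fulltexts):
        records.append({
            "doc_id": f"BGF{i:04d}", "article_type": "research-article",
            "open_access": True, "title": f"Background full text study {i}",
            "abstract": " ".join(_filler(rng) for _ in range(3)),
            "sections": [
                {"heading": "Introduction", "text": _filler(rng)},
                {"heading": "Results", "text": _filler(rng)},
            ], "captions": [],
        })

    jsonl = "\n".join(json.dumps(r, ensure_ascii=False) for r in records) + "\n"
    documents = parse_documents(jsonl, dialect="jsonl")
    return SyntheticCorpus(
        documents=documents, records_jsonl=jsonl,
        target_lexicon=target_lexicon, disease_lexicon=disease_lexicon,
        ground_truth=ground_truth, judgments=judgments,
    )


def default_spec(seed: int = 0) -> CorpusSpec:
    """A standard mixed corpus exercising every zone, filter and formula."""
    pairs = [("T000", "D000"), ("T001", "D001"), ("T002", "D000"), ("T003", "D002")]
    planted = []
    for i, (t, d) in enumerate(pairs):
        planted.append(Plant(t, d, DocPlan("fulltext", {
            "title": 1, "last": 1, "results": 2, "discussion": 1,
            "figure": 1, "methods": 2}, gene_only_abstract=1)))
        planted.append(Plant(t, d, DocPlan("fulltext", {
            "first_or_second": 1, "other": 1, "introduction": 1, "results": 1,
            "table": 1, "conclusion": 1})))
        planted.append(Plant(t, d, DocPlan("abstract", {
            "title": 1, "last": 1, "first_or_second": 1}, gene_only_abstract=2)))
    return CorpusSpec(n_abstracts=40, n_fulltexts=40, planted=planted,
                      distractor_rate=0.2,
                      ambiguous_abbrevs=[("QRS", "quick response service")],
                      seed=seed)
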