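"""Rank-quality evaluation: average precision, MAP, and score correlation.

Average precision is computed over the top-``cutoff`` documents of a ranked
list (default 25) and normalized by the number of relevant documents found
within that cutoff, so a ranking that surfaces all of its relevant hits
early scores 1.0 regardless of collection size. MAP is the arithmetic mean
of per-association AP. The correlation between two scoring variants
(e.g. abstract-only vs full-text scores for the same documents) is Pearson's
r over their shared documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

DEFAULT_CUTOFF = 25

Pair = tuple[str, str]


@dataclass(frozen=True)
class RelevanceJudgment:
    doc_id: str
    target_id: str
    disease_id: str
    relevant: bool


@dataclass
class MapResult:
    per_association_ap: dict[Pair, float]
    map_value: float
    cutoff: int


def _relevant_sets(judgments) -> dict[Pair, set[str]]:
    """Normalize judgments (iterable of RelevanceJudgment, or pair->set) to
    per-pair relevant doc-id sets."""
    if isinstance(judgments, Mapping):
        return {pair: set(docs) for pair, docs in judgments.items()}
    out: dict[Pair, set[str]] = {}
    for j in judgments:
        if j.relevant:
            out.setdefault((j.target_id, j.disease_id), set()).add(j.doc_id)
    return out


def average_precision(
    ranked: Sequence[str],
    relevant: set[str],
    cutoff: int = DEFAULT_CUTOFF,
) -> float:
    """AP over the top-``cutoff`` of ``ranked``: mean of precision@r at each
    relevant rank r, normalized by relevant docs within the cutoff; 0.0 when
    none of the top-``cutoff`` documents is relevant."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    top = list(ranked)[:cutoff]
    hits = 0
    precision_sum = 0.0
    for rank, doc_id in enumerate(top, start=1):
        if doc_id in relevant:
            hits += 1
            precision_sum += hits / rank
    return precision_sum / hits if hits else 0.0


def mean_average_precision(
    rankings: Mapping[Pair, Sequence[str]],
    judgments,
    cutoff: int = DEFAULT_CUTOFF,
) -> MapResult:
    """MAP over associations: arithmetic mean of per-association AP."""
    if not rankings:
        raise ValueError("rankings must contain at least one association")
    relevant_by_pair = _relevant_sets(judgments)
    per_ap = {
        pair: average_precision(ranked, relevant_by_pair.get(pair, set()), cutoff)
        for pair, ranked in rankings.items()
    }
    return MapResult(
        per_association_ap=per_ap,
        map_value=sum(per_ap.values()) / len(per_ap),
        cutoff=cutoff,
    )


def score_correlation(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
) -> float:
    """Pearson correlation between two score assignments over shared documents."""
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared documents")
    a = [scores_a[d] for d in shared]
    b = [scores_b[d] for d in shared]
    if len(set(a)) == 1 or len(set(b)) == 1:
        raise ValueError("scores have zero variance")
    return float(stats.pearsonr(a, b).statistic)
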