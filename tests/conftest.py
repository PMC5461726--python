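import pytest
from hypothesis import HealthCheck, settings

import litassoc as la

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def target_lexicon() -> la.Lexicon:
    return la.refine_lexicon(
        [
            ("IGF1", "P05019"),
            ("insulin-like growth factor 1", "P05019"),
            ("growth factor", "P_GF"),
            ("BRCA1", "P38398"),
            ("NOD2", "Q9HC29"),
            ("TNF alpha", "P01375"),
        ],
        la.EntityKind.TARGET,
    )


@pytest.fixture(scope="session")
def disease_lexicon() -> la.Lexicon:
    return la.refine_lexicon(
        [
            ("diabetes", "EFO_0000400"),
            ("inflammatory bowel disease", "EFO_0003767"),
            ("ALS", "EFO_0000253"),
            ("amyotrophic lateral sclerosis", "EFO_0000253"),
        ],
        la.EntityKind.DISEASE,
    )


def make_document(doc_id="PMID1", article_type="research-article",
                  open_access=False, title="", abstract="",
                  sections=(), captions=()) -> la.Document:
    """Build a Document through the public JSON-lines parser."""
    import json
    rec = {
        "doc_id": doc_id, "article_type": article_type,
        "open_access": open_access, "title": title, "abstract": abstract,
        "sections": list(sections), "captions": list(captions),
    }
    docs = la.parse_documents(json.dumps(rec), dialect="jsonl")
    assert len(docs) == 1
    return docs[0]


@pytest.fixture(scope="session")
def default_corpus() -> la.SyntheticCorpus:
    return la.generate(la.default_spec(seed=7))


@pytest.fixture(scope="session")
def default_corpus_result(default_corpus):
    config = la.PipelineConfig(
        target_lexicon=default_corpus.target_lexicon,
        disease_lexicon=default_corpus.disease_lexicon,
    )
    return la.run_pipeline(config, default_corpus.documents)
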