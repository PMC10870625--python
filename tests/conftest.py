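import pytest

from frdeid.document_model import AnnotatedSentence, Sentence
from frdeid.gazetteer import load_ban, load_health_directory
from frdeid.ingest import tokenize
from frdeid.rule_annotator import GazetteerSet, RuleConfig
from frdeid.synthetic_corpus import SyntheticConfig, gen_corpus, gen_gazetteers


def make_sentence(text: str, doc_ref: str = "doc", sent_index: int = 0) -> Sentence:
    """Build a Sentence directly from text (identity source offsets)."""
    return Sentence(
        text=text,
        tokens=tokenize(text),
        doc_ref=doc_ref,
        sent_index=sent_index,
    )


@pytest.fixture(scope="session")
def rules() -> RuleConfig:
    return RuleConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic zero-noise synthetic corpus with its gazetteers."""
    cfg = SyntheticConfig(n_patients=12, docs_per_patient=2, seed=11)
    return cfg, gen_corpus(cfg)


@pytest.fixture(scope="session")
def small_gazetteers(small_corpus, tmp_path_factory) -> GazetteerSet:
    cfg, _ = small_corpus
    gaz_dir = tmp_path_factory.mktemp("gaz")
    gen_gazetteers(cfg, gaz_dir)
    gaz_str, gaz_zip, gaz_ville = load_ban(gaz_dir / "ban.csv")
    gaz_doc = load_health_directory(gaz_dir / "annuaire.csv")
    return GazetteerSet(doctor=gaz_doc, street=gaz_str, zip=gaz_zip, ville=gaz_ville)


def annotate_corpus(corpus, gazetteers, rules):
    """Gold and predicted sentence lists for a generated corpus."""
    from frdeid.rule_annotator import PatientRecordKeys, annotate_sentence

    gold, pred = [], []
    for gdoc in corpus:
        keys = PatientRecordKeys.from_document(gdoc.doc)
        annotated, _ = gdoc.to_annotated()
        for asent in annotated:
            gold.append(asent)
            pred.append(
                AnnotatedSentence(
                    sentence=asent.sentence,
                    mentions=annotate_sentence(asent.sentence, rules, gazetteers, keys),
                    meta=asent.meta,
                )
            )
    return gold, pred
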