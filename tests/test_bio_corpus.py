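import json
import random

import pytest

from frdeid.bio_corpus import (
    CorpusFormatError,
    bio_decode,
    bio_encode,
    corpus_stats,
    filter_sentences,
    percentages_from_counts,
    read_conll,
    read_jsonl,
    record_to_sentence,
    sentence_to_record,
    split_by_patient,
    write_conll,
    write_jsonl,
)
from frdeid.document_model import (
    AnnotatedSentence,
    EntityMention,
    PIICategory,
    mention_from_tokens,
)
from tests.conftest import make_sentence

# Mention counts of the automatically annotated training partition this
# pipeline's statistics engine must summarize correctly.
TRAINING_COUNTS = {
    PIICategory.DOCTOR: 3_883_360,
    PIICategory.PATIENT: 1_853_646,
    PIICategory.DATE: 4_948_519,
    PIICategory.VILLE: 2_544_287,
    PIICategory.ZIP: 1_305_402,
    PIICategory.STR: 1_165_009,
    PIICategory.EMAIL: 276_208,
    PIICategory.PHONE: 2_210_577,
}


def _random_mentions(sent, rng):
    """Random non-overlapping token-range mentions."""
    n = len(sent.tokens)
    mentions = []
    i = 0
    while i < n:
        if rng.random() < 0.4:
            last = min(n - 1, i + rng.randint(0, 2))
            cat = rng.choice(list(PIICategory))
            mentions.append(mention_from_tokens(sent, cat, i, last))
            i = last + 1
        else:
            i += 1
    return mentions


def test_bio_encode_doctor_example():
    sent = make_sentence("Monsieur le Docteur JEAN DUPONT")
    m = mention_from_tokens(sent, PIICategory.DOCTOR, 3, 4)
    assert bio_encode(sent, [m]) == ["O", "O", "O", "B-DOCTOR", "I-DOCTOR"]


def test_bio_encode_no_mentions_all_outside():
    sent = make_sentence("rien à signaler")
    assert bio_encode(sent, []) == ["O"] * len(sent.tokens)


def test_bio_encode_rejects_overlap():
    sent = make_sentence("un deux trois")
    a = mention_from_tokens(sent, PIICategory.DATE, 0, 1)
    b = mention_from_tokens(sent, PIICategory.ZIP, 1, 2)
    with pytest.raises(ValueError):
        bio_encode(sent, [a, b])


def test_bio_decode_simple_run():
    sent = make_sentence("le 3 janvier fin")
    got = bio_decode(sent, ["O", "B-DATE", "I-DATE", "O"])
    assert len(got) == 1
    assert (got[0].token_first, got[0].token_last, got[0].category) == (
        1, 2, PIICategory.DATE)


def test_bio_decode_repairs_orphan_inside_tag():
    sent = make_sentence("35000 RENNES")
    got = bio_decode(sent, ["I-ZIP", "O"])
    assert [(m.category, m.token_first) for m in got] == [(PIICategory.ZIP, 0)]
    # category switch without B also opens a new mention
    got2 = bio_decode(sent, ["B-ZIP", "I-VILLE"])
    assert [m.category for m in got2] == [PIICategory.ZIP, PIICategory.VILLE]


def test_bio_round_trip_on_randomized_mention_sets():
    rng = random.Random(42)
    texts = ["un deux trois quatre cinq six", "a b c", "mot seul",
             "α β γ δ ε ζ η θ"]
    for _ in range(200):
        sent = make_sentence(rng.choice(texts))
        mentions = _random_mentions(sent, rng)
        decoded = bio_decode(sent, bio_encode(sent, mentions))
        got = [(m.category, m.token_first, m.token_last) for m in decoded]
        want = [(m.category, m.token_first, m.token_last) for m in mentions]
        assert got == want


def test_filter_sentences_predicate_and_idempotence():
    sents = [make_sentence(t) for t in ("a b", "c d", "e f")]
    annotated = [
        AnnotatedSentence(sents[0], []),
        AnnotatedSentence(sents[1], [mention_from_tokens(sents[1], PIICategory.DATE, 0, 0)]),
        AnnotatedSentence(sents[2], []),
    ]
    kept = filter_sentences(annotated)
    assert kept == [annotated[1]]
    assert filter_sentences(kept) == kept
    assert filter_sentences([annotated[1]]) == [annotated[1]]


class TestSplitByPatient:
    def test_partitions_cover_and_are_disjoint(self):
        pids = [f"P{i}" for i in range(500)]
        split = split_by_patient(pids, seed=1)
        assert set(split.assignment) == set(pids)
        assert set(split.assignment.values()) <= {"train", "valid", "test"}

    def test_same_patient_same_partition(self):
        split = split_by_patient(["P1", "P2"], seed=9)
        again = split_by_patient(["P2", "P1", "P1"], seed=9)
        assert split.assignment == again.assignment

    def test_deterministic_given_seed(self):
        pids = [f"P{i}" for i in range(100)]
        assert split_by_patient(pids, seed=3).assignment == \
            split_by_patient(pids, seed=3).assignment

    def test_train_fraction_near_ratio(self):
        pids = [f"P{i}" for i in range(10_000)]
        split = split_by_patient(pids, seed=7)
        frac = sum(v == "train" for v in split.assignment.values()) / len(pids)
        assert abs(frac - 0.8) <= 0.02  # 5 sigma of Binomial(10000, .8)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_by_patient(["P1"], ratios=(0.5, 0.2, 0.2))


class TestCorpusStats:
    def test_training_distribution_identities(self):
        pct = percentages_from_counts(TRAINING_COUNTS)
        assert pct[PIICategory.DATE] == 27.2
        assert pct[PIICategory.DOCTOR] == 21.4
        assert abs(sum(pct.values()) - 100.0) <= 0.3  # rounding slack

    def test_single_mention_corpus(self):
        sent = make_sentence("35000")
        asent = AnnotatedSentence(sent, [mention_from_tokens(sent, PIICategory.ZIP, 0, 0)])
        stats = corpus_stats([asent])
        assert stats.percentages[PIICategory.ZIP] == 100.0
        assert stats.total_mentions == 1

    def test_counts_match_brute_force_tally(self, small_corpus):
        _, corpus = small_corpus
        sentences = [a for g in corpus[:5] for a in g.to_annotated()[0]]
        stats = corpus_stats(sentences)
        tally: dict = {}
        for s in sentences:
            for m in s.mentions:
                tally[m.category] = tally.get(m.category, 0) + 1
        for cat, n in tally.items():
            assert stats.counts[cat] == n
        assert stats.n_sentences == len(sentences)


class TestSerialization:
    def _annotated(self):
        sent = make_sentence("CENTRE HOSPITALIER UNIVERSITAIRE DE RENNES")
        m = mention_from_tokens(sent, PIICategory.VILLE, 4, 4)
        return AnnotatedSentence(sent, [m], meta={
            "ID_PAT": "363342", "ID_ENTREPOT": "141303567",
            "CODE": "EHOP:CR_ECHO", "annotator": 5, "annotator2": 2,
        })

    def test_record_fields(self):
        rec = sentence_to_record(self._annotated())
        assert set(rec) == {"text", "meta", "tokens_parser", "spans"}
        assert set(rec["meta"]) == {"ID_PAT", "ID_ENTREPOT", "CODE",
                                    "annotator", "annotator2"}
        tok0 = rec["tokens_parser"][0]
        assert (tok0["text"], tok0["start"], tok0["end"], tok0["id"]) == (
            "CENTRE", 0, 6, 0)
        assert rec["spans"] == [{"start": 36, "end": 42, "label": "VILLE"}]

    def test_jsonl_round_trip(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        original = [self._annotated()]
        write_jsonl(original, path)
        back = read_jsonl(path)
        assert len(back) == 1
        assert back[0].sentence.text == original[0].sentence.text
        assert back[0].mentions[0].char_start == 36
        # a rewrite is byte-identical
        path2 = tmp_path / "again.jsonl"
        write_jsonl(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_empty_corpus_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        write_jsonl([], path)
        assert path.read_text() == ""
        assert read_jsonl(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = json.dumps(sentence_to_record(self._annotated()))
        path.write_text(good + "\n{broken\n", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_jsonl(path)

    def test_record_round_trip_via_dicts(self):
        rec = sentence_to_record(self._annotated())
        again = sentence_to_record(record_to_sentence(rec))
        assert rec == again

    def test_conll_round_trip(self, tmp_path):
        path = tmp_path / "corpus.conll"
        asent = self._annotated()
        write_conll([asent], path)
        back = read_conll(path)
        assert back == [(
            [t.text for t in asent.sentence.tokens],
            bio_encode(asent.sentence, asent.mentions),
        )]
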