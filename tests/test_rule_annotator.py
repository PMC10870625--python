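from datetime import date
from itertools import product

import pytest

from frdeid.document_model import PIICategory, SourceDocument, span_surface
from frdeid.gazetteer import Gazetteer
from frdeid.rule_annotator import (
    GazetteerSet,
    PatientRecordKeys,
    RuleConfig,
    annotate_sentence,
    detect_city,
    detect_dates,
    detect_doctor,
    detect_email,
    detect_patient,
    detect_phone,
    detect_street,
    detect_zip,
)
from tests.conftest import make_sentence


@pytest.fixture(scope="module")
def cfg():
    return RuleConfig()


def _gaz(category, terms, **kw):
    g = Gazetteer(category, **kw)
    for t in terms:
        g.add(t)
    return g


@pytest.fixture(scope="module")
def gazetteers():
    return GazetteerSet(
        doctor=_gaz(PIICategory.DOCTOR, ["JEAN", "DUPONT", "DURAND"]),
        street=_gaz(PIICategory.STR, ["RUE DE LA PAIX"]),
        zip=_gaz(PIICategory.ZIP, ["35000"], min_len=5, stop_set=frozenset()),
        ville=_gaz(PIICategory.VILLE, ["RENNES", "PARIS", "SAINT-MALO"]),
    )


def surfaces(sent, mentions):
    return [(m.category.value, span_surface(sent, m)) for m in mentions]


# --------------------------------------------------------------------------
# dates
# --------------------------------------------------------------------------

@pytest.mark.parametrize("text", [
    "02/07/1985", "12-03-2020", "01.01.99", "2020-03-12", "3 janvier 2020",
    "lundi 3 janvier 2020", "15 sept 2019", "1er janvier 2020",
])
def test_valid_dates_detected(cfg, text):
    sent = make_sentence(f"vu le {text} au CHU")
    got = detect_dates(sent, cfg)
    assert len(got) == 1
    assert span_surface(sent, got[0]) == text


def test_invalid_day_month_pairs_rejected(cfg):
    """Bound-check oracle: day > 31 or month > 12 never matches."""
    for day, month in product((0, 32, 45, 99), (0, 13, 99)):
        sent = make_sentence(f"le {day:02d}/{month:02d}/2020")
        assert detect_dates(sent, cfg) == []
    # valid/invalid boundary
    assert detect_dates(make_sentence("31/12/2020"), cfg)
    assert not detect_dates(make_sentence("45/99/2020"), cfg)


# --------------------------------------------------------------------------
# phone
# --------------------------------------------------------------------------

@pytest.mark.parametrize("text,n", [
    ("02 99 28 43 21", 1),
    ("00.00.00", 1),
    ("02-99-28-43-21", 1),
    ("0299284321", 1),
    ("2020", 0),
    ("02 99", 0),
])
def test_phone_formats(cfg, text, n):
    got = detect_phone(make_sentence(text), cfg)
    assert len(got) == n


def test_spaced_phone_span_covers_all_groups(cfg):
    sent = make_sentence("Tél : 02 99 28 43 21.")
    got = detect_phone(sent, cfg)
    assert surfaces(sent, got) == [("PHONE", "02 99 28 43 21")]


# --------------------------------------------------------------------------
# zip
# --------------------------------------------------------------------------

def test_zip_by_gazetteer(cfg, gazetteers):
    sent = make_sentence("35000")
    got = detect_zip(sent, cfg, gazetteers.zip)
    assert [m.category for m in got] == [PIICategory.ZIP]


def test_zip_by_city_context(cfg, gazetteers):
    sent = make_sentence("56100 RENNES")  # not in zip gazetteer, city adjacent
    got = detect_zip(sent, cfg, gazetteers.zip, gazetteers.ville)
    assert len(got) == 1


def test_zip_rejects_six_digits_and_bare_unknown(cfg, gazetteers):
    assert detect_zip(make_sentence("123456"), cfg, gazetteers.zip) == []
    assert detect_zip(make_sentence("99999"), cfg, gazetteers.zip, gazetteers.ville) == []


# --------------------------------------------------------------------------
# email
# --------------------------------------------------------------------------

def test_email_detection(cfg):
    sent = make_sentence("écrire à j.dupont@chu-rennes.fr ou arobase")
    got = detect_email(sent, cfg)
    assert surfaces(sent, got) == [("EMAIL", "j.dupont@chu-rennes.fr")]


@pytest.mark.parametrize("candidate,valid", [
    ("a@b.fr", True), ("prenom.nom@chu-brest.fr", True),
    ("arobase", False), ("a@b", False), ("@chu.fr", False),
])
def test_email_grammar(cfg, candidate, valid):
    got = detect_email(make_sentence(f"contact {candidate} fin"), cfg)
    assert bool(got) is valid


# --------------------------------------------------------------------------
# street
# --------------------------------------------------------------------------

def test_street_with_house_number(cfg, gazetteers):
    sent = make_sentence("12 RUE DE LA PAIX")
    got = detect_street(sent, cfg, gazetteers.street)
    assert surfaces(sent, got) == [("STR", "12 RUE DE LA PAIX")]


def test_lowercase_cue_without_continuation(cfg, gazetteers):
    assert detect_street(make_sentence("il continue sa rue"), cfg, gazetteers.street) == []


def test_street_abbreviation_expansion(cfg, gazetteers):
    sent = make_sentence("Ave de Bretagne")
    got = detect_street(sent, cfg, gazetteers.street)
    assert surfaces(sent, got) == [("STR", "Ave de Bretagne")]


# --------------------------------------------------------------------------
# city
# --------------------------------------------------------------------------

def test_city_direct_hit(cfg, gazetteers):
    sent = make_sentence("transfert vers RENNES demain")
    got = detect_city(sent, cfg, gazetteers.ville)
    assert surfaces(sent, got) == [("VILLE", "RENNES")]


def test_lowercase_city_requires_zip_context(cfg, gazetteers):
    assert detect_city(make_sentence("il habite rennes"), cfg, gazetteers.ville) == []
    sent = make_sentence("35000 rennes")
    got = detect_city(sent, cfg, gazetteers.ville)
    assert surfaces(sent, got) == [("VILLE", "rennes")]


def test_longest_match_does_not_overrun(cfg, gazetteers):
    sent = make_sentence("PARIS MATCH est un journal")
    got = detect_city(sent, cfg, gazetteers.ville)
    assert surfaces(sent, got) == [("VILLE", "PARIS")]


def test_hyphenated_city(cfg, gazetteers):
    sent = make_sentence("parti pour SAINT-MALO hier")
    got = detect_city(sent, cfg, gazetteers.ville)
    assert surfaces(sent, got) == [("VILLE", "SAINT-MALO")]


# --------------------------------------------------------------------------
# doctor
# --------------------------------------------------------------------------

def test_trigger_excludes_title(cfg, gazetteers):
    sent = make_sentence("Monsieur le Docteur JEAN DUPONT")
    got = detect_doctor(sent, cfg, gazetteers.doctor)
    assert surfaces(sent, got) == [("DOCTOR", "JEAN DUPONT")]


def test_trigger_without_following_capital(cfg):
    assert detect_doctor(make_sentence("le docteur est absent"), cfg) == []


def test_gazetteer_only_hit(cfg, gazetteers):
    sent = make_sentence("DURAND a prescrit un examen")
    got = detect_doctor(sent, cfg, gazetteers.doctor)
    assert surfaces(sent, got) == [("DOCTOR", "DURAND")]


# --------------------------------------------------------------------------
# patient
# --------------------------------------------------------------------------

def _doc(first="Paul", last="MARTIN", birth=date(1985, 7, 2)):
    return SourceDocument(doc_id="d", patient_id="p", raw="",
                          patient_first_name=first, patient_last_name=last,
                          birthdate=birth)


def test_metadata_name_echo():
    keys = PatientRecordKeys.from_document(_doc())
    sent = make_sentence("Monsieur Paul MARTIN est sorti")
    got = detect_patient(sent, keys)
    assert surfaces(sent, got) == [("PATIENT", "Paul MARTIN")]


def test_birthdate_formats_matched():
    """Format-expansion oracle: the birthdate is found in every configured
    rendering."""
    keys = PatientRecordKeys.from_document(_doc())
    for surface in ("02/07/1985", "02-07-1985", "1985-07-02", "02/07/85",
                    "2 juillet 1985"):
        sent = make_sentence(f"né le {surface}")
        cats = [m.category for m in detect_patient(sent, keys)]
        assert PIICategory.DATE in cats, surface


def test_no_metadata_no_mentions():
    doc = SourceDocument(doc_id="d", patient_id="p", raw="")
    keys = PatientRecordKeys.from_document(doc)
    assert detect_patient(make_sentence("Monsieur Paul MARTIN"), keys) == []


def test_compound_patient_name_parts_match():
    keys = PatientRecordKeys.from_document(_doc(first="Marie-Claire"))
    sent = make_sentence("Madame Claire MARTIN")
    got = detect_patient(sent, keys)
    assert surfaces(sent, got) == [("PATIENT", "Claire MARTIN")]


# --------------------------------------------------------------------------
# cascade
# --------------------------------------------------------------------------

def test_cascade_four_mentions(cfg, gazetteers):
    sent = make_sentence("Dr JEAN DUPONT, 12 RUE DE LA PAIX, 35000 RENNES")
    got = annotate_sentence(sent, cfg, gazetteers)
    assert surfaces(sent, got) == [
        ("DOCTOR", "JEAN DUPONT"),
        ("STR", "12 RUE DE LA PAIX"),
        ("ZIP", "35000"),
        ("VILLE", "RENNES"),
    ]


def test_cascade_empty_sentence(cfg, gazetteers):
    sent = make_sentence("aucun renseignement notable aujourd'hui")
    assert annotate_sentence(sent, cfg, gazetteers) == []


def test_cascade_never_overlaps_and_is_sorted(cfg, gazetteers, small_corpus):
    _, corpus = small_corpus
    for gdoc in corpus[:6]:
        keys = PatientRecordKeys.from_document(gdoc.doc)
        annotated, _ = gdoc.to_annotated()
        for asent in annotated:
            got = annotate_sentence(asent.sentence, cfg, gazetteers, keys)
            for a, b in zip(got, got[1:]):
                assert a.char_end <= b.char_start


def test_longest_span_wins_priority_breaks_ties(cfg, gazetteers):
    # patient surname embedded in a doctor context: longer span wins
    keys = PatientRecordKeys.from_document(_doc(first="Jean", last="LEROY"))
    sent = make_sentence("Dr Jean DUPONT signe")
    got = annotate_sentence(sent, cfg, gazetteers, keys)
    assert surfaces(sent, got) == [("DOCTOR", "Jean DUPONT")]
    # same-length tie: PATIENT outranks DOCTOR
    keys2 = PatientRecordKeys.from_document(_doc(first="Jean", last="DUPONT"))
    sent2 = make_sentence("Jean DUPONT est venu")
    got2 = annotate_sentence(sent2, cfg, gazetteers, keys2)
    assert surfaces(sent2, got2) == [("PATIENT", "Jean DUPONT")]


def test_cascade_deterministic(cfg, gazetteers):
    sent = make_sentence("Dr JEAN DUPONT, 12 RUE DE LA PAIX, 35000 RENNES")
    a = annotate_sentence(sent, cfg, gazetteers)
    b = annotate_sentence(sent, cfg, gazetteers)
    assert a == b


def test_priority_must_be_a_permutation():
    with pytest.raises(ValueError):
        RuleConfig(priority=(PIICategory.DATE,))
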