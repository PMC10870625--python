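"""The distant-supervision engine: per-category PII detectors.

Each detector combines pattern specifications (classic lexical forms of
dates, phone numbers, zip codes, e-mail addresses), orthographic
characteristics (capitalization), lexical indicators (street cue words such
as "RUE", "AVENUE"), contextual triggers (practitioner titles "Dr",
"Docteur"), gazetteer lookups, and the patient's record metadata.  The
cascade unions all detector outputs and resolves overlaps: the longest span
wins, ties broken by a fixed category priority.

Titles are triggers, not content: "Docteur JEAN DUPONT" yields a DOCTOR
mention over "JEAN DUPONT" only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

from frdeid.document_model import (
    EntityMention,
    PIICategory,
    Sentence,
    SourceDocument,
    mention_from_tokens,
)
from frdeid.gazetteer import (
    AbbreviationTable,
    Gazetteer,
    default_abbreviations,
    expand_compound,
    normalize_term,
)

# --------------------------------------------------------------------------
# Lexicons
# --------------------------------------------------------------------------

MONTHS = {
    "JANVIER": 1, "FEVRIER": 2, "MARS": 3, "AVRIL": 4, "MAI": 5, "JUIN": 6,
    "JUILLET": 7, "AOUT": 8, "SEPTEMBRE": 9, "OCTOBRE": 10, "NOVEMBRE": 11,
    "DECEMBRE": 12,
}
MONTH_ABBREV = {
    "JANV": 1, "JAN": 1, "FEV": 2, "FEVR": 2, "AVR": 4, "JUIL": 7,
    "SEPT": 9, "OCT": 10, "NOV": 11, "DEC": 12,
}
MONTH_LEXICON = {**MONTHS, **MONTH_ABBREV}

DAY_NAMES = {
    "LUNDI", "MARDI", "MERCREDI", "JEUDI", "VENDREDI", "SAMEDI", "DIMANCHE",
}

STREET_CUES = {
    "RUE", "AVENUE", "BOULEVARD", "ALLEE", "PLACE", "IMPASSE", "CHEMIN",
    "QUAI", "SQUARE", "ROUTE", "COURS",
}

ROLE_TRIGGERS = {"DR", "DOCTEUR", "PR", "PROFESSEUR", "MEDECIN"}

#: Particles allowed inside street/name spans without capitalization.
SPAN_STOPWORDS = {"DE", "DU", "DES", "LE", "LA", "LES", "L'", "D'"}

DEFAULT_PRIORITY = (
    PIICategory.PATIENT,
    PIICategory.DOCTOR,
    PIICategory.EMAIL,
    PIICategory.PHONE,
    PIICategory.DATE,
    PIICategory.STR,
    PIICategory.ZIP,
    PIICategory.VILLE,
)


@dataclass
class RuleConfig:
    """Tunable knobs of the rule cascade."""

    context_window: int = 4
    priority: tuple[PIICategory, ...] = DEFAULT_PRIORITY
    street_cues: set[str] = field(default_factory=lambda: set(STREET_CUES))
    role_triggers: set[str] = field(default_factory=lambda: set(ROLE_TRIGGERS))
    month_lexicon: dict[str, int] = field(default_factory=lambda: dict(MONTH_LEXICON))
    abbreviations: AbbreviationTable = field(default_factory=default_abbreviations)

    def __post_init__(self) -> None:
        if sorted(self.priority, key=str) != sorted(PIICategory, key=str):
            raise ValueError("priority must be a permutation of all categories")


@dataclass
class GazetteerSet:
    doctor: Gazetteer | None = None
    street: Gazetteer | None = None
    zip: Gazetteer | None = None
    ville: Gazetteer | None = None


# --------------------------------------------------------------------------
# Token predicates
# --------------------------------------------------------------------------

_WORD_RE = re.compile(r"[^\W\d_]", re.UNICODE)


def _is_word(text: str) -> bool:
    return bool(_WORD_RE.search(text))


def _is_capitalized(text: str) -> bool:
    return bool(text) and text[0].isupper()


def _norm(text: str) -> str:
    return normalize_term(text)


# --------------------------------------------------------------------------
# DATE
# --------------------------------------------------------------------------

_NUM_DATE = re.compile(r"(\d{1,2})([/.\-])(\d{1,2})\2(\d{4}|\d{2})\Z")
_ISO_DATE = re.compile(r"(\d{4})-(\d{1,2})-(\d{1,2})\Z")
_YEAR = re.compile(r"(19|20)\d{2}\Z")
_DAY_NUM = re.compile(r"([0-2]?\d|3[01])\Z")


def _is_numeric_date(text: str) -> bool:
    m = _NUM_DATE.match(text)
    if m:
        day, month = int(m.group(1)), int(m.group(3))
        return 1 <= day <= 31 and 1 <= month <= 12
    m = _ISO_DATE.match(text)
    if m:
        month, day = int(m.group(2)), int(m.group(3))
        return 1 <= month <= 12 and 1 <= day <= 31
    return False


def detect_dates(sentence: Sentence, cfg: RuleConfig) -> list[EntityMention]:
    """Numeric (dd/mm/yyyy, dd-mm-yyyy, dd.mm.yyyy, dd/mm/yy, yyyy-mm-dd)
    and lexical ("3 janvier 2020", optional day name and year) dates."""
    out: list[EntityMention] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        text = toks[i].text
        if _is_numeric_date(text):
            out.append(mention_from_tokens(sentence, PIICategory.DATE, i, i,
                                           rule_id="date:numeric"))
            i += 1
            continue
        # lexical: [dayname] day [er] month [year]
        start = i
        j = i
        if _norm(toks[j].text) in DAY_NAMES and j + 1 < len(toks):
            j += 1
        if (
            j < len(toks)
            and _DAY_NUM.match(toks[j].text)
            and 1 <= int(toks[j].text) <= 31
        ):
            k = j + 1
            if k < len(toks) and toks[k].text.lower() == "er":
                k += 1
            if k < len(toks) and _norm(toks[k].text) in cfg.month_lexicon:
                last = k
                if k + 1 < len(toks) and _YEAR.match(toks[k + 1].text):
                    last = k + 1
                out.append(
                    mention_from_tokens(sentence, PIICategory.DATE, start, last,
                                        rule_id="date:lexical")
                )
                i = last + 1
                continue
        i += 1
    return out


# --------------------------------------------------------------------------
# PHONE
# --------------------------------------------------------------------------

_PHONE_COMPACT = re.compile(r"0\d{9}\Z")
_PHONE_GROUPED = re.compile(r"\d{2}(?:[.\-]\d{2}){2,4}\Z")
_PAIR = re.compile(r"\d{2}\Z")


def detect_phone(sentence: Sentence, cfg: RuleConfig) -> list[EntityMention]:
    """Digit-pair sequences (3-5 groups joined by space, '.' or '-') and
    contiguous 10-digit numbers starting with 0."""
    out: list[EntityMention] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        text = toks[i].text
        if _PHONE_COMPACT.match(text) or _PHONE_GROUPED.match(text):
            out.append(mention_from_tokens(sentence, PIICategory.PHONE, i, i,
                                           rule_id="phone:token"))
            i += 1
            continue
        if _PAIR.match(text):
            j = i
            while j + 1 < len(toks) and _PAIR.match(toks[j + 1].text):
                j += 1
            run = j - i + 1
            while run >= 3:
                take = min(run, 5)
                out.append(
                    mention_from_tokens(sentence, PIICategory.PHONE,
                                        i, i + take - 1,
                                        rule_id="phone:spaced")
                )
                i += take
                run -= take
            i = j + 1
            continue
        i += 1
    return out


# --------------------------------------------------------------------------
# ZIP
# --------------------------------------------------------------------------

_ZIP = re.compile(r"\d{5}\Z")


def _has_context(
    sentence: Sentence, i: int, window: int, predicate
) -> bool:
    lo = max(0, i - window)
    hi = min(len(sentence.tokens), i + window + 1)
    return any(predicate(sentence.tokens[k]) for k in range(lo, hi) if k != i)


def detect_zip(
    sentence: Sentence,
    cfg: RuleConfig,
    gaz_zip: Gazetteer | None = None,
    gaz_ville: Gazetteer | None = None,
) -> list[EntityMention]:
    """Standalone 5-digit tokens, validated by gazetteer membership or by a
    nearby city/street cue."""
    out: list[EntityMention] = []
    for i, tok in enumerate(sentence.tokens):
        if not _ZIP.match(tok.text):
            continue
        in_gaz = gaz_zip is not None and tok.text in gaz_zip.entries
        if not in_gaz:
            def near_cue(t) -> bool:
                n = _norm(t.text)
                return (
                    n in cfg.street_cues
                    or cfg.abbreviations.expand(t.text) in cfg.street_cues
                    or (gaz_ville is not None and n in gaz_ville.entries)
                )
            if not _has_context(sentence, i, cfg.context_window, near_cue):
                continue
        out.append(mention_from_tokens(sentence, PIICategory.ZIP, i, i,
                                       source="gazetteer" if in_gaz else "context",
                                       rule_id="zip"))
    return out


# --------------------------------------------------------------------------
# EMAIL
# --------------------------------------------------------------------------

_EMAIL = re.compile(r"[A-Za-z0-9._%+\-]+@[A-Za-z0-9\-]+(?:\.[A-Za-z0-9\-]+)*\.[A-Za-z]{2,}\Z")


def detect_email(sentence: Sentence, cfg: RuleConfig) -> list[EntityMention]:
    return [
        mention_from_tokens(sentence, PIICategory.EMAIL, i, i, rule_id="email")
        for i, tok in enumerate(sentence.tokens)
        if _EMAIL.match(tok.text)
    ]


# --------------------------------------------------------------------------
# STR (street / location)
# --------------------------------------------------------------------------

_HOUSE_NUM = re.compile(r"\d{1,4}(?:bis|ter)?\Z")


def detect_street(
    sentence: Sentence, cfg: RuleConfig, gaz_str: Gazetteer | None = None
) -> list[EntityMention]:
    """A street-cue token ("RUE", "AVENUE", abbreviations thereof) anchors a
    mention over an optional leading house number and the following
    capitalized tokens (particles "de", "la", ... may intervene)."""
    out: list[EntityMention] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        n = _norm(toks[i].text)
        expanded = cfg.abbreviations.expand(toks[i].text)
        if n not in cfg.street_cues and expanded not in cfg.street_cues:
            i += 1
            continue
        first = i
        if i > 0 and _HOUSE_NUM.match(toks[i - 1].text):
            first = i - 1
        last_cap = -1
        j = i + 1
        while j < len(toks):
            tn = _norm(toks[j].text)
            if _is_word(toks[j].text) and _is_capitalized(toks[j].text):
                last_cap = j
                j += 1
            elif tn in SPAN_STOPWORDS:
                j += 1
            else:
                break
        if last_cap < 0:
            i += 1
            continue
        out.append(
            mention_from_tokens(sentence, PIICategory.STR, first, last_cap,
                                source="pattern", rule_id="street:cue")
        )
        i = last_cap + 1
    return out


# --------------------------------------------------------------------------
# VILLE
# --------------------------------------------------------------------------

def detect_city(
    sentence: Sentence, cfg: RuleConfig, gaz_ville: Gazetteer
) -> list[EntityMention]:
    """Longest gazetteer match over token runs.  Capitalized hits stand on
    their own; lowercase hits need an adjacent zip code or street cue."""
    out: list[EntityMention] = []
    toks = sentence.tokens
    max_words = max(gaz_ville.max_words, 1)
    i = 0
    while i < len(toks):
        if not _is_word(toks[i].text):
            i += 1
            continue
        matched = 0
        for length in range(min(max_words, len(toks) - i), 0, -1):
            seq = toks[i:i + length]
            if not all(_is_word(t.text) for t in seq):
                continue
            surface = " ".join(_norm(t.text) for t in seq)
            if surface in gaz_ville.entries:
                matched = length
                break
        if not matched:
            i += 1
            continue
        if not _is_capitalized(toks[i].text):
            def near(t) -> bool:
                return bool(_ZIP.match(t.text)) or _norm(t.text) in cfg.street_cues
            if not _has_context(sentence, i, cfg.context_window, near):
                i += 1
                continue
        out.append(
            mention_from_tokens(sentence, PIICategory.VILLE, i, i + matched - 1,
                                source="gazetteer", rule_id="city:gazetteer")
        )
        i += matched
    return out


# --------------------------------------------------------------------------
# DOCTOR
# --------------------------------------------------------------------------

def detect_doctor(
    sentence: Sentence, cfg: RuleConfig, gaz_doc: Gazetteer | None = None
) -> list[EntityMention]:
    """Practitioner names, via role triggers and via the name gazetteer.

    (a) a title trigger ("Dr", "Docteur", "Pr", ...) followed within the
    context window by capitalized tokens yields a mention over those tokens
    (the title itself is excluded); (b) runs of capitalized tokens found in
    the practitioner-name gazetteer yield mentions on their own.
    """
    out: list[EntityMention] = []
    toks = sentence.tokens
    seen: set[tuple[int, int]] = set()

    for i, tok in enumerate(toks):
        if _norm(tok.text) not in cfg.role_triggers:
            continue
        j = i + 1
        limit = min(len(toks), i + 1 + cfg.context_window)
        while j < limit:
            text = toks[j].text
            if _is_word(text) and _is_capitalized(text):
                break
            if text == "." or (_is_word(text) and not _is_capitalized(text)):
                j += 1  # skip title punctuation and particles
            else:
                j = limit
        if j >= limit or j >= len(toks):
            continue
        last = j
        while (
            last + 1 < len(toks)
            and _is_word(toks[last + 1].text)
            and _is_capitalized(toks[last + 1].text)
        ):
            last += 1
        if (j, last) not in seen:
            seen.add((j, last))
            out.append(
                mention_from_tokens(sentence, PIICategory.DOCTOR, j, last,
                                    source="context", rule_id="doctor:trigger")
            )

    if gaz_doc is not None:
        i = 0
        while i < len(toks):
            if (
                _is_word(toks[i].text)
                and _is_capitalized(toks[i].text)
                and toks[i].text in gaz_doc
            ):
                last = i
                while (
                    last + 1 < len(toks)
                    and _is_word(toks[last + 1].text)
                    and _is_capitalized(toks[last + 1].text)
                    and toks[last + 1].text in gaz_doc
                ):
                    last += 1
                if (i, last) not in seen:
                    seen.add((i, last))
                    out.append(
                        mention_from_tokens(sentence, PIICategory.DOCTOR, i, last,
                                            source="gazetteer",
                                            rule_id="doctor:gazetteer")
                    )
                i = last + 1
            else:
                i += 1
    return out


# --------------------------------------------------------------------------
# PATIENT (record metadata)
# --------------------------------------------------------------------------

#: Numeric formats a birthdate is expanded into for matching.
BIRTHDATE_FORMATS = ("%d/%m/%Y", "%d-%m-%Y", "%d.%m.%Y", "%d/%m/%y", "%Y-%m-%d")

_MONTH_NAMES_FR = {v: k for k, v in MONTHS.items()}


@dataclass(frozen=True)
class PatientRecordKeys:
    """Matching keys derived from a document's record metadata."""

    name_tokens: frozenset[str]
    birthdate_numeric: frozenset[str]
    birthdate_lexical: tuple[tuple[str, ...], ...]

    @classmethod
    def from_document(cls, doc: SourceDocument) -> "PatientRecordKeys":
        names: set[str] = set()
        for part in (doc.patient_first_name, doc.patient_last_name):
            if not part:
                continue
            for word in normalize_term(part).split(" "):
                for variant in expand_compound(word):
                    if len(variant) >= 2:
                        names.add(variant)
        numeric: set[str] = set()
        lexical: list[tuple[str, ...]] = []
        if doc.birthdate is not None:
            bd: date = doc.birthdate
            for fmt in BIRTHDATE_FORMATS:
                numeric.add(bd.strftime(fmt))
            numeric.add(f"{bd.day}/{bd.month:02d}/{bd.year}")  # non-padded day
            month = _MONTH_NAMES_FR[bd.month]
            lexical.append((str(bd.day), month, str(bd.year)))
            lexical.append((f"{bd.day:02d}", month, str(bd.year)))
        return cls(
            name_tokens=frozenset(names),
            birthdate_numeric=frozenset(numeric),
            birthdate_lexical=tuple(dict.fromkeys(lexical)),
        )


def detect_patient(
    sentence: Sentence, keys: PatientRecordKeys
) -> list[EntityMention]:
    """Case- and diacritic-insensitive echoes of the patient's name parts
    (PATIENT) and of the birthdate in any configured format (DATE)."""
    out: list[EntityMention] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        if _norm(toks[i].text) in keys.name_tokens:
            last = i
            while last + 1 < len(toks) and _norm(toks[last + 1].text) in keys.name_tokens:
                last += 1
            out.append(
                mention_from_tokens(sentence, PIICategory.PATIENT, i, last,
                                    source="metadata", rule_id="patient:name")
            )
            i = last + 1
            continue
        i += 1
    for i, tok in enumerate(toks):
        if tok.text in keys.birthdate_numeric:
            out.append(
                mention_from_tokens(sentence, PIICategory.DATE, i, i,
                                    source="metadata", rule_id="patient:birthdate")
            )
    for pattern in keys.birthdate_lexical:
        L = len(pattern)
        for i in range(len(toks) - L + 1):
            if all(_norm(toks[i + k].text) == normalize_term(pattern[k]) for k in range(L)):
                out.append(
                    mention_from_tokens(sentence, PIICategory.DATE, i, i + L - 1,
                                        source="metadata",
                                        rule_id="patient:birthdate-lexical")
                )
    return out


# --------------------------------------------------------------------------
# Cascade
# --------------------------------------------------------------------------

def resolve_overlaps(
    mentions: list[EntityMention], priority: tuple[PIICategory, ...]
) -> list[EntityMention]:
    """Greedy longest-first resolution; ties broken by category priority,
    then left-most position.  Identical (category, span) duplicates keep a
    single representative."""
    rank = {cat: k for k, cat in enumerate(priority)}
    uniq: dict[tuple, EntityMention] = {}
    for m in mentions:
        uniq.setdefault((m.category, m.char_start, m.char_end), m)
    ordered = sorted(
        uniq.values(),
        key=lambda m: (-(m.char_end - m.char_start), rank[m.category], m.char_start),
    )
    chosen: list[EntityMention] = []
    for m in ordered:
        if not any(m.overlaps(c) for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.char_start)


def annotate_sentence(
    sentence: Sentence,
    cfg: RuleConfig,
    gazetteers: GazetteerSet,
    keys: PatientRecordKeys | None = None,
) -> list[EntityMention]:
    """Run every detector and resolve the union into a non-overlapping,
    sorted mention set."""
    raw: list[EntityMention] = []
    raw += detect_dates(sentence, cfg)
    raw += detect_phone(sentence, cfg)
    raw += detect_email(sentence, cfg)
    raw += detect_zip(sentence, cfg, gazetteers.zip, gazetteers.ville)
    raw += detect_street(sentence, cfg, gazetteers.street)
    if gazetteers.ville is not None:
        raw += detect_city(sentence, cfg, gazetteers.ville)
    raw += detect_doctor(sentence, cfg, gazetteers.doctor)
    if keys is not None:
        raw += detect_patient(sentence, keys)
    return resolve_overlaps(raw, cfg.priority)
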