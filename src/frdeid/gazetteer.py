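"""Gazetteer construction from national directory file schemas.

Builds normalized dictionaries for the lookup-based PII categories from
files following the Base Adresse Nationale schema (``nom_voie``,
``code_postal``, ``nom_commune``) and the Health Directory schema
(``Nom d'exercice``, ``Prenom d'exercice``).  Matching is case- and
diacritic-insensitive because directory files and clinical text disagree on
accents.  Compound given names are augmented with their parts
("JEAN-PIERRE" also yields "JEAN" and "PIERRE"), and ambiguous short terms
(articles, elided particles, single letters) are filtered out.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from frdeid.document_model import PIICategory

#: Terms excluded from gazetteers: French articles/particles that collide
#: with ordinary prose, extended with all single letters.
DEFAULT_STOP_SET = frozenset(
    {"DE", "DU", "DES", "LE", "LA", "L", "D"}
    | {chr(c) for c in range(ord("A"), ord("Z") + 1)}
)

DEFAULT_MIN_LEN = 2


class SchemaError(ValueError):
    """A directory file is missing a required column."""


def normalize_term(term: str) -> str:
    """Normalize a dictionary term: uppercase, strip diacritics, collapse
    internal whitespace.  Idempotent."""
    decomposed = unicodedata.normalize("NFKD", term)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.upper().split())


def expand_compound(name: str) -> set[str]:
    """Return a compound name together with its hyphen-separated parts."""
    parts = [p for p in name.split("-") if p]
    out = {name}
    if len(parts) > 1:
        out.update(parts)
    return out


def filter_ambiguous(
    entries: set[str],
    stop_set: frozenset[str] | set[str] = DEFAULT_STOP_SET,
    min_len: int = DEFAULT_MIN_LEN,
) -> set[str]:
    """Drop stop-set members and terms shorter than *min_len*."""
    return {e for e in entries if e not in stop_set and len(e) >= min_len}


@dataclass
class Gazetteer:
    """A normalized term store for one PII category.

    ``entries`` holds normalized single surface forms; ``multiword`` holds
    normalized token tuples for entries spanning several tokens (so the
    annotator can do longest-sequence matching).  Every entry has passed
    ambiguity filtering.
    """

    category: PIICategory
    entries: set[str] = field(default_factory=set)
    multiword: set[tuple[str, ...]] = field(default_factory=set)
    min_len: int = DEFAULT_MIN_LEN
    stop_set: frozenset[str] = DEFAULT_STOP_SET
    #: exactly the normalized terms added (entries also holds spelling
    #: variants used as a match index)
    primary: set[str] = field(default_factory=set)

    def add(self, term: str) -> None:
        norm = normalize_term(term)
        if norm in self.stop_set or len(norm) < self.min_len:
            return
        self.primary.add(norm)
        self.entries.add(norm)
        toks = norm.split(" ")
        if len(toks) > 1:
            self.multiword.add(tuple(toks))
        # hyphenated and space-separated variants are interchangeable in
        # French place names ("SAINT-MALO" / "SAINT MALO"): index both
        if "-" in norm:
            spaced = norm.replace("-", " ")
            self.entries.add(spaced)
            self.multiword.add(tuple(spaced.split(" ")))
        elif " " in norm:
            self.entries.add(norm.replace(" ", "-"))

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.entries

    def __len__(self) -> int:
        return len(self.primary)

    @property
    def max_words(self) -> int:
        return max((len(t) for t in self.multiword), default=1)


@dataclass
class AbbreviationTable:
    """Abbreviations used in addresses and professional titles.

    ``expansions`` map an abbreviation to its full surface ("Ave" →
    "Avenue"); ``role_markers`` are title abbreviations that *trigger* a
    person mention rather than expand into one ("Dr", "Pr").  Keys match
    case-insensitively via :func:`normalize_term`.
    """

    expansions: dict[str, str] = field(default_factory=dict)
    role_markers: set[str] = field(default_factory=set)

    def expand(self, surface: str) -> str | None:
        return self.expansions.get(normalize_term(surface))

    def is_role_marker(self, surface: str) -> bool:
        return normalize_term(surface) in self.role_markers


def default_abbreviations() -> AbbreviationTable:
    return AbbreviationTable(
        expansions={
            "AVE": "AVENUE",
            "AV": "AVENUE",
            "BD": "BOULEVARD",
            "BLD": "BOULEVARD",
            "BVD": "BOULEVARD",
            "PL": "PLACE",
            "IMP": "IMPASSE",
            "CHE": "CHEMIN",
            "SQ": "SQUARE",
            "ST": "SAINT",
            "STE": "SAINTE",
            "RTE": "ROUTE",
        },
        role_markers={"DR", "PR", "DOCTEUR", "PROFESSEUR", "MEDECIN", "INTERNE"},
    )


# --------------------------------------------------------------------------
# Directory-file loading
# --------------------------------------------------------------------------

BAN_COLUMNS = ("nom_voie", "code_postal", "nom_commune")
HEALTH_DIRECTORY_COLUMNS = ("Nom d'exercice", "Prenom d'exercice")


def _read_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a delimited file with a header row; delimiter auto-detected."""
    text = Path(path).read_text(encoding="utf-8")
    first_line = text.splitlines()[0] if text.strip() else ""
    delim = max(",;\t", key=first_line.count)
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    fields = reader.fieldnames or []
    return list(fields), list(reader)


def load_ban(path: str | Path) -> tuple[Gazetteer, Gazetteer, Gazetteer]:
    """Load street, zip and city gazetteers from a BAN-schema file."""
    fields, rows = _read_rows(path)
    for col in BAN_COLUMNS:
        if col not in fields:
            raise SchemaError(f"missing column {col!r} in {path}")
    gaz_str = Gazetteer(PIICategory.STR)
    gaz_zip = Gazetteer(PIICategory.ZIP, min_len=5, stop_set=frozenset())
    gaz_ville = Gazetteer(PIICategory.VILLE)
    for row in rows:
        if row.get("nom_voie"):
            gaz_str.add(row["nom_voie"])
        if row.get("code_postal"):
            gaz_zip.add(row["code_postal"].strip())
        if row.get("nom_commune"):
            gaz_ville.add(row["nom_commune"])
    return gaz_str, gaz_zip, gaz_ville


def load_health_directory(path: str | Path) -> Gazetteer:
    """Load the practitioner-name gazetteer from a Health-Directory file.

    Surnames and given names are pooled, compound names expanded into their
    parts, and the result ambiguity-filtered (a surname like "Le" is
    dropped by the stop set).
    """
    fields, rows = _read_rows(path)
    for col in HEALTH_DIRECTORY_COLUMNS:
        if col not in fields:
            raise SchemaError(f"missing column {col!r} in {path}")
    gaz = Gazetteer(PIICategory.DOCTOR)
    for row in rows:
        for col in HEALTH_DIRECTORY_COLUMNS:
            value = row.get(col) or ""
            if not value.strip():
                continue
            for variant in expand_compound(normalize_term(value)):
                gaz.add(variant)
    return gaz
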