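"""Synthetic French clinical documents with gold PII annotations.

Real discharge summaries and the national directories cannot be shipped, so
this module generates both sides of the pipeline: HTML documents whose PII
is known exactly at generation time (a letterhead with hospital, titled
doctor, address line, phone and e-mail; a dated body echoing the patient's
name and birthdate; a signature block), and companion gazetteer files in
the Base Adresse Nationale and Health Directory column schemas.

The per-document category mix is drawn from a multinomial over the default
category profile (the share of each PII class among all mentions of a large
automatically annotated hospital corpus: dates ~27%, practitioner names
~21%, cities ~14%, phones ~12%, patient names ~10%, zips ~7%, streets ~6%,
e-mails ~2%), so generated corpora stress classes realistically.

A noise model emulates distant-supervision imperfections: per-word typos
(adjacent transposition or character deletion), accent dropping, and
cue-word abbreviation ("Avenue" → "Ave").  Noise is applied before gold
offsets are recorded, so gold surfaces may themselves be noisy — exactly
the situation a rule cascade faces on real text.

Vocabulary pools are small bundled lists.  Patient and doctor name pools
are disjoint (and disjoint from street/city/prose vocabulary) so that
strict-span scoring on synthetic corpora is not confounded by accidental
homonyms, which real text of course contains.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from frdeid.document_model import (
    AnnotatedSentence,
    EntityMention,
    PIICategory,
    SourceDocument,
)
from frdeid.ingest import OffsetMap, ingest_document

# --------------------------------------------------------------------------
# Bundled vocabulary (synthetic stand-ins for the national directories)
# --------------------------------------------------------------------------

DOCTOR_FIRST = (
    "Jean", "Marie", "Pierre", "Anne", "Jacques", "Sophie", "Jean-Pierre",
    "Anne-Laure", "François", "Isabelle", "Philippe", "Catherine",
)
DOCTOR_LAST = (
    "DUPONT", "DURAND", "LEFEVRE", "MOREAU", "GARNIER", "ROUSSEAU",
    "BLANCHARD", "FONTAINE", "CHEVALIER", "GAUTHIER",
)
PATIENT_FIRST = (
    "Paul", "Lucie", "Marc", "Julie", "Hugo", "Emma", "Louis", "Alice",
    "Nathan", "Chloé", "Théo", "Marie-Claire",
)
PATIENT_LAST = (
    "MARTIN", "BERNARD", "PETIT", "ROBERT", "RICHARD", "DUBOIS", "LAURENT",
    "SIMON", "MICHEL", "GIRARD",
)
#: filler directory names never used in generated text (imperfect-coverage
#: realism: real directories contain far more names than any one corpus)
FILLER_LAST = ("LAMBERT", "BONNET", "MERCIER", "BOYER", "ROUX")

STREET_CUES = ("Rue", "Avenue", "Boulevard", "Allée", "Impasse")
STREET_COMPLEMENTS = (
    ("de", "la", "Paix"), ("Pasteur",), ("des", "Lilas"), ("Jaurès",),
    ("du", "Général", "Leclerc"), ("de", "Bretagne"), ("des", "Acacias",),
    ("Clemenceau",),
)
CITIES = (
    "RENNES", "VANNES", "BREST", "NANTES", "SAINT-MALO", "QUIMPER",
    "LORIENT", "FOUGÈRES", "DINAN", "REDON", "LAVAL", "AURAY",
)
ZIP_PREFIXES = ("35", "56", "29", "44", "22", "53")

FILLER_SENTENCES = (
    "Le bilan biologique est sans particularité.",
    "Poursuite du traitement habituel.",
    "Surveillance clinique rapprochée.",
    "Pas de signe de gravité ce jour.",
    "Une nouvelle évaluation sera programmée.",
)

#: Default category profile: share of each class among all mentions of the
#: automatically annotated training corpus this generator emulates.
DEFAULT_PROFILE_COUNTS: dict[PIICategory, int] = {
    PIICategory.DOCTOR: 3_883_360,
    PIICategory.PATIENT: 1_853_646,
    PIICategory.DATE: 4_948_519,
    PIICategory.VILLE: 2_544_287,
    PIICategory.ZIP: 1_305_402,
    PIICategory.STR: 1_165_009,
    PIICategory.EMAIL: 276_208,
    PIICategory.PHONE: 2_210_577,
}


def default_profile() -> dict[PIICategory, float]:
    total = sum(DEFAULT_PROFILE_COUNTS.values())
    return {c: v / total for c, v in DEFAULT_PROFILE_COUNTS.items()}


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    typo_rate: float = 0.0
    accent_drop_rate: float = 0.0
    abbreviation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("typo_rate", "accent_drop_rate", "abbreviation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 50
    docs_per_patient: int = 2
    mentions_per_doc: int = 25
    profile: dict[PIICategory, float] = field(default_factory=default_profile)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gazetteer_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gazetteer_coverage <= 1.0:
            raise ValueError("gazetteer_coverage must be in [0, 1]")


@dataclass
class GoldDocument:
    """A synthetic source document plus its gold spans over extracted text."""

    doc: SourceDocument
    #: (start, end, category) spans over the extracted (visible) text
    gold_spans: list[tuple[int, int, PIICategory]]

    def to_annotated(self) -> tuple[list[AnnotatedSentence], OffsetMap]:
        """Ingest the document and convert gold character spans to
        token-level mentions per sentence."""
        sentences, omap = ingest_document(self.doc)
        annotated = [
            AnnotatedSentence(
                sentence=s,
                mentions=[],
                meta={
                    "ID_PAT": self.doc.patient_id,
                    "ID_ENTREPOT": self.doc.doc_id,
                    "CODE": self.doc.code,
                },
            )
            for s in sentences
        ]
        for start, end, cat in self.gold_spans:
            placed = False
            for asent in annotated:
                s = asent.sentence
                lo, hi = s.text_offset, s.text_offset + len(s.text)
                if not (lo <= start and end <= hi):
                    continue
                first = last = None
                for t in s.tokens:
                    if t.start == start - lo:
                        first = t.id
                    if t.end == end - lo:
                        last = t.id
                if first is None or last is None:
                    raise AssertionError(
                        f"gold span {(start, end, cat)} not on token "
                        f"boundaries in {self.doc.doc_id}"
                    )
                asent.mentions.append(
                    EntityMention(
                        category=cat,
                        token_first=first,
                        token_last=last,
                        char_start=start - lo,
                        char_end=end - lo,
                        source="manual",
                        rule_id="gold",
                    )
                )
                placed = True
                break
            if not placed:
                raise AssertionError(
                    f"gold span {(start, end, cat)} crosses a sentence "
                    f"boundary in {self.doc.doc_id}"
                )
        for asent in annotated:
            asent.mentions.sort(key=lambda m: m.char_start)
        return annotated, omap


# --------------------------------------------------------------------------
# Noise model
# --------------------------------------------------------------------------

ABBREVIATION_SUBS = {
    "Avenue": "Ave", "Boulevard": "Bd", "Docteur": "Dr", "Professeur": "Pr",
    "Saint": "St", "Sainte": "Ste",
}


def _strip_accents(word: str) -> str:
    decomposed = unicodedata.normalize("NFKD", word)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def _corrupt_word(word: str, noise: NoiseConfig, rng: np.random.Generator) -> str:
    if not any(c.isalpha() for c in word):
        return word
    if noise.abbreviation_rate and word in ABBREVIATION_SUBS:
        if rng.random() < noise.abbreviation_rate:
            return ABBREVIATION_SUBS[word]
    if noise.accent_drop_rate and rng.random() < noise.accent_drop_rate:
        word = _strip_accents(word)
    if noise.typo_rate and rng.random() < noise.typo_rate and len(word) >= 4:
        # interior-only edits so word boundaries survive
        if rng.random() < 0.5:
            k = int(rng.integers(1, len(word) - 2))
            word = word[:k] + word[k + 1] + word[k] + word[k + 2:]
        else:
            k = int(rng.integers(1, len(word) - 1))
            word = word[:k] + word[k + 1:]
    return word


def corrupt_with_rng(text: str, noise: NoiseConfig, rng: np.random.Generator) -> str:
    """Apply the noise model word-by-word (whitespace preserved)."""
    parts = text.split(" ")
    return " ".join(_corrupt_word(p, noise, rng) for p in parts)


def corrupt(text: str, noise: NoiseConfig, seed: int = 0) -> str:
    """Deterministic noisy variant of *text* under the given rates."""
    return corrupt_with_rng(text, noise, np.random.default_rng(seed))


# --------------------------------------------------------------------------
# Universe: the sampled name/address space shared by corpus and gazetteers
# --------------------------------------------------------------------------

@dataclass
class _Universe:
    doctors: list[tuple[str, str]]          # (first, LAST)
    patients: list[tuple[str, str]]         # (first, LAST)
    streets: list[tuple[str, ...]]          # cue + complement tokens
    addresses: list[tuple[str, str]]        # (zip, CITY)
    emails: list[str]


def _build_universe(cfg: SyntheticConfig, rng: np.random.Generator) -> _Universe:
    n_doc = max(6, cfg.n_patients // 4)
    doctors = [
        (DOCTOR_FIRST[int(rng.integers(len(DOCTOR_FIRST)))],
         DOCTOR_LAST[int(rng.integers(len(DOCTOR_LAST)))])
        for _ in range(n_doc)
    ]
    patients = [
        (PATIENT_FIRST[int(rng.integers(len(PATIENT_FIRST)))],
         PATIENT_LAST[int(rng.integers(len(PATIENT_LAST)))])
        for _ in range(cfg.n_patients)
    ]
    streets = [
        (STREET_CUES[int(rng.integers(len(STREET_CUES)))],)
        + STREET_COMPLEMENTS[int(rng.integers(len(STREET_COMPLEMENTS)))]
        for _ in range(12)
    ]
    addresses = []
    for city in CITIES:
        prefix = ZIP_PREFIXES[int(rng.integers(len(ZIP_PREFIXES)))]
        addresses.append((f"{prefix}{int(rng.integers(0, 1000)):03d}", city))
    emails = [
        f"{_strip_accents(first).lower().replace('-', '.')}"
        f".{_strip_accents(last).lower()}@chu-"
        f"{_strip_accents(city).lower().replace('-', '')}.fr"
        for (first, last), (_, city) in zip(
            doctors, [addresses[i % len(addresses)] for i in range(n_doc)]
        )
    ]
    return _Universe(doctors, patients, streets, addresses, emails)


def _universe_rng(cfg: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 0xA11CE])


# --------------------------------------------------------------------------
# Document assembly
# --------------------------------------------------------------------------

class _LineBuilder:
    """Accumulates fragments of one extracted-text line, recording gold
    spans as the line grows."""

    def __init__(self, noise: NoiseConfig, rng: np.random.Generator):
        self.noise = noise
        self.rng = rng
        self.fragments: list[tuple[str, PIICategory | None, bool]] = []

    def add(self, text: str, category: PIICategory | None = None,
            bold: bool = False) -> "_LineBuilder":
        text = corrupt_with_rng(text, self.noise, self.rng)
        self.fragments.append((text, category, bold))
        return self

    def render(self, line_offset: int) -> tuple[str, str, list[tuple[int, int, PIICategory]]]:
        """Return (html_inner, extracted_line, gold spans at document level)."""
        html_parts: list[str] = []
        text_parts: list[str] = []
        gold: list[tuple[int, int, PIICategory]] = []
        pos = line_offset
        for text, category, bold in self.fragments:
            if category is not None:
                gold.append((pos, pos + len(text), category))
            html_parts.append(f"<b>{text}</b>" if bold else text)
            text_parts.append(text)
            pos += len(text)
        return "".join(html_parts), "".join(text_parts), gold


_PHONE_STYLES = ("spaced", "dotted", "compact", "short")


def _sample_phone(rng: np.random.Generator) -> str:
    pairs = ["02", "99"] + [f"{int(rng.integers(0, 100)):02d}" for _ in range(3)]
    style = _PHONE_STYLES[int(rng.integers(len(_PHONE_STYLES)))]
    if style == "spaced":
        return " ".join(pairs)
    if style == "dotted":
        return ".".join(pairs)
    if style == "compact":
        return "".join(pairs)
    return ".".join(pairs[:3])  # short dotted form seen on some reports


def _sample_date_surface(rng: np.random.Generator, d: date | None = None) -> str:
    if d is None:
        d = date(2000, 1, 1) + timedelta(days=int(rng.integers(0, 9000)))
    style = int(rng.integers(4))
    if style == 0:
        return d.strftime("%d/%m/%Y")
    if style == 1:
        return d.strftime("%d-%m-%Y")
    if style == 2:
        return d.strftime("%d/%m/%y")
    months = ("janvier", "février", "mars", "avril", "mai", "juin", "juillet",
              "août", "septembre", "octobre", "novembre", "décembre")
    return f"{d.day} {months[d.month - 1]} {d.year}"


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def gen_corpus(cfg: SyntheticConfig) -> list[GoldDocument]:
    """Generate the full synthetic corpus, deterministically under the seed."""
    universe = _build_universe(cfg, _universe_rng(cfg))
    cats = list(cfg.profile)
    probs = np.array([cfg.profile[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    docs: list[GoldDocument] = []
    for p_idx in range(cfg.n_patients):
        patient_id = f"PAT{p_idx:05d}"
        first, last = universe.patients[p_idx]
        birth = date(1930, 1, 1) + timedelta(days=7 * p_idx + (p_idx % 200) * 37)
        for d_idx in range(cfg.docs_per_patient):
            doc_id = f"DOC{p_idx:05d}-{d_idx}"
            rng = np.random.default_rng([cfg.seed, 1, p_idx, d_idx])
            counts = dict(zip(cats, rng.multinomial(cfg.mentions_per_doc, probs)))
            docs.append(
                _gen_document(cfg, universe, rng, counts,
                              doc_id, patient_id, first, last, birth)
            )
    return docs


def _gen_document(
    cfg: SyntheticConfig,
    universe: _Universe,
    rng: np.random.Generator,
    counts: dict[PIICategory, int],
    doc_id: str,
    patient_id: str,
    first: str,
    last: str,
    birth: date,
) -> GoldDocument:
    noise = cfg.noise
    remaining = dict(counts)

    def take(cat: PIICategory) -> bool:
        if remaining.get(cat, 0) > 0:
            remaining[cat] -= 1
            return True
        return False

    lines: list[_LineBuilder] = []

    def line() -> _LineBuilder:
        lb = _LineBuilder(noise, rng)
        lines.append(lb)
        return lb

    zip_code, city = _pick(rng, universe.addresses)
    doctor = _pick(rng, universe.doctors)

    # ---- letterhead ----
    lh = line().add("CENTRE HOSPITALIER ")
    if take(PIICategory.VILLE):
        lh.add("DE ").add(city, PIICategory.VILLE)
    else:
        lh.add("REGIONAL")
    if take(PIICategory.DOCTOR):
        line().add("Service de médecine - Dr ").add(
            f"{doctor[0]} {doctor[1]}", PIICategory.DOCTOR,
            bold=rng.random() < 0.3,
        )
    addr = []
    if take(PIICategory.STR):
        street = _pick(rng, universe.streets)
        num = int(rng.integers(1, 200))
        addr.append((f"{num} {' '.join(street)}", PIICategory.STR))
    if take(PIICategory.ZIP):
        addr.append((zip_code, PIICategory.ZIP))
        if take(PIICategory.VILLE):
            addr.append((city, PIICategory.VILLE))
    elif take(PIICategory.VILLE):
        addr.append((city, PIICategory.VILLE))
    if addr:
        lb = line().add("Adresse : ")
        prev_cat = None
        for k, (text, cat) in enumerate(addr):
            if k:
                lb.add(", " if prev_cat is PIICategory.STR else " ")
            lb.add(text, cat)
            prev_cat = cat
    if take(PIICategory.PHONE):
        line().add("Tél : ").add(_sample_phone(rng), PIICategory.PHONE)
    if take(PIICategory.EMAIL):
        line().add("Courriel : ").add(_pick(rng, universe.emails), PIICategory.EMAIL)
    if take(PIICategory.DATE):
        line().add("Le ").add(_sample_date_surface(rng), PIICategory.DATE)

    # ---- body ----
    if take(PIICategory.PATIENT):
        lb = line().add("Monsieur " if first[-1] not in "aeé" else "Madame ")
        lb.add(f"{first} {last}", PIICategory.PATIENT,
               bold=rng.random() < 0.2)
        lb.add(" a été hospitalisé dans notre service.")
    if take(PIICategory.DATE):
        line().add("Patient né le ").add(
            birth.strftime("%d/%m/%Y"), PIICategory.DATE).add(".")

    body_templates: dict[PIICategory, list] = {
        PIICategory.DATE: [
            lambda lb: lb.add("Examen réalisé le ").add(
                _sample_date_surface(rng), PIICategory.DATE).add("."),
            lambda lb: lb.add("Prochain rendez-vous le ").add(
                _sample_date_surface(rng), PIICategory.DATE).add("."),
        ],
        PIICategory.DOCTOR: [
            lambda lb: lb.add("Courrier adressé au Dr ").add(
                "{0} {1}".format(*_pick(rng, universe.doctors)),
                PIICategory.DOCTOR).add("."),
            lambda lb: lb.add("Avis demandé au Pr ").add(
                "{0} {1}".format(*_pick(rng, universe.doctors)),
                PIICategory.DOCTOR).add("."),
        ],
        PIICategory.PATIENT: [
            lambda lb: lb.add("Nous avons revu ").add(
                f"{first} {last}", PIICategory.PATIENT).add(" en consultation."),
        ],
        PIICategory.VILLE: [
            lambda lb: lb.add("Le patient réside à ").add(
                _pick(rng, universe.addresses)[1], PIICategory.VILLE).add("."),
        ],
        PIICategory.ZIP: [
            lambda lb: lb.add("Code postal : ").add(
                _pick(rng, universe.addresses)[0], PIICategory.ZIP).add("."),
        ],
        PIICategory.STR: [
            lambda lb: lb.add("Consultation au ").add(
                f"{int(rng.integers(1, 200))} {' '.join(_pick(rng, universe.streets))}",
                PIICategory.STR).add("."),
        ],
        PIICategory.PHONE: [
            lambda lb: lb.add("Joignable au ").add(
                _sample_phone(rng), PIICategory.PHONE).add("."),
        ],
        PIICategory.EMAIL: [
            lambda lb: lb.add("Contact : ").add(
                _pick(rng, universe.emails), PIICategory.EMAIL).add("."),
        ],
    }

    pending: list[PIICategory] = []
    for cat, n in remaining.items():
        if cat in body_templates:
            pending.extend([cat] * n)
    # interleave with filler prose
    rng.shuffle(pending)
    for k, cat in enumerate(pending):
        if k % 4 == 3:
            line().add(_pick(rng, FILLER_SENTENCES))
        template = body_templates[cat][int(rng.integers(len(body_templates[cat])))]
        template(line())
    line().add(_pick(rng, FILLER_SENTENCES))

    # ---- assemble HTML + gold ----
    html_lines: list[str] = []
    gold: list[tuple[int, int, PIICategory]] = []
    offset = 0
    for lb in lines:
        inner, text, line_gold = lb.render(offset)
        html_lines.append(f"<p>{inner}</p>")
        gold.extend(line_gold)
        offset += len(text) + 1  # block element contributes one newline
    raw = "<html><body>" + "".join(html_lines) + "</body></html>"

    doc = SourceDocument(
        doc_id=doc_id,
        patient_id=patient_id,
        raw=raw,
        patient_first_name=first,
        patient_last_name=last,
        birthdate=birth,
        code="EHOP:SYNTH",
    )
    return GoldDocument(doc=doc, gold_spans=gold)


# --------------------------------------------------------------------------
# Gazetteer emission
# --------------------------------------------------------------------------

def gen_gazetteer_rows(cfg: SyntheticConfig) -> tuple[list[dict], list[dict]]:
    """BAN rows and Health-Directory rows for the corpus universe.

    With ``gazetteer_coverage`` < 1, each universe entity is included
    independently with that probability, emulating incomplete directories.
    """
    universe = _build_universe(cfg, _universe_rng(cfg))
    rng = np.random.default_rng([cfg.seed, 0xC0FE])
    cov = cfg.gazetteer_coverage

    ban_rows: list[dict] = []
    for k, street in enumerate(universe.streets):
        zip_code, city = universe.addresses[k % len(universe.addresses)]
        row = {"nom_voie": " ".join(street), "code_postal": "", "nom_commune": ""}
        if rng.random() >= cov:
            row["nom_voie"] = ""
        ban_rows.append(row)
    for zip_code, city in universe.addresses:
        ban_rows.append({
            "nom_voie": "",
            "code_postal": zip_code if rng.random() < cov else "",
            "nom_commune": city if rng.random() < cov else "",
        })
    ban_rows = [r for r in ban_rows if any(r.values())]

    hd_rows: list[dict] = []
    for first, last in universe.doctors:
        if rng.random() < cov:
            hd_rows.append({"Nom d'exercice": last, "Prenom d'exercice": first})
    for last in FILLER_LAST:
        hd_rows.append({"Nom d'exercice": last, "Prenom d'exercice": "Claude"})
    return ban_rows, hd_rows


def gen_gazetteers(cfg: SyntheticConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``ban.csv`` and ``annuaire.csv`` under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ban_rows, hd_rows = gen_gazetteer_rows(cfg)
    ban_path = out / "ban.csv"
    with open(ban_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["nom_voie", "code_postal", "nom_commune"])
        w.writeheader()
        w.writerows(ban_rows)
    hd_path = out / "annuaire.csv"
    with open(hd_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["Nom d'exercice", "Prenom d'exercice"])
        w.writeheader()
        w.writerows(hd_rows)
    return ban_path, hd_path


# --------------------------------------------------------------------------
# Surrogates (for masking in surrogate mode)
# --------------------------------------------------------------------------

def surrogate_sampler(seed: int = 0):
    """Return a callable (category, surface) -> replacement value.

    Replacements are same-category synthetic values and never equal the
    surface they replace.
    """
    rng = np.random.default_rng([seed, 0x5A])

    def sample(category: PIICategory, surface: str) -> str:
        for _ in range(20):
            if category is PIICategory.PATIENT:
                value = f"{_pick(rng, PATIENT_FIRST)} {_pick(rng, PATIENT_LAST)}"
            elif category is PIICategory.DOCTOR:
                value = f"{_pick(rng, DOCTOR_FIRST)} {_pick(rng, DOCTOR_LAST)}"
            elif category is PIICategory.DATE:
                value = _sample_date_surface(rng)
            elif category is PIICategory.PHONE:
                value = _sample_phone(rng)
            elif category is PIICategory.EMAIL:
                value = f"contact{int(rng.integers(100, 999))}@exemple.fr"
            elif category is PIICategory.STR:
                value = (f"{int(rng.integers(1, 200))} "
                         f"{' '.join(_pick(rng, STREET_COMPLEMENTS))}")
                value = f"{value}"
            elif category is PIICategory.ZIP:
                value = f"{_pick(rng, ZIP_PREFIXES)}{int(rng.integers(0, 1000)):03d}"
            else:  # VILLE
                value = _pick(rng, CITIES)
            if value != surface:
                return value
        return f"X-{value}"

    return sample
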