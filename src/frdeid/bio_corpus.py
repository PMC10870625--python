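"""BIO encoding/decoding, sentence filtering, patient-level splitting, and
corpus readers/writers (annotation-tool JSONL dialect and CoNLL TSV).

The JSONL dialect is one object per line with fields ``text``, ``meta``
(``ID_PAT``, ``ID_ENTREPOT``, ``CODE``, ``annotator``, ``annotator2``),
``tokens_parser`` (per-token ``start_char``/``end_char`` source offsets and
``start``/``end`` sentence-local offsets) and ``spans``
(sentence-local, half-open character spans with a category label).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from frdeid.document_model import (
    AnnotatedSentence,
    EntityMention,
    PIICategory,
    Sentence,
    TokenSpan,
    CATEGORY_ORDER,
)

PARTITIONS = ("train", "valid", "test")


class CorpusFormatError(ValueError):
    """A malformed line in a corpus file; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


# --------------------------------------------------------------------------
# BIO encode / decode
# --------------------------------------------------------------------------

def bio_encode(sentence: Sentence, mentions: list[EntityMention]) -> list[str]:
    """Per-token BIO tags: B-cat on the first token of each mention, I-cat on
    the rest, O elsewhere.  Mentions must be non-overlapping."""
    tags = ["O"] * len(sentence.tokens)
    occupied = [False] * len(sentence.tokens)
    for m in mentions:
        for t in range(m.token_first, m.token_last + 1):
            if occupied[t]:
                raise ValueError("overlapping mentions passed to bio_encode")
            occupied[t] = True
        tags[m.token_first] = f"B-{m.category.value}"
        for t in range(m.token_first + 1, m.token_last + 1):
            tags[t] = f"I-{m.category.value}"
    return tags


def bio_decode(sentence: Sentence, tags: list[str]) -> list[EntityMention]:
    """Decode BIO tags into mentions; invalid sequences are repaired (an
    orphan I-X opens a new mention, as if tagged B-X)."""
    if len(tags) != len(sentence.tokens):
        raise ValueError("tag sequence length differs from token count")
    mentions: list[EntityMention] = []
    cur_cat: PIICategory | None = None
    cur_first = -1
    for i, tag in enumerate(tags):
        if tag == "O":
            prefix, cat = "O", None
        else:
            prefix, _, label = tag.partition("-")
            cat = PIICategory(label)
        if prefix == "I" and cat is cur_cat and cur_cat is not None:
            continue
        if cur_cat is not None:
            mentions.append(_make(sentence, cur_cat, cur_first, i - 1))
            cur_cat = None
        if prefix in ("B", "I") and cat is not None:  # orphan I repaired to B
            cur_cat, cur_first = cat, i
    if cur_cat is not None:
        mentions.append(_make(sentence, cur_cat, cur_first, len(tags) - 1))
    return mentions


def _make(sentence: Sentence, cat: PIICategory, first: int, last: int) -> EntityMention:
    return EntityMention(
        category=cat,
        token_first=first,
        token_last=last,
        char_start=sentence.tokens[first].start,
        char_end=sentence.tokens[last].end,
        source="manual",
        rule_id="bio",
    )


# --------------------------------------------------------------------------
# Corpus containers
# --------------------------------------------------------------------------

@dataclass
class AnnotatedDocument:
    doc_id: str
    patient_id: str
    sentences: list[AnnotatedSentence] = field(default_factory=list)


def filter_sentences(sentences: list[AnnotatedSentence]) -> list[AnnotatedSentence]:
    """Keep exactly the sentences carrying at least one mention."""
    return [s for s in sentences if s.mentions]


# --------------------------------------------------------------------------
# Patient-level splitting
# --------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def partition_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def split_by_patient(
    patient_ids,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign every patient to train/valid/test so all documents of one
    patient land in the same partition.

    The mechanism is a stable hash of the patient identifier salted with the
    seed, mapped to [0, 1) and thresholded at the cumulative ratios —
    deterministic, order-independent, and reproducible without storing
    state.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    c1 = ratios[0]
    c2 = ratios[0] + ratios[1]
    assignment: dict[str, str] = {}
    for pid in patient_ids:
        digest = hashlib.sha256(f"{seed}:{pid}".encode("utf-8")).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        assignment[pid] = "train" if u < c1 else ("valid" if u < c2 else "test")
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios), seed=seed)


# --------------------------------------------------------------------------
# Corpus statistics
# --------------------------------------------------------------------------

@dataclass
class CorpusStats:
    n_sentences: int
    counts: dict[PIICategory, int]
    percentages: dict[PIICategory, float]

    @property
    def total_mentions(self) -> int:
        return sum(self.counts.values())


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    raw = Decimal(count) * 100 / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percentages_from_counts(counts: dict[PIICategory, int]) -> dict[PIICategory, float]:
    """Per-category share of all mentions, rounded half-up to one decimal."""
    total = sum(counts.values())
    return {cat: _pct(counts.get(cat, 0), total) for cat in CATEGORY_ORDER}


def corpus_stats(sentences: list[AnnotatedSentence]) -> CorpusStats:
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for s in sentences:
        for m in s.mentions:
            counts[m.category] += 1
    return CorpusStats(
        n_sentences=len(sentences),
        counts=counts,
        percentages=percentages_from_counts(counts),
    )


# --------------------------------------------------------------------------
# JSONL dialect
# --------------------------------------------------------------------------

def sentence_to_record(asent: AnnotatedSentence) -> dict:
    s = asent.sentence
    meta = {
        "ID_PAT": asent.meta.get("ID_PAT", ""),
        "ID_ENTREPOT": asent.meta.get("ID_ENTREPOT", ""),
        "CODE": asent.meta.get("CODE", ""),
        "annotator": asent.meta.get("annotator"),
        "annotator2": asent.meta.get("annotator2"),
    }
    return {
        "text": s.text,
        "meta": meta,
        "tokens_parser": [
            {
                "start_char": t.start_char,
                "end_char": t.end_char,
                "text": t.text,
                "start": t.start,
                "end": t.end,
                "id": t.id,
            }
            for t in s.tokens
        ],
        "spans": [
            {"start": m.char_start, "end": m.char_end, "label": m.category.value}
            for m in asent.mentions
        ],
    }


def record_to_sentence(rec: dict) -> AnnotatedSentence:
    tokens = [
        TokenSpan(
            text=t["text"],
            start=t["start"],
            end=t["end"],
            start_char=t["start_char"],
            end_char=t["end_char"],
            id=t["id"],
        )
        for t in rec.get("tokens_parser", [])
    ]
    sentence = Sentence(text=rec["text"], tokens=tokens)
    mentions: list[EntityMention] = []
    for span in rec.get("spans", []):
        first = last = None
        for t in tokens:
            if t.start == span["start"]:
                first = t.id
            if t.end == span["end"]:
                last = t.id
        if first is None or last is None:
            raise ValueError(
                f"span {span} does not align with token boundaries"
            )
        mentions.append(
            EntityMention(
                category=PIICategory(span["label"]),
                token_first=first,
                token_last=last,
                char_start=span["start"],
                char_end=span["end"],
                source="manual",
                rule_id="jsonl",
            )
        )
    return AnnotatedSentence(sentence=sentence, mentions=mentions,
                             meta=dict(rec.get("meta", {})))


def write_jsonl(sentences: list[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for asent in sentences:
            fh.write(json.dumps(sentence_to_record(asent), ensure_ascii=False))
            fh.write("\n")


def read_jsonl(path: str | Path) -> list[AnnotatedSentence]:
    out: list[AnnotatedSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append(record_to_sentence(rec))
            except (ValueError, KeyError, TypeError) as exc:
                raise CorpusFormatError(str(exc), lineno) from exc
    return out


# --------------------------------------------------------------------------
# CoNLL TSV
# --------------------------------------------------------------------------

def write_conll(
    sentences: list[AnnotatedSentence], path: str | Path
) -> None:
    """token TAB tag per line, blank line between sentences."""
    with open(path, "w", encoding="utf-8") as fh:
        for asent in sentences:
            tags = bio_encode(asent.sentence, asent.mentions)
            for tok, tag in zip(asent.sentence.tokens, tags):
                fh.write(f"{tok.text}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read back (tokens, tags) pairs per sentence."""
    out: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                if toks:
                    out.append((toks, tags))
                    toks, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(f"expected 2 columns, got {len(parts)}", lineno)
            toks.append(parts[0])
            tags.append(parts[1])
    if toks:
        out.append((toks, tags))
    return out
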