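"""Shared domain types and offset conventions.

All offsets in the package are 0-based and half-open ``[start, end)``.
Tokens carry two coordinate systems: *sentence-local* offsets (``start``,
``end``) into the sentence text, and *source-document* offsets
(``start_char``, ``end_char``) into the decoded characters of the original
HTML, so that any annotation can be projected back onto the source document
for masking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date


class PIICategory(str, enum.Enum):
    """The eight categories of personally identifiable information.

    The ordering is stable and is used for report columns.
    """

    PATIENT = "PATIENT"  # patient last and first name
    DOCTOR = "DOCTOR"    # health-professional last and first name
    DATE = "DATE"        # any date, including birth/admission/discharge
    EMAIL = "EMAIL"
    PHONE = "PHONE"      # phone and fax numbers
    STR = "STR"          # postal address / location designation
    ZIP = "ZIP"          # 5-digit postal code
    VILLE = "VILLE"      # city name

    def __str__(self) -> str:  # report-friendly
        return self.value


#: Stable category order for report columns.
CATEGORY_ORDER: tuple[PIICategory, ...] = tuple(PIICategory)


class MalformedMentionError(ValueError):
    """A mention whose indices do not address a valid sentence span."""


@dataclass(frozen=True)
class TokenSpan:
    """One token with sentence-local and source-document character offsets."""

    text: str
    start: int        # sentence-local, inclusive
    end: int          # sentence-local, exclusive
    start_char: int   # source-document, inclusive
    end_char: int     # source-document, exclusive
    id: int           # 0-based token index within the sentence

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid token span [{self.start}, {self.end})")
        if self.end - self.start != len(self.text):
            raise ValueError(
                f"span width {self.end - self.start} != len({self.text!r})"
            )


@dataclass
class Sentence:
    """A sentence with its tokens and its position within a document."""

    text: str
    tokens: list[TokenSpan]
    doc_ref: str = ""
    sent_index: int = 0
    #: offset of this sentence's first character in the extracted text
    text_offset: int = 0

    def validate(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if not (0 <= tok.start < tok.end <= len(self.text)):
                raise ValueError(f"token {tok} outside sentence bounds")
            if self.text[tok.start:tok.end] != tok.text:
                raise ValueError(f"token text mismatch for {tok}")
            if tok.start < prev_end:
                raise ValueError(f"token {tok} overlaps previous token")
            prev_end = tok.end


@dataclass(frozen=True)
class EntityMention:
    """A stand-off PII span over a contiguous token run of one sentence.

    ``token_first``/``token_last`` are inclusive token indices; the character
    span (sentence-local) must equal the span covered by that token range.
    ``source`` records provenance: pattern, gazetteer, metadata, context, or
    manual annotation.
    """

    category: PIICategory
    token_first: int
    token_last: int
    char_start: int
    char_end: int
    source: str = "pattern"
    rule_id: str = ""

    def __post_init__(self) -> None:
        if self.token_first > self.token_last:
            raise ValueError("token_first > token_last")
        if self.char_start >= self.char_end:
            raise ValueError("zero- or negative-length mention span")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end

    @property
    def n_tokens(self) -> int:
        return self.token_last - self.token_first + 1


@dataclass
class SourceDocument:
    """One clinical document: raw HTML plus record metadata.

    The metadata mirrors what a clinical data warehouse attaches to a
    document: the patient's name parts and birthdate (used for
    metadata-grounded detection) and optional contact details.
    """

    doc_id: str
    patient_id: str
    raw: str
    dialect: str = "native-HTML"
    patient_first_name: str = ""
    patient_last_name: str = ""
    birthdate: date | None = None
    address: str | None = None
    phone: str | None = None
    email: str | None = None
    #: opaque document-type code (LOINC-style), carried through untouched
    code: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class AnnotatedSentence:
    """A sentence paired with a resolved (non-overlapping) mention set."""

    sentence: Sentence
    mentions: list[EntityMention] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def span_surface(sentence: Sentence, mention: EntityMention) -> str:
    """Return the surface form of *mention* within *sentence*.

    Raises :class:`MalformedMentionError` when the mention's character or
    token indices do not address a valid span of the sentence.
    """
    if not (0 <= mention.char_start < mention.char_end <= len(sentence.text)):
        raise MalformedMentionError(
            f"char span [{mention.char_start}, {mention.char_end}) outside "
            f"sentence of length {len(sentence.text)}"
        )
    n = len(sentence.tokens)
    if not (0 <= mention.token_first <= mention.token_last < n):
        raise MalformedMentionError(
            f"token range [{mention.token_first}, {mention.token_last}] "
            f"invalid for {n} tokens"
        )
    first = sentence.tokens[mention.token_first]
    last = sentence.tokens[mention.token_last]
    if first.start != mention.char_start or last.end != mention.char_end:
        raise MalformedMentionError(
            "character span does not match the covered token range"
        )
    return sentence.text[mention.char_start:mention.char_end]


def mention_from_tokens(
    sentence: Sentence,
    category: PIICategory,
    token_first: int,
    token_last: int,
    source: str = "pattern",
    rule_id: str = "",
) -> EntityMention:
    """Build a mention over an inclusive token range, deriving char offsets."""
    first = sentence.tokens[token_first]
    last = sentence.tokens[token_last]
    return EntityMention(
        category=category,
        token_first=token_first,
        token_last=token_last,
        char_start=first.start,
        char_end=last.end,
        source=source,
        rule_id=rule_id,
    )
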