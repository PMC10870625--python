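"""HTML-to-text extraction with a reversible offset map, sentence
splitting and tokenization.

The extractor is a custom parser built on the standard-library
``html.parser`` machinery: it keeps, for every character of the extracted
visible text, the range of source-document characters it was decoded from.
This is what makes end-of-pipeline masking possible — any span of extracted
text can be projected back onto the exact bytes of the original HTML.

Conventions (fixed so behaviour is reproducible):

* block-level elements contribute a newline to the extracted text (keeps
  letterhead lines separate); inline elements contribute nothing;
* ``script``/``style`` content is dropped;
* character/entity references decode to their character(s), mapped to the
  source range of the reference;
* sentence boundaries: any newline, and sentence-final ``. ! ? …`` followed
  by whitespace and an uppercase letter or digit, except after a known
  abbreviation ("Dr", "Mme", month abbreviations, single initials, ...);
* tokens are non-whitespace runs split at punctuation, except intra-token
  hyphens, elision apostrophes, ``@``/``.`` in e-mail addresses and
  ``. / -`` inside date- or phone-like digit runs.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from html.parser import HTMLParser

from frdeid.document_model import Sentence, SourceDocument, TokenSpan

# --------------------------------------------------------------------------
# Offset map
# --------------------------------------------------------------------------


@dataclass
class OffsetMap:
    """Per-character mapping from extracted text to source-document ranges.

    ``src_start[i]``/``src_end[i]`` is the half-open source range character
    ``i`` of the extracted text was decoded from.  Plain data characters map
    to a width-1 range; all characters decoded from one entity reference
    share the reference's range; synthetic newlines inserted at block-tag
    boundaries carry an empty range (they have no source text).  Starts are
    non-decreasing over the whole text and strictly increasing over
    characters with non-empty source ranges.
    """

    src_start: list[int] = field(default_factory=list)
    src_end: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.src_start)

    def append(self, start: int, end: int) -> None:
        self.src_start.append(start)
        self.src_end.append(end)

    def to_source(self, i: int) -> int:
        """Source position of extracted character *i* (its range start)."""
        return self.src_start[i]

    def source_runs(self, start: int, end: int) -> list[tuple[int, int]]:
        """Contiguous source ranges covering extracted span ``[start, end)``.

        A run breaks wherever the source positions jump (markup between two
        extracted characters), which is exactly where masking must preserve
        the intervening tags.  Empty ranges (synthetic newlines) are
        skipped.
        """
        runs: list[tuple[int, int]] = []
        for i in range(start, end):
            s, e = self.src_start[i], self.src_end[i]
            if s == e:
                continue
            if runs and runs[-1][1] == s:
                runs[-1] = (runs[-1][0], e)
            else:
                runs.append((s, e))
        return runs


# --------------------------------------------------------------------------
# HTML extraction
# --------------------------------------------------------------------------

#: Elements whose boundaries force a line break in the extracted text.
BLOCK_TAGS = frozenset(
    """address article aside blockquote body br caption div dd dl dt
    fieldset figcaption figure footer form h1 h2 h3 h4 h5 h6 header hr html
    li main nav ol option p pre section table tbody td tfoot th thead tr
    ul""".split()
)

_SKIP_TAGS = frozenset({"script", "style"})


class _ExtractingParser(HTMLParser):
    """Tolerant HTML parser that records source offsets of visible text."""

    def __init__(self) -> None:
        super().__init__(convert_charrefs=False)
        self.out: list[str] = []
        self.map = OffsetMap()
        self._skip_depth = 0
        self._line_starts: list[int] = [0]

    def feed_document(self, raw: str) -> None:
        pos = 0
        for line in raw.splitlines(keepends=True):
            pos += len(line)
            self._line_starts.append(pos)
        self.feed(raw)
        self.close()

    def _abs_pos(self) -> int:
        lineno, col = self.getpos()
        return self._line_starts[lineno - 1] + col

    def _emit(self, ch: str, src_start: int, src_end: int) -> None:
        self.out.append(ch)
        self.map.append(src_start, src_end)

    def _break_line(self) -> None:
        if self.out and self.out[-1] != "\n":
            p = self._abs_pos()
            self._emit("\n", p, p)

    # -- tag handling ------------------------------------------------------

    def handle_starttag(self, tag: str, attrs) -> None:
        if tag in _SKIP_TAGS:
            self._skip_depth += 1
        if tag in BLOCK_TAGS:
            self._break_line()

    def handle_startendtag(self, tag: str, attrs) -> None:
        if tag in BLOCK_TAGS:
            self._break_line()

    def handle_endtag(self, tag: str) -> None:
        if tag in _SKIP_TAGS and self._skip_depth:
            self._skip_depth -= 1
        if tag in BLOCK_TAGS:
            self._break_line()

    # -- character data ----------------------------------------------------

    def handle_data(self, data: str) -> None:
        if self._skip_depth:
            return
        base = self._abs_pos()
        for i, ch in enumerate(data):
            self._emit(ch, base + i, base + i + 1)

    def handle_entityref(self, name: str) -> None:
        if self._skip_depth:
            return
        base = self._abs_pos()
        ref = f"&{name};"
        decoded = _html.unescape(ref)
        if decoded == ref:  # unknown entity: keep verbatim
            for i, ch in enumerate(ref):
                self._emit(ch, base + i, base + i + 1)
            return
        for ch in decoded:
            self._emit(ch, base, base + len(ref))

    def handle_charref(self, name: str) -> None:
        if self._skip_depth:
            return
        base = self._abs_pos()
        ref = f"&#{name};"
        decoded = _html.unescape(ref)
        for ch in decoded:
            self._emit(ch, base, base + len(ref))


def parse_html(doc: SourceDocument | str) -> tuple[str, OffsetMap]:
    """Extract visible text from HTML with a character-level offset map.

    Accepts a :class:`SourceDocument` or a raw string.  Plain text (no
    markup) passes through with an identity map.  Parsing is tolerant:
    unclosed tags never raise.
    """
    raw = doc.raw if isinstance(doc, SourceDocument) else doc
    if not raw:
        return "", OffsetMap()
    parser = _ExtractingParser()
    parser.feed_document(raw)
    return "".join(parser.out), parser.map


# --------------------------------------------------------------------------
# Sentence splitting
# --------------------------------------------------------------------------

#: Words after which a period does not end a sentence.
ABBREVIATIONS = frozenset(
    """dr pr prof m mme mlle mr mrs st ste ste med ref tel fax ex cf etc
    janv fev févr avr juil sept oct nov dec déc""".split()
)

_UPPER = "A-ZÀÂÄÆÇÉÈÊËÎÏÔÖŒÙÛÜŸ"
_SENT_END = re.compile(rf"[.!?…]+(?=\s+[{_UPPER}0-9])")
_WORD_BEFORE = re.compile(r"([\w'’-]+)$", re.UNICODE)


def _split_line(line: str) -> list[tuple[str, int]]:
    """Split one physical line at sentence-final punctuation."""
    pieces: list[tuple[str, int]] = []
    start = 0
    for m in _SENT_END.finditer(line):
        wb = _WORD_BEFORE.search(line, start, m.start())
        if wb is not None:
            word = wb.group(1).rstrip(".")
            if word.lower() in ABBREVIATIONS or (len(word) == 1 and word.isalpha()):
                continue
        pieces.append((line[start:m.end()], start))
        start = m.end()
    if start < len(line):
        pieces.append((line[start:], start))
    return pieces


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split extracted text into sentences with their text offsets.

    Returns ``(sentence_text, offset)`` pairs where ``offset`` indexes the
    sentence's first character in *text*.  Sentences are stripped of leading
    and trailing whitespace; whitespace-only input yields an empty list.
    """
    out: list[tuple[str, int]] = []
    line_start = 0
    for line in text.split("\n"):
        for piece, rel in _split_line(line):
            stripped = piece.strip()
            if stripped:
                lead = len(piece) - len(piece.lstrip())
                out.append((stripped, line_start + rel + lead))
        line_start += len(line) + 1
    return out


# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

_L = rf"[a-z{_UPPER.lower()}{_UPPER}]"  # French letter, either case
_TOKEN = re.compile(
    rf"""
    [A-Za-z0-9._%+-]+@[A-Za-z0-9-]+(?:\.[A-Za-z0-9-]+)+   # e-mail
    | \d+(?:[./-]\d+)+                                    # date/phone run
    | {_L}['’]                                            # elision (l', d')
    | {_L}+(?:-{_L}+)*                                    # word, hyphens kept
    | \d+                                                 # number
    | \S                                                  # any other symbol
    """,
    re.VERBOSE,
)


def tokenize(
    sentence_text: str,
    text_offset: int = 0,
    offset_map: OffsetMap | None = None,
) -> list[TokenSpan]:
    """Tokenize a sentence into :class:`TokenSpan` objects.

    ``text_offset`` is the sentence's offset in the extracted document text;
    with an ``offset_map`` each token also receives its source-document
    character range, otherwise source offsets equal extracted-text offsets
    (identity map, appropriate for plain-text input).
    """
    tokens: list[TokenSpan] = []
    for i, m in enumerate(_TOKEN.finditer(sentence_text)):
        ext_start = text_offset + m.start()
        ext_end = text_offset + m.end()
        if offset_map is not None:
            start_char = offset_map.to_source(ext_start)
            end_char = offset_map.src_end[ext_end - 1]
        else:
            start_char, end_char = ext_start, ext_end
        tokens.append(
            TokenSpan(
                text=m.group(),
                start=m.start(),
                end=m.end(),
                start_char=start_char,
                end_char=end_char,
                id=i,
            )
        )
    return tokens


def ingest_document(doc: SourceDocument) -> tuple[list[Sentence], OffsetMap]:
    """Full ingestion: HTML → extracted text → sentences → tokens."""
    text, omap = parse_html(doc)
    sentences: list[Sentence] = []
    for idx, (sent_text, offset) in enumerate(split_sentences(text)):
        toks = tokenize(sent_text, text_offset=offset, offset_map=omap)
        sentences.append(
            Sentence(
                text=sent_text,
                tokens=toks,
                doc_ref=doc.doc_id,
                sent_index=idx,
                text_offset=offset,
            )
        )
    return sentences, omap
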