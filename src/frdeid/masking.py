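"""Offset-faithful masking of the original HTML.

Mentions detected on the extracted text are projected back onto the source
document through the offset map and replaced in place — every character
outside a masked range stays byte-identical, and markup is never touched
(a mention crossing a tag boundary is masked piecewise around the tags).

Two policies: ``placeholder`` replaces each span with "[CATEGORY]";
``surrogate`` replaces it with a same-category synthetic value drawn from
the corpus generator's samplers (never equal to the original surface).
"""

from __future__ import annotations

from dataclasses import dataclass

from frdeid.document_model import AnnotatedSentence, EntityMention, SourceDocument
from frdeid.ingest import OffsetMap


@dataclass
class MaskPolicy:
    mode: str = "placeholder"  # or "surrogate"
    template: str = "[{category}]"
    surrogate_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("placeholder", "surrogate"):
            raise ValueError(f"unknown mask mode {self.mode!r}")


def _replacement(
    mention: EntityMention, surface: str, policy: MaskPolicy, sampler
) -> str:
    if policy.mode == "placeholder":
        return policy.template.format(category=mention.category.value)
    value = sampler(mention.category, surface)
    return value


def mask_document(
    doc: SourceDocument,
    sentences: list[AnnotatedSentence],
    offset_map: OffsetMap,
    policy: MaskPolicy | None = None,
) -> str:
    """Return the document's HTML with every mention's source range replaced.

    ``sentences`` are the annotated sentences produced from *doc* (their
    ``text_offset`` fields position them in the extracted text that
    ``offset_map`` describes).
    """
    policy = policy or MaskPolicy()
    sampler = None
    if policy.mode == "surrogate":
        from frdeid.synthetic_corpus import surrogate_sampler

        sampler = surrogate_sampler(policy.surrogate_seed)

    # collect (source_start, source_end, replacement) edits
    edits: list[tuple[int, int, str]] = []
    for asent in sentences:
        base = asent.sentence.text_offset
        for m in asent.mentions:
            ext_start = base + m.char_start
            ext_end = base + m.char_end
            runs = offset_map.source_runs(ext_start, ext_end)
            if not runs:
                continue
            surface = asent.sentence.text[m.char_start:m.char_end]
            repl = _replacement(m, surface, policy, sampler)
            # tag-crossing mention: each visible-text part masked separately
            for s, e in runs:
                edits.append((s, e, repl))

    out = doc.raw
    for s, e, repl in sorted(edits, key=lambda t: t[0], reverse=True):
        out = out[:s] + repl + out[e:]
    return out
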