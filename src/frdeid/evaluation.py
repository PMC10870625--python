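"""Entity-level NER scoring.

Per-class and aggregate precision, recall and F1 with supports, for any two
annotation sets over the same sentences (gold vs. the rule cascade, or gold
vs. an external tagger's output read from the JSONL dialect).

Two matching criteria are provided:

* ``strict`` (default): a predicted mention is a true positive iff its
  category, start and end offsets all equal a gold mention, matched
  one-to-one;
* ``token``: counts are over per-token category labels, so partial span
  overlaps earn partial credit.

Aggregates follow the usual conventions: *micro* pools TP/FP/FN over
classes, *macro* averages per-class metrics unweighted, *weighted* averages
per-class metrics by gold support.  P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); any metric with a zero denominator is defined as 0 and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from frdeid.document_model import (
    AnnotatedSentence,
    EntityMention,
    PIICategory,
    CATEGORY_ORDER,
)


@dataclass
class ConfusionCounts:
    """Per-class true positives, false positives and false negatives."""

    tp: dict[PIICategory, int] = field(default_factory=dict)
    fp: dict[PIICategory, int] = field(default_factory=dict)
    fn: dict[PIICategory, int] = field(default_factory=dict)

    def add(self, other: "ConfusionCounts") -> None:
        for cat in CATEGORY_ORDER:
            self.tp[cat] = self.tp.get(cat, 0) + other.tp.get(cat, 0)
            self.fp[cat] = self.fp.get(cat, 0) + other.fp.get(cat, 0)
            self.fn[cat] = self.fn.get(cat, 0) + other.fn.get(cat, 0)

    def support(self, cat: PIICategory) -> int:
        return self.tp.get(cat, 0) + self.fn.get(cat, 0)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    degenerate: bool = False  # a zero denominator was hit


@dataclass
class EvalReport:
    per_class: dict[PIICategory, ClassMetrics]
    micro: ClassMetrics
    macro: ClassMetrics
    weighted: ClassMetrics

    def to_rows(self) -> list[tuple[str, float, float, float, int]]:
        rows = [
            (cat.value, m.precision, m.recall, m.f1, m.support)
            for cat, m in self.per_class.items()
        ]
        rows.append(("micro avg", self.micro.precision, self.micro.recall,
                     self.micro.f1, self.micro.support))
        rows.append(("macro avg", self.macro.precision, self.macro.recall,
                     self.macro.f1, self.macro.support))
        rows.append(("weighted avg", self.weighted.precision,
                     self.weighted.recall, self.weighted.f1,
                     self.weighted.support))
        return rows


def _check_no_overlap(mentions: list[EntityMention], which: str) -> None:
    ordered = sorted(mentions, key=lambda m: m.char_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping mentions in {which} annotation set")


def match_mentions(
    gold: list[EntityMention],
    pred: list[EntityMention],
    mode: str = "strict",
) -> ConfusionCounts:
    """Confusion counts between two mention sets over one sentence."""
    if mode not in ("strict", "token"):
        raise ValueError(f"unknown matching mode {mode!r}")
    _check_no_overlap(gold, "gold")
    _check_no_overlap(pred, "predicted")
    counts = ConfusionCounts()
    if mode == "strict":
        unmatched = {(m.category, m.char_start, m.char_end) for m in gold}
        for p in pred:
            key = (p.category, p.char_start, p.char_end)
            if key in unmatched:
                unmatched.discard(key)
                counts.tp[p.category] = counts.tp.get(p.category, 0) + 1
            else:
                counts.fp[p.category] = counts.fp.get(p.category, 0) + 1
        for cat, _, _ in unmatched:
            counts.fn[cat] = counts.fn.get(cat, 0) + 1
    else:
        def token_labels(mentions: list[EntityMention]) -> dict[int, PIICategory]:
            labels: dict[int, PIICategory] = {}
            for m in mentions:
                for t in range(m.token_first, m.token_last + 1):
                    labels[t] = m.category
            return labels

        g, p = token_labels(gold), token_labels(pred)
        for t, cat in p.items():
            if g.get(t) == cat:
                counts.tp[cat] = counts.tp.get(cat, 0) + 1
            else:
                counts.fp[cat] = counts.fp.get(cat, 0) + 1
        for t, cat in g.items():
            if p.get(t) != cat:
                counts.fn[cat] = counts.fn.get(cat, 0) + 1
    return counts


def match_corpora(
    gold: list[AnnotatedSentence],
    pred: list[AnnotatedSentence],
    mode: str = "strict",
) -> ConfusionCounts:
    """Pool confusion counts over aligned sentence lists."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted corpora differ in length")
    total = ConfusionCounts()
    for g, p in zip(gold, pred):
        total.add(match_mentions(g.mentions, p.mentions, mode=mode))
    return total


def _metrics(tp: int, fp: int, fn: int) -> ClassMetrics:
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(precision, recall, f1, tp + fn, degenerate)


def prf(counts: ConfusionCounts) -> EvalReport:
    """Per-class and micro/macro/weighted aggregate metrics.

    Classes absent from both gold and prediction are omitted from the
    per-class table and from the macro average.
    """
    per_class: dict[PIICategory, ClassMetrics] = {}
    for cat in CATEGORY_ORDER:
        tp = counts.tp.get(cat, 0)
        fp = counts.fp.get(cat, 0)
        fn = counts.fn.get(cat, 0)
        if tp + fp + fn == 0:
            continue
        per_class[cat] = _metrics(tp, fp, fn)

    tp_all = sum(counts.tp.values())
    fp_all = sum(counts.fp.values())
    fn_all = sum(counts.fn.values())
    micro = _metrics(tp_all, fp_all, fn_all)

    n_classes = len(per_class)
    total_support = sum(m.support for m in per_class.values())
    if n_classes == 0:
        macro = ClassMetrics(0.0, 0.0, 0.0, 0, degenerate=True)
        weighted = ClassMetrics(0.0, 0.0, 0.0, 0, degenerate=True)
    else:
        macro = ClassMetrics(
            precision=sum(m.precision for m in per_class.values()) / n_classes,
            recall=sum(m.recall for m in per_class.values()) / n_classes,
            f1=sum(m.f1 for m in per_class.values()) / n_classes,
            support=total_support,
        )
        if total_support == 0:
            weighted = ClassMetrics(0.0, 0.0, 0.0, 0, degenerate=True)
        else:
            weighted = ClassMetrics(
                precision=sum(m.precision * m.support for m in per_class.values()) / total_support,
                recall=sum(m.recall * m.support for m in per_class.values()) / total_support,
                f1=sum(m.f1 * m.support for m in per_class.values()) / total_support,
                support=total_support,
            )
    return EvalReport(per_class=per_class, micro=micro, macro=macro,
                      weighted=weighted)


def evaluate(
    gold: list[AnnotatedSentence],
    pred: list[AnnotatedSentence],
    mode: str = "strict",
) -> EvalReport:
    return prf(match_corpora(gold, pred, mode=mode))


def report_to_tsv(report: EvalReport) -> str:
    lines = ["Class\tPrecision\tRecall\tF1-score\tSupport"]
    for name, p, r, f1, support in report.to_rows():
        lines.append(f"{name}\t{p:.4f}\t{r:.4f}\t{f1:.4f}\t{support}")
    return "\n".join(lines) + "\n"
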