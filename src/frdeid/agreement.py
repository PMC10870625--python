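"""Multi-annotator concordance over token labelings.

Agreement is computed at the token level: every token of every shared
sentence is one item, and its rating is the entity tag covering it (the
eight PII categories plus ``O`` for tokens outside any entity).  The chance-
corrected statistic is Fleiss' kappa,

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e),

where ``P_bar`` is the mean pairwise agreement per item and ``P_bar_e`` the
chance agreement from the category marginals.  Confidence intervals come
from a document-level percentile bootstrap; pairwise agreement is Fleiss'
kappa restricted to the two raters (equivalently Scott's pi) on their
shared documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from frdeid.document_model import CATEGORY_ORDER

#: Token-level rating categories: outside + the eight PII classes.
TAG_CATEGORIES = ("O",) + tuple(c.value for c in CATEGORY_ORDER)


@dataclass
class RatedDocument:
    """Per-rater token labels for one document (all equal length)."""

    doc_id: str
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.labels.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"raters disagree on token count for document {self.doc_id}"
            )

    @property
    def raters(self) -> set[str]:
        return set(self.labels)

    @property
    def n_tokens(self) -> int:
        return len(next(iter(self.labels.values()))) if self.labels else 0


@dataclass
class AgreementReport:
    kappa: float
    ci_low: float
    ci_high: float
    per_tag: dict[str, float]
    pairwise: dict[tuple[str, str], tuple[float, tuple[float, float]] | None]


def build_rating_matrix(
    docs: list[RatedDocument],
    raters: list[str] | None = None,
    categories: tuple[str, ...] = TAG_CATEGORIES,
) -> np.ndarray:
    """Items x categories count matrix over the documents all given raters
    share.  Each row sums to the number of raters."""
    if raters is None:
        raters = sorted(set.union(set(), *(d.raters for d in docs)))
    cat_index = {c: k for k, c in enumerate(categories)}
    rows: list[list[int]] = []
    for doc in docs:
        if not set(raters) <= doc.raters:
            continue
        for t in range(doc.n_tokens):
            row = [0] * len(categories)
            for r in raters:
                row[cat_index[doc.labels[r][t]]] += 1
            rows.append(row)
    return np.asarray(rows, dtype=float).reshape(-1, len(categories))


def fleiss_kappa(matrix: np.ndarray) -> float:
    """Fleiss' kappa for an items x categories count matrix.

    Requires a constant number of raters n >= 2 per item.  When every
    rating falls in a single category the chance agreement is 1 and kappa
    is defined as 1.0 (all raters are trivially unanimous).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("rating matrix must be non-empty and 2-D")
    n_per_item = m.sum(axis=1)
    n = n_per_item[0]
    if n < 2 or not np.all(n_per_item == n):
        raise ValueError("every item needs the same number (>=2) of raters")
    p_item = (np.sum(m * m, axis=1) - n) / (n * (n - 1))
    p_bar = float(p_item.mean())
    marginals = m.sum(axis=0) / m.sum()
    p_e = float(np.sum(marginals**2))
    if p_e >= 1.0 - 1e-12:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def kappa_for_docs(
    docs: list[RatedDocument],
    raters: list[str] | None = None,
    categories: tuple[str, ...] = TAG_CATEGORIES,
) -> float:
    matrix = build_rating_matrix(docs, raters=raters, categories=categories)
    if matrix.shape[0] == 0:
        raise ValueError("no shared documents among the requested raters")
    return fleiss_kappa(matrix)


def per_tag_kappa(docs: list[RatedDocument], tag: str) -> float:
    """Fleiss' kappa on the binary tag-vs-rest reduction of the labels."""
    reduced = [
        RatedDocument(
            doc_id=d.doc_id,
            labels={
                r: [lab if lab == tag else "_other" for lab in labs]
                for r, labs in d.labels.items()
            },
        )
        for d in docs
    ]
    return kappa_for_docs(reduced, categories=(tag, "_other"))


def pairwise_agreement(
    docs: list[RatedDocument],
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], tuple[float, tuple[float, float]] | None]:
    """Two-rater kappa (with bootstrap CI) for every rater pair; pairs with
    no shared document are marked unavailable (None)."""
    raters = sorted(set.union(set(), *(d.raters for d in docs)))
    out: dict[tuple[str, str], tuple[float, tuple[float, float]] | None] = {}
    for a in raters:
        for b in raters:
            if b < a:
                continue
            pair = [a, b] if a != b else [a]
            shared = [d for d in docs if set(pair) <= d.raters]
            if a == b:
                out[(a, b)] = (1.0, (1.0, 1.0))
                continue
            if not shared:
                out[(a, b)] = None
                continue
            kappa = kappa_for_docs(shared, raters=pair)
            ci = kappa_ci(shared, raters=pair, level=level, reps=reps, seed=seed)
            out[(a, b)] = (kappa, ci)
    return out


def kappa_ci(
    docs: list[RatedDocument],
    raters: list[str] | None = None,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa, resampling documents."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if raters is None:
        raters = sorted(set.union(set(), *(d.raters for d in docs)))
    shared = [d for d in docs if set(raters) <= d.raters]
    if not shared:
        raise ValueError("no shared documents among the requested raters")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(reps):
        sample = [shared[k] for k in rng.integers(0, len(shared), len(shared))]
        try:
            estimates.append(kappa_for_docs(sample, raters=raters))
        except ValueError:
            continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def rated_documents_from_sentences(sentences) -> list[RatedDocument]:
    """Group annotated sentences (JSONL dialect) into per-document,
    per-rater token labelings.

    Each record contributes its BIO-derived token tags under the rater
    named by ``meta["annotator"]`` for the document ``meta["ID_ENTREPOT"]``;
    sentences are concatenated in input order per (document, rater).
    """
    from frdeid.bio_corpus import bio_encode

    per_doc: dict[str, dict[str, list[str]]] = {}
    for asent in sentences:
        doc_id = str(asent.meta.get("ID_ENTREPOT", ""))
        rater = str(asent.meta.get("annotator", ""))
        tags = bio_encode(asent.sentence, asent.mentions)
        labels = [t.split("-", 1)[1] if t != "O" else "O" for t in tags]
        per_doc.setdefault(doc_id, {}).setdefault(rater, []).extend(labels)
    return [
        RatedDocument(doc_id=d, labels=labels) for d, labels in per_doc.items()
    ]


def agreement_report(
    docs: list[RatedDocument],
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> AgreementReport:
    """Overall kappa + CI, per-tag kappas, and the pairwise matrix, over the
    documents shared by all raters (overall/per-tag) or by each pair."""
    raters = sorted(set.union(set(), *(d.raters for d in docs)))
    shared = [d for d in docs if set(raters) <= d.raters]
    kappa = kappa_for_docs(shared, raters=raters)
    lo, hi = kappa_ci(shared, raters=raters, level=level, reps=reps, seed=seed)
    per_tag: dict[str, float] = {}
    for tag in TAG_CATEGORIES:
        try:
            per_tag[tag] = per_tag_kappa(shared, tag)
        except ValueError:
            continue
    pairwise = pairwise_agreement(docs, level=level, reps=reps, seed=seed)
    return AgreementReport(kappa=kappa, ci_low=lo, ci_high=hi,
                           per_tag=per_tag, pairwise=pairwise)
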