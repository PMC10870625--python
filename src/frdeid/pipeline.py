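"""End-to-end orchestration: ingest -> gazetteers -> annotate -> filter ->
patient-level split -> corpus files + statistics.

Input layout: a directory of ``.html`` (or ``.txt``) documents named by
document id, plus a ``metadata.csv`` with columns ``doc_id``,
``patient_id``, ``first_name``, ``last_name``, ``birthdate`` (ISO).  The
gazetteer directory holds ``ban.csv`` and ``annuaire.csv`` in the national
directory schemas.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from frdeid.bio_corpus import (
    AnnotatedDocument,
    corpus_stats,
    filter_sentences,
    split_by_patient,
    write_conll,
    write_jsonl,
    PARTITIONS,
)
from frdeid.document_model import AnnotatedSentence, SourceDocument
from frdeid.gazetteer import load_ban, load_health_directory
from frdeid.ingest import ingest_document
from frdeid.rule_annotator import (
    GazetteerSet,
    PatientRecordKeys,
    RuleConfig,
    annotate_sentence,
)

logger = logging.getLogger("frdeid")


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing paths, bad ratios)."""


class DataError(ValueError):
    """A document or corpus file could not be processed."""


@dataclass
class PipelineConfig:
    input_dir: Path
    gazetteer_dir: Path
    output_dir: Path
    rules: RuleConfig = field(default_factory=RuleConfig)
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    eval_mode: str = "strict"

    def validate(self) -> None:
        for p in (self.input_dir, self.gazetteer_dir):
            if not Path(p).is_dir():
                raise ConfigError(f"directory does not exist: {p}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError(f"split ratios must sum to 1: {self.ratios}")


def load_input_documents(input_dir: str | Path) -> list[SourceDocument]:
    """Load documents + metadata from an input directory."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    meta: dict[str, dict] = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                meta[row["doc_id"]] = row
    docs: list[SourceDocument] = []
    for path in sorted(list(input_dir.glob("*.html")) + list(input_dir.glob("*.txt"))):
        doc_id = path.stem
        row = meta.get(doc_id, {})
        birth = None
        if row.get("birthdate"):
            birth = date.fromisoformat(row["birthdate"])
        docs.append(
            SourceDocument(
                doc_id=doc_id,
                patient_id=row.get("patient_id", doc_id),
                raw=path.read_text(encoding="utf-8"),
                dialect="native-HTML" if path.suffix == ".html" else "plain-text",
                patient_first_name=row.get("first_name", ""),
                patient_last_name=row.get("last_name", ""),
                birthdate=birth,
                code=row.get("code", ""),
            )
        )
    return docs


def load_gazetteers(gazetteer_dir: str | Path) -> GazetteerSet:
    gdir = Path(gazetteer_dir)
    gaz = GazetteerSet()
    ban = gdir / "ban.csv"
    if ban.exists():
        gaz.street, gaz.zip, gaz.ville = load_ban(ban)
    hd = gdir / "annuaire.csv"
    if hd.exists():
        gaz.doctor = load_health_directory(hd)
    return gaz


def annotate_documents(
    docs: list[SourceDocument],
    gazetteers: GazetteerSet,
    rules: RuleConfig,
) -> list[AnnotatedDocument]:
    out: list[AnnotatedDocument] = []
    for doc in docs:
        try:
            sentences, _ = ingest_document(doc)
            keys = PatientRecordKeys.from_document(doc)
            annotated = [
                AnnotatedSentence(
                    sentence=s,
                    mentions=annotate_sentence(s, rules, gazetteers, keys),
                    meta={
                        "ID_PAT": doc.patient_id,
                        "ID_ENTREPOT": doc.doc_id,
                        "CODE": doc.code,
                    },
                )
                for s in sentences
            ]
            out.append(AnnotatedDocument(doc.doc_id, doc.patient_id, annotated))
        except Exception as exc:
            raise DataError(f"annotation failed for document {doc.doc_id}: {exc}") from exc
    return out


def run_distant_supervision(cfg: PipelineConfig) -> dict:
    """Execute the full distant-supervision path and write the corpus.

    Returns a summary dict with per-stage counts and per-partition
    statistics; also written to ``run.log`` in the output directory.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    docs = load_input_documents(cfg.input_dir)
    if not docs:
        logger.warning("no input documents found in %s", cfg.input_dir)
    gazetteers = load_gazetteers(cfg.gazetteer_dir)
    annotated = annotate_documents(docs, gazetteers, cfg.rules)

    split = split_by_patient(
        sorted({d.patient_id for d in annotated}), cfg.ratios, cfg.seed
    )

    partitions: dict[str, list[AnnotatedSentence]] = {p: [] for p in PARTITIONS}
    n_sentences = 0
    for doc in annotated:
        kept = filter_sentences(doc.sentences)
        n_sentences += len(doc.sentences)
        partitions[split.partition_of(doc.patient_id)].extend(kept)

    summary: dict = {
        "n_documents": len(docs),
        "n_sentences": n_sentences,
        "seed": cfg.seed,
        "ratios": list(cfg.ratios),
        "partitions": {},
    }
    for name, sents in partitions.items():
        write_jsonl(sents, out_dir / f"{name}.jsonl")
        write_conll(sents, out_dir / f"{name}.conll")
        stats = corpus_stats(sents)
        summary["partitions"][name] = {
            "n_sentences": stats.n_sentences,
            "counts": {c.value: n for c, n in stats.counts.items()},
            "percentages": {c.value: p for c, p in stats.percentages.items()},
        }

    log_lines = [f"documents={len(docs)} sentences={n_sentences} seed={cfg.seed}"]
    for name in PARTITIONS:
        part = summary["partitions"][name]
        log_lines.append(
            f"{name}: sentences={part['n_sentences']} "
            f"mentions={sum(part['counts'].values())}"
        )
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    for msg in log_lines:
        logger.info(msg)
    return summary
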