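# frdeid — de-identification of French clinical text by distant supervision

Clinical free text is full of personally identifiable information (PII):
patient and practitioner names, dates, addresses, phone numbers.  Before
such documents can be reused for research, that PII must be found and
masked.  Manually annotating enough text to train a de-identification
system is expensive, so this package implements the *distant-supervision*
alternative: PII labels are produced automatically by rules, record
metadata, and gazetteers built from the French national address database
(BAN) and the Health Directory of practitioners, and the resulting silver
corpus can train any downstream sequence tagger.

The package is aimed at clinical-NLP engineers and data-warehouse teams
working with French EHR documents.  It provides:

* **Ingestion** — a tolerant HTML parser that keeps, for every extracted
  character, its source offset, so any annotation can be projected back
  onto the original document; deterministic French sentence splitting and
  tokenization.
* **Gazetteers** — normalized dictionaries for streets, zip codes, cities
  (BAN schema: `nom_voie`, `code_postal`, `nom_commune`) and practitioner
  names (Health Directory schema: `Nom d'exercice`, `Prenom d'exercice`),
  with compound-name expansion ("JEAN-PIERRE" → JEAN, PIERRE) and
  ambiguity filtering (`DE`, `DU`, `LA`, single letters, ...).
* **Rule cascade** — eight per-category detectors (PATIENT, DOCTOR, DATE,
  EMAIL, PHONE, STR, ZIP, VILLE) combining patterns (`dd/mm/yyyy`,
  `02 99 00 00 00`, 5-digit zips, e-mail grammar), orthography, street
  cues ("RUE", "Ave"), title triggers ("Dr", "Docteur"), gazetteer lookup
  and patient record metadata, with longest-span-first overlap resolution.
* **Corpus building** — BIO encoding/decoding, filtering to sentences with
  at least one entity, patient-level 80/10/10 splits (all documents of one
  patient stay together), JSONL (`text` / `meta` / `tokens_parser` /
  `spans`) and CoNLL writers.
* **Evaluation** — entity-level precision, recall and F1 (strict span+type
  or token criterion), per class and micro/macro/weighted:
  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).
* **Agreement** — Fleiss' κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) over token labels, with
  per-tag κ, pairwise rater matrices, and document-level bootstrap CIs.
* **Masking** — placeholder or surrogate replacement applied to the
  original HTML through the offset map, leaving markup untouched.
* **Synthetic corpus** — a generator of French-style clinical HTML with
  letterhead, body and signature blocks, gold PII spans known by
  construction, companion gazetteer files, and a noise model (typos,
  accent dropping, abbreviation), so the whole pipeline is testable
  without access to any real hospital data.

## Worked example

```bash
# generate an 80-document synthetic corpus with gazetteers
deid synth --patients 40 --seed 13 --out corpus/

# run the full distant-supervision pipeline
deid run --in corpus/ --gaz corpus/gaz --out build/ --seed 5
```

The `run` command prints a summary (abridged):

```json
{
  "n_documents": 80,
  "n_sentences": 2253,
  "partitions": {
    "train": {"n_sentences": 1446, "counts": {"DATE": 408, "DOCTOR": 331, "...": "..."}},
    "valid": {"n_sentences": 143,  "counts": {"DATE": 44,  "DOCTOR": 27,  "...": "..."}},
    "test":  {"n_sentences": 281,  "counts": {"DATE": 73,  "DOCTOR": 79,  "...": "..."}}
  }
}
```

Every sentence written to `build/{train,valid,test}.jsonl` carries at least
one mention, partitions are patient-disjoint, and `build/*.conll` holds the
same data as token/BIO-tag pairs.  Scoring the cascade's output against a
gold file uses the evaluation engine:

```bash
deid eval --gold corpus/gold.jsonl --pred pred.jsonl --mode strict
```

which prints a per-class table (`Class  Precision  Recall  F1-score
Support`) followed by micro/macro/weighted rows; on a noise-free synthetic
corpus with complete gazetteers the cascade reaches micro precision and
recall of 1.0000 by construction, and realistic noise lowers recall first
(dictionary classes degrade as surface forms are corrupted).

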