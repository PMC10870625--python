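# Methods

This note documents the models, conventions and design decisions behind
each stage of the pipeline, including the choices made where the design
space was genuinely open, and what passing the test suite does and does
not establish.

## Offset conventions

All offsets are 0-based and half-open `[start, end)`.  A token carries two
coordinates: sentence-local (`start`/`end` into the sentence text) and
source-document (`start_char`/`end_char` into the decoded characters of
the original HTML).  Source offsets index decoded characters, not bytes;
the per-character offset map stores for every extracted character the
half-open source range it was decoded from.  Plain data characters map to
width-1 ranges; all characters decoded from one entity reference
(`&eacute;` → `é`) share the reference's range; newlines inserted at
block-tag boundaries carry an empty range, since they have no source text.
This representation makes masking exact: an extracted-text span projects
to a list of contiguous source runs, which break precisely where markup
intervenes, so a mention crossing a tag boundary is masked piecewise and
the markup survives untouched.

## HTML extraction

The extractor is built on the standard-library `html.parser` machinery and
is tolerant by construction (unclosed tags never raise).  Block-level
elements (`p`, `div`, `br`, `tr`, `li`, headings, ...) contribute one
newline to the extracted text — this keeps letterhead lines separate —
while inline elements contribute nothing.  `script`/`style` content is
dropped.  Tables and headers are linearized in document order; no
column-aware layout reconstruction is attempted.

## Sentence splitting and tokenization

No canonical rule set exists for clinical French, so the splitter fixes a
deterministic one: a boundary at every newline of the extracted text
(block elements emit newlines, so this separates letterhead lines), and at
sentence-final `. ! ? …` followed by whitespace and an uppercase letter or
digit, except after a known abbreviation (`Dr`, `Pr`, `M`, `Mme`, month
abbreviations, ...) or a single-letter initial (`J. DUPONT`).

The tokenizer keeps together the surface forms the detectors need whole:
e-mail addresses, digit runs joined by `/ . -` (dates, dotted phone
numbers), hyphenated words (`JEAN-PIERRE`, `SAINT-MALO`), and elision
clitics (`l'`, `d'`) as separate tokens.  Everything else splits at
whitespace and punctuation.  Tokenizing a token's own text returns that
single token (idempotence, property-tested).

## Gazetteers

Matching is uppercase, diacritic-stripped (NFKD, combining marks removed)
and whitespace-collapsed, because directory files and clinical text
disagree on accents and case.  Compound given names are expanded into
their hyphen-separated parts.  The ambiguity stop set is
`{DE, DU, DES, LE, LA, L, D}` extended with all single letters, with a
minimum term length of 2; both are configuration fields, since any fixed
list is a judgment call.  Place names are indexed under both hyphenated
and space-separated variants (`SAINT-MALO` / `SAINT MALO`), as both occur
in text.  The abbreviation table ships `Ave → Avenue`, `St → Saint` and
the like as *expansions*, while `Dr` and `Pr` are *role markers*: they
trigger a person mention but are never part of its span.

## The rule cascade

Per-category detectors:

* **DATE** — numeric `dd/mm/yyyy`, `dd-mm-yyyy`, `dd.mm.yyyy`, `dd/mm/yy`,
  `yyyy-mm-dd` with day ≤ 31 and month ≤ 12 validated, and lexical dates
  (optional day name, day number, month word or abbreviation, optional
  year).
* **PHONE** — 3-to-5 two-digit groups joined by space, `.` or `-`, or a
  contiguous 10-digit run starting with 0.  The floor of 3 groups admits
  the short dotted forms that appear on real reports.
* **ZIP** — standalone 5-digit tokens, accepted when in the zip gazetteer
  or within the context window of a city hit or street cue.
* **EMAIL** — `local@domain.tld` grammar per token.
* **STR** — a street-cue token (`RUE`, `AVENUE`, ..., or an abbreviation
  expanding to one) anchors a span over an optional leading house number
  and the following capitalized tokens; particles (`de`, `la`, ...) may
  intervene but the span must contain at least one capitalized
  continuation and ends at the last one.
* **VILLE** — longest gazetteer match over token runs; lowercase hits
  need an adjacent zip or street cue, an interpretation of orthographic
  gating that controls false positives.
* **DOCTOR** — (a) a title trigger followed within a 4-token window by
  capitalized tokens (the title itself excluded from the span); (b) runs
  of capitalized tokens found in the practitioner-name gazetteer.
* **PATIENT** — case- and diacritic-insensitive echoes of the patient's
  name parts from record metadata (compound-expanded); the record
  birthdate is additionally expanded into every configured date format
  and matched as DATE.

Overlap resolution is greedy longest-span-first with ties broken by a
fixed category priority — PATIENT > DOCTOR > EMAIL > PHONE > DATE > STR >
ZIP > VILLE — placing metadata-grounded and structurally unambiguous
classes first; position breaks any remaining tie, so the cascade is fully
deterministic.  The trigger window of 4 tokens and the priority order are
package choices; nothing in the task pins them, and both are exposed in
`RuleConfig`.

## Corpus construction

BIO encoding is standard; decoding repairs invalid sequences by opening a
new mention at an orphan `I-X` (equivalent to reading it as `B-X`).
Sentence filtering keeps exactly the sentences with at least one mention.
The patient-level split hashes `"{seed}:{patient_id}"` with SHA-256, maps
the digest to [0, 1) and thresholds at the cumulative ratios — a
reproducible, order-independent mechanism that needs no stored state; for
10,000 patients the realized train fraction is within ±0.02 of 0.8 (five
binomial standard deviations).  Category percentages are rounded half-up
to one decimal.

The JSONL dialect carries `text`, `meta` (`ID_PAT`, `ID_ENTREPOT`,
`CODE`, `annotator`, `annotator2`), `tokens_parser` (both offset systems
per token) and `spans` (sentence-local, half-open, labeled).  Reading then
writing a file is byte-identical.

## Evaluation

Strict mode (default) counts a prediction as a true positive only when
category, start and end all equal a gold mention, matched one-to-one;
token mode scores per-token category labels and gives partial credit.
Micro pools TP/FP/FN; macro averages per-class metrics unweighted over the
classes present; weighted averages by gold support.  Metrics with zero
denominators are defined as 0 and flagged.  Token mode is cross-checked
against scikit-learn's micro precision/recall on identical label
sequences; strict counts are checked against a brute-force one-to-one
matching oracle.

## Agreement

Fleiss' κ is computed from the items × categories count matrix over token
labels, with `O` as a first-class category (tokens outside entities are
rated too).  When every rating falls in one category, chance agreement is
1 and κ is defined as 1.0 (trivially unanimous).  Confidence intervals
use a document-level percentile bootstrap (default 1,000 replicates,
seeded); pairwise agreement is Fleiss' κ restricted to the two raters
(equivalently Scott's π) on their shared documents, with `NA` for pairs
sharing none.  The implementation is checked to machine precision against
both a direct-formula oracle and `statsmodels`' Fleiss kappa.

## Masking

Placeholder mode substitutes `[CATEGORY]`; the template is configurable.
Surrogate mode draws a same-category replacement from the synthetic
samplers under a fixed seed and never emits a value equal to the masked
surface.  Characters outside masked source runs are byte-identical to the
input, placeholder masking is idempotent (placeholders match no detector),
and on synthetic corpora zero gold surfaces survive re-extraction of the
masked output.  Surrogates are not kept consistent across documents of a
patient; that would require cross-document state and is out of scope.

## Synthetic corpus

Each document is HTML with a letterhead (hospital with city, titled
doctor, address line "number STREET, ZIP CITY", phone, e-mail, letter
date), a body echoing the patient's name and birthdate plus templated
sentences, and a signature.  The per-document category mix is drawn
`Multinomial(25, profile)` where the default profile is the mention-share
distribution of the large automatically annotated corpus this generator
emulates (DATE 27.2 %, DOCTOR 21.4 %, VILLE 14.0 %, PHONE 12.2 %,
PATIENT 10.2 %, ZIP 7.2 %, STR 6.4 %, EMAIL 1.5 %); letterhead elements
are rendered only when the sampled counts allow, and the remainder is
realized by body templates, so realized shares equal the sampled
multinomial exactly.

Noise is applied per word as the fragments are assembled, before gold
offsets are recorded: adjacent transposition or interior deletion
(words ≥ 4 letters, so boundaries survive), accent stripping, and cue-word
abbreviation.  Gold spans therefore cover the *noisy* surfaces — the
situation distant supervision actually faces — and rising typo rates
provably degrade dictionary-class recall while trigger-based detection is
more robust.  Gazetteer files include each universe entity independently
with probability `gazetteer_coverage`, plus filler names never used in
text.

Deliberate idealizations: patient and doctor name pools are disjoint from
each other and from street/city/prose vocabulary, so strict-span scores on
synthetic data are not confounded by homonyms; templates are short and
regular; narrative clinical content is absent.  Perfect cascade scores on
the clean synthetic corpus therefore demonstrate the *internal
consistency* of generator, ingester, annotator and scorer — not expected
performance on real text, where ambiguity, homonymy and layout noise
dominate the error budget.

## Problem sizes

The bundled checks run at desk scale, chosen to exercise every code path
with comfortable statistical margins: 100–200 documents for end-to-end
and masking checks (≈ 2,500 gold mentions), 1,000 randomized mention sets
for the BIO round trip, 100 random matrices for the κ oracle, and 10,000
patients for the split contract.

## Known limitations

* French only; no statistical disambiguation of person vs. place names,
  and no coreference.
* The sentence splitter's abbreviation list is finite; unseen
  abbreviations can over-split.
* Gazetteer-based DOCTOR detection will flag any capitalized directory
  name; on real text precision depends on directory curation.
* The evaluation engine assumes non-overlapping mention sets on both
  sides (the cascade and BIO decoding guarantee this for package-produced
  data).
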