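# Methods

## The benchmark procedure

babeldx implements a five-stage evaluation of ranked differential
diagnosis from structured phenotype data, across languages:

1. **Case ingestion.** Cases are clinical vignettes in a strict subset
   of the GA4GH Phenopacket Schema v2 JSON: subject id, sex, age
   (ISO-8601 duration, kept verbatim as a string), an ordered list of
   phenotype terms (`HP:` CURIEs) each flagged observed or excluded and
   optionally carrying an onset, and a curated diagnosis (disease CURIE,
   label, optional disease-level onset). Unknown fields are ignored
   with a logged warning so richer phenopackets still load. The
   diagnosis is carried for scoring only; the prompt renderer refuses
   to emit it.

2. **Cohort filter.** A case enters the analyzed cohort only if *every*
   one of its phenotype terms — observed and excluded alike — has a
   translation in all eight non-English study languages. This is the
   defining restriction of the corpus the benchmark emulates: it makes
   the nine per-language runs strictly comparable, at the cost of a
   smaller cohort.

3. **Prompt rendering.** Each language ships a template: constant
   header (task statement and the statement that the case is a genetic
   disease), an example-output block that is always in English, an
   explicit directive to answer in English, and phrase templates for
   the sex/age sentence, disease-onset sentence, observed-features
   sentence and excluded-features sentence, with per-language list
   connectors. Rendering is a pure function of (vignette, language,
   lexicon, templates), so prompts are byte-reproducible. A final
   substring scan raises if the diagnosis label or id would leak.

4. **Querying.** A backend maps prompt → raw text. The mock backend
   (below) is the default; a recorded backend replays a response
   directory; a live adapter exists behind the same contract but is
   never exercised by tests.

5. **Scoring.** The raw text is parsed for a numbered or bulleted list
   (rank markers, trailing punctuation and trailing parenthetical gene
   annotations stripped; no truncation at parse time). Each candidate
   is grounded by exact match after normalization — NFKC, casefold,
   punctuation→space, whitespace collapse, leading/trailing English
   article dropped — first against primary disease labels, then
   synonyms. A synonym shared by more than one disease grounds nothing
   (a deterministic failure beats an arbitrary pick). The case outcome
   is RANKED(k) at the smallest rank whose grounding lies in the
   truth's equivalence class — the clinical disease plus all of its
   genetic subtypes, via a single-level subtype→group-head link map —
   NOT_RANKED if none does, NO_DIAGNOSIS if no list was parseable.

### Reporting

Per language: Top-1/Top-3/Top-10 cumulative counts, Not Ranked, No
Diagnosis, with the conservation law Top-10 + Not Ranked + No
Diagnosis = n enforced by the summary type itself. A correct hit
beyond rank 10 is reported as Not Ranked: the cap is a reporting
policy, and parsing keeps all ranks so the policy is changeable in one
place. Frequencies are 100·Top-N/(n − NoDiagnosis), rounded half-up to
one decimal using exact integer arithmetic (no binary-float ties).

Cross-language comparison is a Kruskal-Wallis H-test (scipy, tie
corrected, chi-squared reference with groups − 1 degrees of freedom)
over per-case ordinal scores. The score construction is genuinely
underdetermined for unsolved cases, so it is explicit and configurable:
by default RANKED(k) → k, NOT_RANKED → 11 (one beyond the reporting
cap), NO_DIAGNOSIS excluded; an alternative includes No-Diagnosis cases
at score 12. The construction used is written into the run manifest.
When every pooled observation is identical the statistic is defined as
H = 0, p = 1 (no between-group variation).

## The mock backend

The mock realizes a planted per-language outcome distribution:
P(correct at rank k) for k ≥ 1, P(not ranked), P(refusal), which must
sum to 1 (tolerance 1e-9). Two planting modes:

* **exact** (default): outcomes are apportioned to cases by largest
  remainder and assigned through a seeded permutation — aggregate
  counts match the distribution as closely as integers allow, which
  makes aggregation tests exact and lets the ledger be joined
  case-by-case;
* **sample**: each case draws independently, for statistical
  recovery tests at binomial tolerances.

Responses are numbered lists of `n_items` (default 10, stretched to
the planted rank when larger) disease names. Distractors are sampled
from the graph *excluding* the truth's equivalence class, so a
NOT_RANKED case can never be an accidental subtype hit. The correct
answer is the truth's primary label, or — at `synonym_rate`
(default 0.3) — an unambiguous label/synonym of any member of its
equivalence class, exercising the subtype rollup. Each distractor item
is independently replaced by an ungroundable string at
`ungroundable_rate` (default 0.05, within the few-percent item-level
grounding-failure band typical of this kind of pipeline). Refusals are
drawn from a small multilingual bank that includes the canonical
English refusal sentence the parser must classify as NO_DIAGNOSIS.
Every draw comes from a generator keyed by (seed, language, case
index), so responses are independent of query order.

## The synthetic-data generator

Defaults mirror the emulated corpus: 4967 cases, 378 clinical
diseases, 2618 phenotype terms, nine languages, mean 14 phenotype
terms per case. Other shape parameters the corpus description does not
fix were chosen once as field-realistic: subtype counts uniform on
0–6 (anchored by the six-subform example that motivates the
equivalence rule), synonyms per disease Poisson with mean 2, excluded
features at 20% of terms (at least one observed term guaranteed), 90%
of subjects with a recorded age, feature-level onsets on 20% of
observed features and a disease-level onset on half the cases.
Per-case term counts are a shifted Poisson (1 + Poisson(mean − 1)) so
the configured mean is preserved while every case keeps ≥ 1 observed
term; a `terms_per_case_fixed` switch yields constant-size cases for
exact fixtures. At `translation_completeness_rate` < 1 a term is made
incomplete by deleting a random non-empty subset of its non-English
entries; the ledger records exactly which cases remain fully
translated, so the cohort filter can be checked against the plant
rather than against itself.

What the generator does **not** emulate, and what passing tests
therefore do not show: disease–phenotype co-occurrence (case features
are clinically arbitrary, so nothing here validates diagnostic
*difficulty*), real translation quality (non-English labels are
language-tagged pseudo-translations — the machinery needs distinct
strings, not linguistics), real Mondo synonymy breadth or ambiguity
structure, and any actual LLM behavior beyond the list/refusal/
ungroundable response shapes. Results on synthetic fixtures validate
the measurement machinery, not model performance.

## Numerical and design choices

* **Published counts as package data.** The per-language outcome
  counts of the reference GPT-4o benchmark ship as a TSV; the
  reporting layer recomputes all percentages from the raw counts at
  run time (single source of truth, never stored percentages).
* **Rounding** is half-up at one decimal via integer arithmetic
  `(2000·a + b) // (2·b) / 10`, immune to binary-float representation
  of ties.
* **Grounding is English-only** (labels/synonyms of the disease graph),
  matching the answer-in-English study design; non-English candidates
  are counted as grounding failures, and the two failure sources
  (model wrong vs mapping missed) are deliberately not disentangled —
  they are not separable without manual review.
* **Exact match only**: no fuzzy or edit-distance grounding, because
  approximate matching would silently change failure statistics.
  EXACT and RELATED synonym scopes are both indexed by default, with
  an `exact_only` flag to restrict.
* **Grounding-failure rate** is item-level (failed items / all
  candidate items), counting duplicated candidate strings per
  occurrence; empty input yields 0.
* **Subtype links are single-level** (subtype → clinical group head,
  no chains); the graph validator rejects a head that is itself a
  subtype, which also guarantees acyclicity.
* **Ages and onsets** stay ISO-8601 strings end-to-end and are
  interpreted only at rendering: years if ≥ 1 year, else months, else
  days — natural clinical phrasing. Onset-class CURIEs render via
  their lexicon label, falling back to the raw CURIE.
* **Excluded features** render as one negated sentence listing the
  excluded labels (the template set's choice; per-feature negation
  would be a template-only change).
* **Degenerate inputs**: empty cohort directories, all-No-Diagnosis
  summaries, single-group H-tests and zero-item failure rates all
  raise typed errors or return defined values rather than NaNs.

## Problem sizes used in tests

The default test suite runs on 25–60-disease graphs, 80–120-term
vocabularies and 40–200-case cohorts, with two statistical recovery
runs at n = 5000 (term-count mean) and n = 4967/2000 (outcome
recovery); the full-size generator defaults are exercised through the
same code paths. Statistical assertions use 3-standard-error binomial
tolerances at the planted parameters.

## Known limitations

* The parser recognizes numbered and bulleted lists; prose-embedded
  differentials ("the most likely diagnosis is X, followed by Y")
  become NO_DIAGNOSIS. The reference study's prompt format makes this
  rare, but recorded corpora from other prompts may need a parser
  extension.
* Template grammar is deliberately simple (no declension/agreement
  machinery); templates are data, so better phrasing is a YAML edit,
  not a code change.
* The Kruskal-Wallis input construction for unsolved cases is a
  convention, not a fact of the data; conclusions sensitive to the
  choice should be checked under the alternative constructions the
  API exposes.
* The live backend is an untested stub by design; recorded-response
  directories are the supported route for evaluating a real model.
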