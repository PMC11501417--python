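# Methods

This note records the models, conventions and numerical choices behind
`semiokit`, in the order the pipeline runs.

## Lexicon and surface matching

A lexicon is a flat dictionary of terms, each with per-language
canonical labels, synonym lists, a category (symptom, location, or a
cue category), and an optional `parent_id` hierarchy carried as
metadata only — extraction never reasons over the hierarchy. Surfaces
are normalized by trimming, lowercasing, and full-width/half-width
unification (character-by-character NFKC, so offsets into raw text stay
valid for CJK input). Within one language a surface may belong to only
one term: a duplicate across terms — whether or not the categories
differ — is a load-time error rather than a runtime tie-break, because
a dictionary-driven matcher has no principled way to choose between
homonymous entries.

Matching is greedy leftmost-longest: at each position the longest index
entry starting there wins and the scanner jumps past it. This is
exactly maximum "coarsest-granularity" phrase extraction — a fixed
collocation such as "tonic clonic" is never split into its sub-terms —
and it is verified against an exhaustive enumerate-then-schedule oracle
in the tests. Latin-script matches must sit on alphanumeric boundaries
("tonic" does not fire inside "catatonic"); CJK text needs no boundary.
Unmatched text is ignored: there is no open-vocabulary fallback.

The bundled English lexicon is synthetic in the sense that it was
authored for this package (103 primary symptom terms spanning motor,
autonomic, automatism, sensory/aura, awareness and speech/behavioral
signs, plus 16 seizure-site terms and common synonyms); it is a
working default, not a clinically validated terminology.

## Clause segmentation and cue scope

Narratives are partitioned into clauses at sentence punctuation
(including CJK punctuation and commas) and before adversative
connectives ("but", "however", ...). Spans are contiguous and cover the
text, so clause-relative offsets are document offsets.

Status assignment uses a windowed pre-mention cue scope: a negation cue
("no", "without", "denies", ...) within 6 tokens (10 characters for
unsegmented CJK) before the mention, with no intervening connective,
yields `without`; an uncertainty cue ("possibly", "unclear", ...)
yields `unknown`; otherwise `with`. The nearest in-scope cue wins.
Mention surfaces already matched in the clause are masked before cue
search, so a cue word embedded in a synonym ("**no** response to
calling") cannot scope over a neighbouring mention. Scope resolution
sits behind a `ScopeResolver` interface so a dependency-parser-backed
resolver can replace the window rule without touching the engine; the
window rule is the package's documented default because no parse-based
scope algorithm is specified anywhere we could follow, and pretrained
Chinese parsing models are deliberately not a dependency.

`unknown` is produced only by explicit uncertainty cues, never by
absence of a mention.

## Temporal normalization and anchoring

Durations normalize by unit table (s = 1, min = 60, h = 3600); numeric
ranges take the arithmetic midpoint ("1–2 minutes" → 90 s).
Frequencies normalize to events/day with day = 1, week = 7, month = 30,
year = 365 ("once a month" → 1/30 ≈ 0.033). Both conventions are
package choices — clinical text states no arithmetic — and are applied
consistently by the generator, so round-trip tests are exact. A
negative lookahead keeps relative time stamps ("2 minutes ago") from
being read as durations.

Temporal anchors are relative-time patterns ("3 years ago"), a few
absolute forms ("in 2015", "since childhood"), and configurable
temporal adverbs. Every document has at least the implicit anchor
`onset` at offset 0. One seizure record is emitted per anchor;
mentions, durations and frequencies attach to the nearest anchor at or
before their character offset, and the first duration/frequency per
record wins.

## Evaluation

Per-dimension counts follow the audit design: elements are compared
within the same anchored record (records pair by normalized anchor
string), `correct` is the size of a maximum one-to-one matching — for
keyed elements this is the multiset intersection, verified against a
maximum-bipartite-matching oracle. The default `term` mode compares
concept identity (plus the status value for the status dimension);
`exact_text` compares normalized surfaces for stricter audits. Symptom
and status are scored as independent dimensions over the same mention
set.

`prf` computes recall = c/N, precision = c/n_r, F1 = 2PR/(P+R), with
0/0 cases returning 0 under a warning. The presentation helper
`table_row` rounds percentages half-up to integers and computes F1 from
the **2-dp-rounded** precision and recall: published audit tables
derive F1 from the displayed fractions, and the unrounded harmonic mean
visibly disagrees with such tables in the second decimal (e.g. counts
1126/1325/1219 give 0.8852 unrounded but 0.88 from the displayed 0.85
and 0.92). One known residual: a displayed-value harmonic mean can
still differ by one unit in the last place from a table produced by
truncation instead of rounding; `semiokit` rounds half-up everywhere.

Fleiss's κ is implemented directly from the counts matrix,
κ = (P̄ − P̄e)/(1 − P̄e), with validation that every item has the same
number of raters m ≥ 2 and that more than one category is used (P̄e = 1
is undefined). It is cross-checked in the tests against brute-force
formula evaluation and an independent library implementation.

## Cohort construction and classification

A document's feature row sets entry j to 1 iff any of its records has
an affirmed mention mapping (via lexicon synonyms) to vocabulary term j;
pertinent negatives and uncertain mentions encode as 0, matching a
binary-presence feature model. The default vocabulary is the lexicon's
103 primary symptom terms. Diagnosis strings map to
generalized/focal/unclassified through an ordered first-match regex
table; unclassified documents are excluded before modelling.

Train/test splitting is stratified at a 7:3 ratio: per-class train
shares are floored, then classes are topped up by largest fractional
remainder until the train set holds round(0.7 n) rows (2632 + 3857
documents split 4542/1947).

The stack is two-stage. Stage 1 runs stratified 5-fold CV over the
training set; each base model's out-of-fold probability becomes one
meta-feature column, and its five fold models each predict the test
set, averaged into the test meta-feature (the averaging rule is a
package decision; per-fold test prediction admits several aggregations
and the mean is the standard one). Stage 2 fits an L2 logistic
regression (C = 1, fixed) on the out-of-fold matrix. Folds are rebuilt
with a shifted seed (at most 5 attempts) in the degenerate case of a
single-class training part. Base models are ordinary library
classifiers behind a fit/predict-probability contract; the default
pairing is XGBoost + random forest, with decision tree and LightGBM in
the full roster. Generalized epilepsy is class A and the positive ROC
axis throughout.

Macro metrics average the two per-class precisions/recalls and take
the harmonic mean for F1; AUC uses the Mann–Whitney rank formulation
with midranks for ties. Feature selection offers ANOVA F (constant
features score 0), plug-in mutual information of each feature's 2×2
table (0·log 0 = 0), random-forest impurity importance, and RFE.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of a present-history narrative:
1–3 temporal anchors per document in chronological order, affirmed
symptom surfaces sampled from the lexicon (random synonym choice),
optional seizure site, duration and frequency phrases, and pertinent
negatives drawn from symptoms the patient does not have. All
randomness flows from one seed through per-document substreams, so
equal specs give byte-identical bundles, and gold spans are tracked
during rendering, not re-derived.

Default study conditions: 45% generalized prior; 8 generalized-marker
and 8 focal-marker symptoms at P(present | class) = 0.85/0.15 with a
0.03 background rate for the remaining 87 (Bayes error well under 2%);
negation rate 0.3 per episode; duration phrase probability 0.6,
frequency 0.5, location 0.5. These were fixed as the generator's
definition of a separable cohort before any classifier was run.

Because narratives use only lexicon surfaces and unambiguous cue
templates, extraction recovers them perfectly; the pipeline-identity
test (P = R = 1.0 on 1,000 documents, planted matrix recovered exactly)
therefore certifies the *plumbing* — offsets, scoping, normalization,
anchoring, matrix construction — and says nothing about recall on real
clinical prose with misspellings, out-of-lexicon phrasing, coreference
or witness attribution. Published extraction accuracies on real EHR
text (F1 0.80–0.98 by dimension) are not reproducible from synthetic
data and are not claimed.

The agreement simulation treats annotators as noisy channels over gold
mention statuses. Fleiss's κ is strongly marginal-dependent: with ~94%
"with" items chance agreement reaches ≈ 0.86 and even 98%-reliable
annotators cap near κ ≈ 0.7. The κ reference checks therefore use a
corpus with one pertinent negative per episode (status marginals
≈ 0.84/0.16), where a 2% per-rating error rate gives an expected
κ ≈ (0.961 − 0.721)/0.279 ≈ 0.86 by the closed-form calculation —
inside the "near-perfect" band, and stable across seeds (Monte-Carlo
minimum 0.81 over 60 seeds).

## Problem sizes and tolerances

The shipped test suite and acceptance script use: 1,000 rendered
documents for pipeline identity; n = 2000 cohorts over 5 seeds for
stack recovery (macro-F1 threshold 0.95; measured ≈ 0.998); n = 10,000
for the null-AUC check (tolerance ±0.02); 50-record samples with 4
simulated annotators for κ. Sampling tolerances in property tests are
sized at 4 standard errors per estimate, since several hundred parallel
Bernoulli estimates make a flat ±0.02 bound tighter than 3σ for the
0.85-rate markers.

## Known limitations

- The window scope rule has no access to syntax; long-range negation
  ("denies that he ever had ...") and post-mention cues
  (`scope_direction` other than `pre`) are configured but not default.
- Coreference, witness-vs-patient attribution, spelling correction and
  abbreviation expansion are out of scope.
- The bundled lexicon and diagnosis rule table are working defaults,
  not validated clinical resources; real deployments should load their
  own lexicon JSON and rule config.
- Durations/frequencies recognize numeric and small-word numbers only;
  vague quantifiers ("a few minutes", "occasionally") normalize to
  nothing by design.
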