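# Methods

This note documents the models, the synthetic-corpus design, the numerical
conventions, and the design choices that were genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Section parsing

Operative notes are assembled from EHR templates whose sections are
introduced by short headers, but surgeons overwrite sections as free text
and header surface forms drift across template vintages.  The parser makes
the surface convention explicit:

* a **candidate** header is a line-initial run of 1–5 words ending in a
  colon, in any case;
* a candidate is **well-formed** when ≥ 80 % of its alphabetic characters
  are uppercase, or it is title-case and ≤ 40 characters.

Well-formed headers are canonicalized against a user-supplied alias map:
exact case-insensitive lookup first, then normalized indel similarity
(`2·LCS/(|a|+|b|)`, the Levenshtein-ratio family) against every known
alias, accepting the best match at or above `fuzzy_threshold = 0.85`.  The
threshold tolerates one-to-two character typos at typical header lengths
(a one-character typo in "operative details" scores 32/33 ≈ 0.97) while
rejecting unrelated section names, which score far below 0.85.

A note that cannot yield the requested section gets exactly one failure
status, with precedence: `no_header` (no candidate lines at all) →
`malformed_header` (candidates exist, none well-formed — e.g. lowercase
headers indistinguishable from body text) → `unrecognized_header`
(well-formed headers exist, but none canonicalizes to the target with a
non-empty body).  The last bucket deliberately includes the case where
*other* sections were recognized but the target is missing or empty: the
taxonomy stays exhaustive and mutually exclusive.  Failures are data, not
exceptions; a corpus parse returns per-reason counts.

Splitting is lossless: the preamble, every raw header and every segment
body are retained, and their concatenation reproduces the input text byte
for byte (property-tested).  Input is treated as UTF-8 with replacement of
invalid bytes.

## Featurization

Tokens are purely alphabetic character runs, lowercased.  The stop list is
a fixed ~290-word English function-word list shipped in the package;
negations (`no, not, without, never, non`) are in the stop list and rescued
by a whitelist, so the whitelist is the single switch controlling negation
handling.  Lemmatization is a pluggable `str -> str` callable.  The bundled
default is a deterministic lookup table (~80 clinical/irregular forms) plus
conservative suffix rules (`-ies/-ied -> -y`, sibilant `-es`, `-ing`/`-ed`
with doubled-consonant repair, plural `-s`), chosen so results do not
depend on an external NLP model version; an adapter to a full pipeline can
be passed via `lemmatizer=`.

The TF-IDF dialect is pinned exactly so every number is reproducible:

* terms = unigrams plus bigrams of adjacent **post-filter** tokens (so
  "water tight" survives stop-word removal as a bigram); bigrams never
  cross section boundaries because featurization sees one section;
* vocabulary = the `max_features = 500` terms with the highest **total
  corpus count**, ties broken lexicographically ascending;
* `idf(t) = ln((1+N)/(1+df(t))) + 1` (smoothed; always ≥ 1);
* document vector = raw count × idf, L2-normalized; out-of-vocabulary
  terms ignored; all-OOV documents map to the zero vector.

Fitting consults training documents only.  The implementation is
hand-rolled (numpy/scipy.sparse) because the tie-break on the top-500 cut
must be deterministic; the test suite cross-checks it against both a
pure-Python brute-force oracle (to 1e-9) and scikit-learn's
`TfidfVectorizer` in the same dialect.

## Classifier cascade

* **Scorers.** One `RandomForestClassifier` per class and level: 500 trees,
  unlimited depth, √p features per split, per-class seed `seed + class
  index` (default seed 42), `n_jobs=1`.  The per-note score is the fraction
  of trees voting positive — this puts scores on [0, 1] and makes grid
  thresholds well defined, at the cost of coarser granularity than averaged
  leaf probabilities.
* **Class weighting.** Balanced weights `w_c = n_total/(n_classes · n_c)`
  computed per binary subproblem; a class with zero training examples is an
  error, not a silent skip.
* **Thresholds.** For each class, F1 is evaluated on the grid
  {0, 0.01, …, 1} with the ≥ convention; ties take the lowest threshold.
  During cross-validated *evaluation*, each fold's threshold is optimized
  on that fold's held-out scores (which is why averaged final thresholds
  can be suboptimal for an individual fold); the *final model* threshold is
  the cross-fold arithmetic mean, clamped to [0, 1].  Model refitting after
  threshold selection is on the full training data by default
  (`refit="all"`), with `refit="best_fold"` exposed as an alternative.
* **Hierarchy.** Subtype and technique models are trained only on notes
  whose *gold* labels contain the parent class, and applied at inference
  only to notes whose *predicted* labels contain it.  Training on gold
  conditioning isolates each level; inference on predictions means primary
  errors propagate downward — deliberately, so cumulative accuracy is
  measurable.  A conditional level with fewer than two observed classes is
  skipped and recorded (e.g. a corpus with no revision ABG notes trains no
  ABG subtype model).  Conditional levels are single-label: prediction is
  the argmax over class scores, ties to the first class in taxonomy order.
* **"Other"** is an explicit sixth primary label with its own scorer, not
  the absence of labels; the empty prediction set remains legal.

## Cross-validation and metrics

Primary: patient-grouped 5-fold (patients shuffled by seed, dealt into
near-equal groups; every note of a patient shares one fold).  Conditional:
stratified note-level 3-fold (classes dealt round-robin from rarest to most
frequent after a seeded shuffle; a class with fewer notes than folds is
flagged unstable).  Synthetic augmentation notes carry fold −1: they join
every training split and never a test split.

Metrics are computed per class and per fold: AUC (Mann-Whitney with tie
correction), AUPRC in the average-precision step form (no trapezoidal
interpolation), micro/macro F1 and Hamming loss — all delegated to
scikit-learn behind the module surface, with brute-force oracles asserted
to 1e-9 in the tests.  Conventions: a per-class F1 with no true and no
predicted positives counts 0 toward the macro average; a test fold lacking
a class skips that class's AUC/AUPRC with a warning rather than imputing;
cross-fold aggregation is the unweighted mean and sample SD (ddof 1).
Because the order of macro-averaging is ambiguous, the report emits both
`macro_auc` (fold mean of per-fold class macros) and
`macro_auc_class_first` (macro over per-class cross-fold means), labeled.

Feature importances are the forests' impurity importances mapped to
vocabulary terms, top-10 per class, normalized to max 1 within each class.

## Synthetic corpus

The generator is a seeded template engine, not a language model: the role
its LLM-generated counterpart plays in practice (hermetic stand-in for
protected text, augmentation of rare classes) is preserved while keeping
every byte reproducible.  Notes are assembled as three headed sections;
the operative-details body is a per-procedure *signal block* (three
class-bank sentences, a subtype cue, two technique sentences) followed by
filler drawn 70 % from a ~90-sentence shared boilerplate bank and 30 % from
the note's own class/technique/subtype banks (technique banks weighted 4×),
until a target word count is reached.  The target is lognormal with median
223 and mean 244 words, clipped to [5, 809] — matching the emulated
corpus's reported distribution.  Multi-note patients share an
attending-surgeon style sentence (swapped for trailing filler so lengths
stay on target), which is what makes patient-grouped CV measurably harder
than note-level CV.

The recurrence of class and technique vocabulary in the filler is a
deliberate condition, not decoration: the featurizer keeps only the 500
highest-count terms, so a class mentioned once per note would fall below
the boilerplate n-gram counts and become invisible to the classifier.
Real operative notes do return to their procedure's vocabulary repeatedly
(a Furlow note keeps naming the z-plasty), and the generator reproduces
exactly that property.  With the default settings the corpus is separable
by construction, and the acceptance suite verifies parameter recovery:
cross-validated primary macro-F1 ≥ 0.95 and conditional-level accuracy
≥ 0.90.

Two overlap knobs degrade separability on purpose.  `vocabulary_overlap`
(default 0.02) replaces any class-conditioned sentence draw with a draw
from the pooled all-class bank; at 1.0 the corpus carries no class signal
and cross-validated AUC falls to chance.  `subtype_overlap` applies the
same blending per parent class to the primary-vs-revision cues only —
setting it to 1.0 for ABG reproduces qualitatively the clinical failure
mode in which primary and revision bone grafts are documented in
near-identical language and the subtype AUC collapses to ~0.5.

The full-scale default (`paper_scale_config`) fixes the corpus structure
exactly: 656 notes, of which 26 single-procedure "other" notes are
rewritten to trigger parse failures (3 unrecognized / 8 absent / 15
malformed headers), leaving a parsed cohort of 630 notes with 958
procedures — 100 cleft lip, 105 ABG, 104 cleft palate, 32 VPI, 36
rhinoplasty, 581 other — and 184 multi-procedure notes.  Restricting
failure injection to single-"other" notes is a modeling choice that keeps
the parsed cohort's class distribution exact.  Every multi-procedure note
includes an "other" procedure (combined cases typically bundle minor
interventions such as ear tubes with the index repair).  Augmentation adds
24 synthetic-flagged notes (9 cleft-lip revision, 9 ABG revision, 6 VPI by
palate revision) with counts matched to the rare real categories; they are
train-only everywhere.  Ages are drawn from a gamma(1, 4) clipped to
[0, 19] years, emulating a young, right-skewed surgical population.

What the generator does **not** emulate: real lexical diversity (its
type-token ratio is ~0.4 %, far below a real corpus's ~3 %), dictation
errors, OCR noise, section cross-references, surgeon-specific grammar, or
genuinely ambiguous documentation.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and recoverable under known
conditions — not that any particular clinical accuracy would be achieved
on real notes.

## Fixed problem sizes

The acceptance suite runs the full 656-note corpus with the default
500-tree forests (a few minutes on one CPU).  The null-behavior checks use
the 60-note smoke corpus for the label-permutation test and a dedicated
240-note balanced ABG corpus for the overlap test: chance-level behavior
is a property of the construction, not of scale, and these sizes keep the
permutation band (0.5 ± 0.15) honest and fast.

## Known limitations

* The fuzzy threshold (0.85), the header surface rules, and the
  failure-reason precedence are explicit conventions; other reasonable
  choices exist and are configurable.
* The bundled lemmatizer is intentionally minimal; unknown inflections pass
  through unchanged.  Swap in a full NLP pipeline via the `lemmatizer=`
  hook when version pinning is not a concern.
* Scores are vote fractions, not calibrated probabilities; thresholds are
  comparable within a model but scores are not probabilities.
* The percent column of a code-distribution table can drift from 100.0 by
  up to ±0.05 per row under half-up rounding; the ±0.2 figure quoted for
  table-sized outputs assumes ≤ 4 rows beyond the largest.
* Multilabel stratification assigns each note by its rarest class;
  perfectly balanced folds for all classes simultaneously are not
  guaranteed (nor generally possible).
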