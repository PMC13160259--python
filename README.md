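# opnote

Hierarchical machine-learning classification of surgical operative notes,
with a deterministic synthetic-corpus generator so the whole pipeline can be
developed and tested without access to protected clinical text.

## The problem

Surgical outcomes research needs to know *which* procedure a note documents,
whether it was a first-time repair or a revision, and which named technique
was used.  CPT billing codes cannot answer this reliably: alveolar bone
grafting (ABG) has no dedicated code at all, velopharyngeal insufficiency
(VPI) correction is scattered across half a dozen palatoplasty codes, and
identical procedures are routinely coded differently.  The alternative —
manual chart review — does not scale.  Cleft and craniofacial care is a
worst case: patients undergo many staged procedures over two decades, and
several procedures are frequently combined under one anesthetic, so a
single operative note often documents multiple procedures at once.

## The method

`opnote` classifies the free-text *operative details* section of each note
at three levels:

1. **Primary (multilabel)** — which of six procedure types the note
   documents: cleft lip repair, ABG, cleft palate repair, VPI correction,
   rhinoplasty, other.  A One-vs-Rest (OvR) ensemble trains one random
   forest per class on TF-IDF features (unigrams + bigrams, top 500 terms
   by corpus count, fit strictly in-fold); class *c* is assigned when its
   score s_c — the fraction of trees voting positive — clears a per-class
   threshold chosen to maximize F1 over a 0.01 grid and averaged across
   folds.  Class weights w_c = n/(K·n_c) counter imbalance.
2. **Subtype (conditional, binary)** — primary vs revision, for cleft lip
   and ABG.
3. **Technique (conditional, multiclass)** — e.g. Fisher / modified
   rotation-advancement / Mulliken for cleft lip; von Langenbeck / Bardach /
   Veau-Wardill-Kilner / Furlow / Sommerlad for cleft palate; palate
   revision vs sphincteroplasty/pharyngoplasty for VPI.

Conditional models are trained on gold parent labels and applied to
predicted ones, so primary-level errors propagate by design and can be
measured.  Evaluation uses patient-grouped 5-fold cross-validation at the
primary level (no patient's notes straddle train and test) and stratified
note-level 3-fold cross-validation at the conditional levels, reporting
AUC, AUPRC, micro/macro F1 and Hamming loss as cross-fold mean (SD).

Upstream of the classifier, a section parser detects template headers
(line-initial word runs ending in a colon), canonicalizes them against an
alias map by exact and fuzzy (normalized indel similarity ≥ 0.85) matching,
and records a typed failure (`no_header`, `malformed_header`,
`unrecognized_header`) for unparseable notes.  Token filtering preserves
clinically load-bearing negations ("no", "not", "without").

Because no public operative-note corpus exists, the package includes a
seeded template generator that emulates the structure of a real
single-institution corpus — 656 notes from ~320 patients, 26 unparseable
notes (3 unrecognized / 8 absent / 15 malformed headers), 630 parsed notes
carrying 958 procedures (184 multi-procedure notes), bodies averaging ~244
words with very low lexical diversity — plus synthetic-flagged augmentation
notes for the rare revision categories that are used in training folds only.

## Worked example

```bash
opnote simulate --preset tiny --seed 5 --out notes.jsonl
opnote parse --input notes.jsonl --out sections.jsonl --report report.csv
```

The parse step prints the failure taxonomy for the 60-note smoke corpus:

```
{"parsed": 60, "unrecognized_header": 0, "no_header": 0, "malformed_header": 0}
```

Training and evaluating the full cascade end to end:

```bash
cat > run.yaml <<EOF
seed: 5
out_dir: runs
generator: {preset: tiny}
model: {n_trees: 100}
cv: {primary_folds: 3, conditional_folds: 3}
EOF
opnote run --config run.yaml --stages simulate,parse,train,evaluate
```

This writes `runs/<confighash>/metrics.json` plus ROC/PR curve point
tables and a per-class feature-importance report.  With the config above,
the tiny-corpus primary level reports `macro_auc` 1.00 (SD 0.01),
`macro_f1` 0.99 and `hamming_loss` 0.01 across folds — the corpus is
separable by construction, so near-ceiling scores mean the pipeline
recovered the generator's class vocabularies, not that any clinical claim
is being made.

At full scale (`--preset paper_scale`, 656 notes + 24 augmentation notes),
a complete train/evaluate run takes a few minutes on one CPU.

## Layout

| Module | Role |
| --- | --- |
| `opnote.parser` | header detection, fuzzy canonicalization, section extraction |
| `opnote.featurize` | negation-preserving preprocessing, exact TF-IDF dialect |
| `opnote.cascade` | OvR forests, threshold selection, three-level cascade |
| `opnote.evaluate` | grouped/stratified folds, multilabel metric suite, importances |
| `opnote.simulate` | seeded synthetic-corpus generator and failure injection |
| `opnote.summary` | cohort characteristics and CPT code distributions |
| `opnote.cli` | `opnote simulate/parse/featurize/train/evaluate/classify/summarize/run` |

See `docs/methods.md` for the model assumptions, generator design and known
limitations.
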