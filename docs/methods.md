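# Methods

## Problem setting

The package models in-hospital MACE (a composite endpoint: all-cause
death, myocardial infarction, angina attack, heart failure, arrhythmias,
re-revascularization, transfer to CABG, and long length of stay — the LOS
threshold defaults to 14 days and is configurable, since no canonical
cutoff exists) as a binary outcome of an ACS admission, predicted from
features extracted out of the free-text admission record plus structured
vitals and labs.

## Rule-based extraction

**Tokenization.** Clauses are segmented by reverse-directional maximum
matching: scanning from the clause end, the longest lexicon entry (≤ the
lexicon's maximum surface length) ending at the current position is taken;
otherwise a single character is emitted unmatched. Characters are Unicode
code points, so mixed Chinese/ASCII lexemes ("CT", "ECG") need no separate
Latin tokenizer. Duplicate lexicon surfaces resolve last-wins with a
warning, keeping loads deterministic.

**Annotation.** Matched tokens are replaced by `CODE#k#` symbols, where
`CODE` is a two-letter semantic class (BP body part, ST symptom, DS
description, DG diagnosis, MD medication, EX examination, plus extensible
placeholders PS/SG/EC). Indices count matched tokens right-to-left — the
rightmost match is `#1#` — which is the only convention consistent with
the published worked examples. Substituting surfaces back into the
annotated string reproduces the clause byte-for-byte (property-tested).

**Rule matching.** Rules are regular expressions over the symbol alphabet
with named capture groups; the feature name is the concatenation of the
resolved surfaces of the emit groups. Rule application is "every rule
tried, in priority order", but symbols claimed by an earlier match are
skipped by later rules. Pure all-matches semantics cannot coexist with a
rule set containing both compound rules ([BodyPart]+[Symptom]) and
single-symbol fallbacks ([Symptom] alone): the fallback would re-extract
every compound concept and precision could never reach 1 even on perfectly
regular text. Consumption is configurable (`consume_symbols=False`
restores literal all-matches).

Only four rules of the original 18-rule matcher are public; the shipped
default set contains those four plus combinatorial fallbacks
(examination+description, symptom/personal/surgery/ECG singletons) and is
a YAML file users can extend. The published [Body Part]+[Description]
pattern is typeset with unbalanced parentheses and a stray `\*`; the
shipped form is the minimal repair that compiles and admits the
enumeration mark 、 between body-part symbols, which its own worked
example requires. Likewise the en-dash in `[0–9]` is read as `[0-9]`.

**Negation.** A concept is negated when a cue (defaults 否认, 未, 无, 不)
occurs earlier in the same clause and no scope-breaking noun from an
exception list sits between cue and concept. The exception mechanism is
this package's resolution of an underspecified step: plain
"cue-precedes-concept" wrongly negates 无明显诱因出现胸闷 ("chest
tightness without obvious incentive", an affirmed finding); the default
exception 诱因 handles that family of phrases. Both lists are config.
Only affirmed/negated polarities are modeled; temporal or hypothetical
assertion classes are out of scope.

## CRF extraction

A linear-chain CRF labels characters with typed BIO tags (B-ST, I-ST, …).
Typed tags are the default because downstream bookkeeping categorizes
features by semantic class; a plain B/I/O mode is retained. The feature
template is fixed: 7 character unigrams (offsets −3…3), 6 bigrams
(−3…2), 7 punctuation indicators and 7 negation-word indicators (−3…3) —
27 features at every position, with reserved sentinel strings (never equal
to a real character) standing in for out-of-range offsets.

Training maximizes the L2-regularized conditional likelihood with L-BFGS
from a zero start, so it is deterministic for a fixed corpus; the penalty
coefficient defaults to 0.1 and the iteration cap to 200. The
forward–backward pass is batched over sequences (padded, with a length
mask) and active features live in one sparse position×feature matrix, so
training on hundreds of full-length records takes seconds rather than
hours. Decoding is Viterbi; predicted taggings are normalized so spans
start with B (an I after O or after a different span type is promoted).
Maximal B,I⁺ runs become feature-value pairs; the span text is the feature
name and polarity comes from the same clause-bounded negation detector the
rule engine uses.

## Structured panel and matrix

Vitals (body temperature, pulse, breathing rate, SBP/DBP, height, weight,
age) and a configurable lab panel are parsed from `name[:：]value unit`
lines by regular expressions; values outside physiologic sanity bounds are
treated as missing with a warning. A lab is flagged abnormal when a
reference range is configured and the value falls outside it.

The matrix encodes affirmed text features as 1 and negated-or-absent as 0.
Folding negation into absence keeps features binary and matches
presence-style feature frequencies; a three-state mode (negated = −1) is
available. Missing numerics are median-imputed with a companion
missing-indicator column — the original data's missing-data strategy is
unstated, and median+indicator is a conservative default that never alters
observed values (the missingness mask is preserved exactly). All-missing
and constant columns are dropped with a warning. Row/column order is
deterministic (sorted ids, sorted feature names).

## Risk-score baselines

The additive-point engine is table-agnostic; the shipped GRACE
(in-hospital mortality) and TIMI (UA/NSTEMI) tables are transcribed from
their original publications and labeled as such in the YAML files — they
are not contained in the admission-record study itself. A missing optional
variable contributes its lowest-point bin with a (once-per-variable)
warning; required variables can be declared and then raise. The raw point
total is the ROC ranking score. How extracted features map onto score
inputs is a config mapping (column, scale factor or binarizing threshold);
the synthetic cohort exposes age, heart rate, SBP and creatinine
(μmol/L → mg/dL via 1/88.4), while Killip class, cardiac arrest, ST
deviation and marker elevation fall to the missing-variable policy.

## Evaluation protocol

Stratified 5-fold CV repeated 10 times, fold seeds derived from one base
seed; every patient receives exactly one out-of-fold score per repetition.
A degenerate single-class training fold triggers a refold with a shifted
seed. Classifiers:

- **SVM**: RBF kernel, C/γ chosen by an inner 3-fold CV over a small fixed
  grid (the original grids are unpublished; fixing them in config keeps
  runs reproducible), features standardized.
- **RF**: 1000 trees, √p features per split (as specified), seeded.
- **NB**: Gaussian likelihoods on numeric columns, Bernoulli on binary
  columns, combined by summing class-conditional log-likelihoods under one
  shared prior — the published work says only "naive Bayes", and the
  matrix is mixed-type.
- **ℓ₁-LR**: lasso logistic regression, penalty tuned by inner 3-fold CV
  over a fixed grid, standardized features.

AUC uses the Mann–Whitney formulation with ties counted ½ (verified
against pairwise enumeration to 1e-12). The per-repetition AUCs are
summarized by their mean and a t-distribution 95% CI — the original CI
construction is undefined, and with 10 repetitions a t-interval is the
natural choice. DeLong's test uses the structural components V10/V01 via
midranks; identical score vectors return z = 0, p = 1 exactly. How DeLong
interacts with repeated CV is also undefined in the source; here it is
computed per repetition on the pooled out-of-fold scores and the median
p-value reported. Learning curves subsample the same proportion from
positives and negatives, preserving prevalence. Rankings: permutation
importance (mean accuracy decrease over shuffles) for the forest; nonzero
lasso coefficients by |value| with sign retained (positive =
risk-increasing).

## Synthetic cohort

The generator emulates the study conditions: n = 2930 patients, target
prevalence 752/2930 ≈ 25.66%, vitals/labs from truncated normals with the
published cohort means/SDs (BT 36.2 ± 0.3 °C, pulse 73.4 ± 9.7, SBP
132.1 ± 17.6 mmHg, age 62.3 ± 12.1 y, …), and ~20 narrative concepts
rendered through clause templates instantiating the published rule
patterns. Absent concepts are explicitly negated with probability 0.3
(else unmentioned). Default concept prevalences echo the published
free-text feature frequencies (coronary heart disease near-universal,
hypertension ~60%, aspirin ~60%, …).

Labels are drawn from a known logistic model: per-SD weights on age
(+0.55), SBP (−0.30), pulse (+0.15) and creatinine (+0.25), and five
planted text factors — myocardial infarction (+1.2), heart failure
(+1.0), lower-extremity edema (+0.8), diabetes (+0.6), smoking (+0.5) —
plus a weak stenosis effect (+0.3) and a mildly protective aspirin term
(−0.2); every other concept is null. These magnitudes were chosen once to
put the information ceiling near the AUC range reported for real admission
records (the realized theoretical AUC is ≈ 0.76) while keeping GRACE's
inputs (age, SBP, HR, creatinine) genuinely informative but incomplete, so
the learned-model > GRACE > TIMI ordering emerges from the construction
rather than being asserted. The intercept is calibrated by Monte Carlo
root-finding so the expected prevalence hits the target; the calibration
uses a fixed internal seed, making the true model one well-defined object
independent of the cohort seed. `theoretical_auc` estimates the ceiling by
simulating the linear predictor at n = 10⁶ (reproducible across seeds to
within ±0.005).

Gold BIO spans tag the full contiguous concept phrase with the concept's
head class, so gold pairs and gold taggings are mutually consistent and
both extractors produce the same canonical feature names. Text noise
(spurious clause breaks, deleted delimiters, character substitutions) is
applied per-clause from a separate RNG stream after the gold is fixed:
gold reflects intended content, so measured precision/recall genuinely
degrade with noise, monotonically in expectation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: full-length admission-record layouts with
section headings, vocabulary outside the mini-lexicon, misspellings beyond
single-character substitution, paraphrase variation outside the template
inventory, correlated vitals/labs (the covariance is diagonal by design,
for interpretable recovery tests), label noise in MACE adjudication, and
concept prevalences conditioned on outcome beyond the logistic model.
Perfect extraction on noise-free synthetic text is a correctness check of
the engines, not an estimate of real-world extraction accuracy.

## Numerical and reporting choices

- Extraction metrics are reported as percentages rounded to two decimals;
  F1 is computed from unrounded precision/recall. One published worked
  value is internally inconsistent: the CRF precision is printed as 98.15%
  but the stated counts give 3685/3754 = 98.16%; this package treats the
  recall and F1 as the checkable values and documents the discrepancy.
- All randomness funnels through explicit integer seeds; repetition seeds
  are derived as `base + 1000·rep` modulo 2³¹−1.
- Problem sizes used by the shipped acceptance run: the full n = 2930
  cohort; 10 CV repetitions for the fast linear/NB models and 3 (RF) / 2
  (SVM) for the expensive ones; 150 records for CRF training; 5 regenerated
  cohorts for ranking recovery; 10⁶ draws for the theoretical AUC. These
  are the package's default study sizes; all are parameters.
- Known limitations: the rule set covers the synthetic template inventory,
  not general clinical Chinese; the negation model is clause-local with a
  small exception list; GRACE/TIMI inputs not present in the matrix fall
  to lowest-bin defaults, which lower-bounds the baselines' achievable
  discrimination; hospital-cohort quantities (demographics tables,
  cohort-specific AUCs and p-values, the identities of real top-20 risk
  factors) depend on confidential data and are out of scope.
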