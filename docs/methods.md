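# Methods

## The phenotype and its scoring model

Physician-documented insomnia is an empirical case definition: a patient
counts as a case if a physician recorded an insomnia billing code,
prescribed a medication indicated *only* for insomnia, or documented
sleep difficulty in a narrative note. Formal diagnostic criteria (DSM-V)
are rarely documented in EMR text at the level of detail they require,
so this empirical definition is what chart review can actually label and
what the classifier predicts.

The classifier is a logistic regression on seven non-negative counts:
number of notes indicating a sleep disorder, billing codes for insomnia,
billing codes for anxiety/depression, notes indicating a psychiatric
disorder, pharmacy prescriptions for insomnia, billing codes for joint
disorder, and total EMR facts (a utilization proxy: every coded event,
prescription and note attached to the patient). Counts enter raw —
untransformed and unstandardized — so the printed coefficients apply
directly to observable tallies. Classification thresholds the predicted
probability at 0.828, the cut anchored at 97% specificity; a tie at the
threshold classifies positive (a deliberate, configurable convention:
the published scenarios describe the cut as attainable, and erring
toward sensitivity at the boundary is the conservative choice for cohort
discovery).

## Rule-based extraction

Note covariates count **notes**, not mentions: a note containing an
expression three times contributes one. Matching is literal —
lowercase, collapse whitespace runs, substring search — with no
stemming and no negation-scope detection, because the expression lists
were curated to be non-negated descriptors ("poor sleep",
"sleeplessness", ...). Text that merely mentions sleep ("patient sleeps
well", "denies insomnia") matches the broad screening keywords but none
of the disorder expressions, which is precisely the separation between
candidate-mart inclusion and case evidence.

The 500-character minimum note length is stated for cohort inclusion
(at least two such notes); this package applies the same single
`min_note_chars` knob to note-covariate counting, a conservative,
configurable choice (set it to 0 to count every note).

Billing codes are counted per dated occurrence, not per distinct code —
the codes-only scoring scenario accumulates "5 or more" codes, which
only makes sense for occurrence counting. ICD-9 codes compare as exact
strings after trimming; a code-set entry ending in `*` is an explicit
prefix wildcard. The anxiety/depression, joint-disorder and psychiatric
vocabularies bundled as defaults are clearly-marked synthetic
placeholders (the original comorbidity vocabularies were never published
in full); any serious use should override them from a config file. The
EMR-fact tally here is codes + prescriptions + notes — the record
representation has no laboratory or visit tables; with richer extracts
the tally should be extended, and the covariate's tiny coefficient makes
the model insensitive to moderate redefinitions.

## Model development protocol

- **Split.** Stratified by label, 2:1 train:validation,
  floor(fraction·n) per stratum, seeded. (Stratification is this
  package's choice; it stabilizes specificity targeting in small
  validation sets.)
- **Adaptive LASSO.** Stage 1 fits an unpenalized logistic pilot
  (ridge-stabilized with a warning if the likelihood is monotone, i.e.
  separation). Stage 2 solves L1-penalized logistic regression with
  penalty weights `1/|b0_j|^γ`, γ = 1, implemented by rescaling columns
  by `|b0_j|^γ` and penalizing uniformly over a 30-point geometric
  penalty path.
- **Penalty strength** defaults to minimizing BIC
  (deviance + df·ln n) along the path, with 5-fold cross-validated
  deviance available via `penalty_selection="cv"`. BIC is the
  selection-consistent criterion for the adaptive LASSO; in calibration
  runs on model-simulated data, CV-minimum deviance retained a truly
  null covariate in roughly a third of replicates and the CV
  one-standard-error rule discarded genuinely weak signals, while BIC
  both drops nulls and keeps all seven generating covariates at
  moderate sample sizes.
- **Relaxed refit.** Covariates with zero second-stage coefficient are
  dropped; the returned coefficients are an unpenalized maximum-
  likelihood refit on the selected support, so reported values are not
  shrunken — matching how clinical scoring equations are published.
  Wald standard errors come from the observed information at the refit.
- **Threshold.** The smallest observed validation probability whose
  specificity on the validation negatives (fraction strictly below the
  cut, since ties classify positive) reaches the target (default 0.97).
  With fewer than `1/(1−target)` negatives the target is unresolvable;
  the cut is then placed just above the largest negative probability,
  with a warning. The target is applied on the designated validation
  split.
- **AUROC.** Rank-statistic (Mann–Whitney) form, half credit for ties.
  Confidence intervals are percentile 2.5/97.5 over 1,000
  patient-resampled bootstrap replicates; single-class replicates are
  redrawn, and the bounds are widened if needed to bracket the point
  estimate (a rare edge of the percentile method).
- **Overfitting check.** 100 seeded 2:1 sub-splits of the training set,
  refitting on each sub-derivation part and scoring the held-out part;
  the mean sub-validation AUROC and its standard error are compared to
  the external-validation AUROC. With one permutation the standard
  error is reported as absent.
- **Variable subsets.** `icd_only` (insomnia codes),
  `structured_only` (codes, prescriptions, EMR facts),
  `unstructured_only` (the two note covariates), `combined` (all
  seven), all run on identical splits.

## Synthetic EMR corpora

No real extract is distributable, so the generator emulates the
statistical structure the pipeline assumes. Each patient draws a latent
insomnia status (prevalence 0.46, matching a chart-reviewed candidate
sample of 230 cases / 270 controls); covariate counts are
status-conditional Poisson (cases: mean 2.0 sleep-disorder notes, 0.8
insomnia codes, 1.0 hypnotic prescriptions, higher psychiatric and
joint comorbidity; controls: 0.1, 0.05, 0.05 respectively), plus
background codes, benign prescriptions (including trazodone, which must
not count) and neutral notes for realistic volume. Poisson is the
simplest non-negative count law and gives exact standard-error oracles.
Every planted indicator note embeds exactly one vocabulary expression in
filler padded past the 500-character filter, so note-level extraction
recovers the planted counts exactly; distractor notes embed benign
sleep phrases that trigger keyword screening but no disorder
expression. An optional shared lognormal severity multiplier
(`severity_sd`) induces positive covariate correlation; its calibration
is arbitrary and it is off by default.

For parameter-recovery studies, `simulate_from_model` samples covariates
from a configurable count law and draws labels Bernoulli of the scoring
model's probability, making the model the true data-generating process.
The default law uses modest Poisson means and a rounded-lognormal EMR-
fact tally (median 800, log-sd 1.0) whose heavy-tailed spread makes even
the per-fact coefficient (2.3 × 10⁻⁴) identifiable at n ≈ 5,000.

**What passing tests do and do not show.** The generator's notes are
templated, its covariates conditionally independent given status, and
its case/control separation stronger than chart-reviewed reality —
synthetic AUROCs (≈ 0.95–0.99) therefore exceed what real validation
yields, and absolute performance numbers on synthetic corpora say
nothing about real EMR data. What the tests do establish: extraction is
exact against planted ground truth, the scoring equation reproduces its
published scenario probabilities, the protocol hits its specificity
target, recovers generating coefficients, and ranks variable subsets in
the expected information ordering.

## Numerical choices and degenerate inputs

- Logistic evaluated in branch form (no overflow at any |L|); linear
  predictor summed in fixed covariate order for bit-stable results.
- Problem sizes in the test suite — 1,000–2,000-patient corpora, 5,000
  rows for coefficient recovery, 100 overfit permutations, 1,000
  bootstrap replicates — are chosen so each statistical check has
  comfortable power while the whole suite runs in about a minute.
- Feature vectors constructed by hand (what-if scenarios) may violate
  the superset relation between the EMR-fact tally and the structured
  counts; vectors extracted from records or generated by the simulator
  always satisfy it, and `extract_features` raises if overlapping
  user-supplied code sets would break it.
- Empty corpora, single-class label sets, validation sets without
  negatives, and sub-10-row fits are hard errors; malformed corpus
  lines are reported with file and line number.

## Known limitations

- Expression matching is fixed-vocabulary substring search: misspellings
  ("poor slep"), novel phrasings, and genuinely negated disorder
  expressions ("no longer reports poor sleep") are outside its reach by
  design.
- The comorbidity code sets and psychiatric expression defaults are
  synthetic placeholders, not validated vocabularies.
- Real-data performance (AUROC, PPV) cannot be reproduced or verified
  here; only protocol properties and qualitative orderings are testable
  against synthetic corpora.
- The record model carries no laboratory, visit or procedure tables, so
  the EMR-fact tally under-counts relative to a full warehouse extract.
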