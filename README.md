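# somnotype

EMR phenotyping of **physician-documented insomnia**: identify insomnia
patients in electronic medical records by combining structured data
(ICD-9 billing codes, pharmacy prescriptions, utilization volume) with
rule-based extraction from the free text of clinical narrative notes.

Insomnia is chronically under-coded: most patients whose physicians
document sleep difficulty in notes never receive an insomnia billing
code, so billing-code cohorts both miss most cases and bias who is
studied. This package is for clinical informaticians and
pharmaco-epidemiologists who need reproducible insomnia cohorts from EMR
extracts — and for anyone who wants to study, stress-test or re-derive
the scoring algorithm itself without access to protected health data
(a synthetic EMR generator stands in for real extracts).

## The model

For each patient, seven non-negative counts are extracted with fixed
vocabularies (ten non-negated sleep-disorder expressions, an
insomnia-only hypnotic medication list, ICD-9 code sets). The published
logistic scoring equation is

```
L = −1.927027677
    + 2.329738590 · [# notes indicating a sleep disorder]
    + 0.802462562 · [# billing codes for insomnia]
    + 0.264231683 · [# billing codes for anxiety or depression]
    + 0.098835169 · [# notes indicating a psychiatric disorder]
    + 0.086364249 · [# pharmacy prescriptions for insomnia]
    + 0.048271004 · [# billing codes for joint disorder]
    + 0.000231521 · [# of EMR facts]

p(insomnia) = exp(L) / (1 + exp(L))
```

A patient is classified as having physician-documented insomnia when
`p ≥ 0.828`, the probability cut point anchored to 97% specificity.
The full model-development protocol is also implemented: stratified 2:1
train/validation splitting, adaptive-LASSO logistic regression over four
variable subsets (ICD-only, structured-only, unstructured-only,
combined), specificity-anchored threshold calibration, bootstrap AUROC
confidence intervals (1,000 replicates), and a permutation overfitting
check (100 sub-splits of the training set).

## Worked example

```
$ somnotype demo --seed 42
somnotype demo (seed=42, n=600)
  check: one sleep-disorder note: p=0.60 (expected 0.60) OK -> classified negative
  check: two sleep-disorder notes: p=0.94 (expected 0.94) OK -> classified positive
  check: five insomnia billing codes: p=0.89 (expected 0.89) OK -> classified positive
  scored 600 synthetic patients with the published model: 199 classified insomnia-positive
  subset comparison (fresh fit on synthetic truth labels):
    combined           AUROC=0.994 [0.985, 0.999] threshold=0.505
    structured_only    AUROC=0.981 [0.962, 0.994] threshold=0.448
    unstructured_only  AUROC=0.959 [0.923, 0.979] threshold=0.881
    icd_only           AUROC=0.774 [0.721, 0.819] threshold=0.990
demo complete
```

The three checks are the simplified-score scenarios: a single
sleep-disorder note gives p = 0.60 (below the 0.828 cut), a second note
pushes p to 0.94 (classified insomnia), and with no notes at all five
insomnia billing codes are needed to clear the threshold (p = 0.89;
four codes give p = 0.78 and a negative call). The table below them is a
fresh run of the development protocol on a seeded synthetic corpus: a
model using notes and codes together outperforms either alone, and a
billing-codes-only model trails far behind — the ordering that motivates
note-based phenotyping. (Absolute AUROCs on synthetic corpora are higher
than on real chart-reviewed data; only the ordering is meaningful.)

The same stages are scriptable: `simulate`, `extract`, `mart`, `score`,
`train`, `evaluate` (see `somnotype --help`), or from Python:

```python
from somnotype import FeatureVector, load_model, probability

model = load_model("published")
probability(FeatureVector(n_sleep_notes=2), model)   # 0.9389...
```

## Layout

| module | contents |
| --- | --- |
| `somnotype.emr_model` | domain types, invariants, corpus/label/model/vocabulary IO, the published model |
| `somnotype.features` | expression matching and the seven-covariate extraction |
| `somnotype.candidate_mart` | broad screening filters, empirical case rules, age exclusion |
| `somnotype.scoring` | linear predictor, logistic probability, thresholded classification |
| `somnotype.training` | adaptive LASSO, threshold calibration, bootstrap AUROC, overfitting check |
| `somnotype.evaluation` | confusion metrics, PPV on labeled samples, cohort summaries |
| `somnotype.synthetic_emr` | seeded synthetic corpus generator and model-based simulation |
| `somnotype.cli` | the `somnotype` command |

See `docs/methods.md` for the statistical methods, the synthetic-data
assumptions, and the numerical design choices.
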