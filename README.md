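# lesiondx

Collaborative multilabel case-based reasoning for skin-lesion diagnosis.

## The problem

Early melanoma diagnosis draws on several imaging modalities read by
different specialists. The two most informative are dermoscopy
(epiluminescence microscopy, ~×10–30) and reflectance confocal microscopy
(RCM, cellular resolution, ~×100, the more trusted but scarcer and costlier
test). Once a lesion is reduced to per-modality attribute vectors, the
clinical question is multilabel: is the lesion *melanocytic*, and is it
*malignant*? The 2×2 label combinations give the four working diagnoses —
melanoma (both), basal cell carcinoma (malignant only), and two nonmalignant
classes.

`lesiondx` implements a clinical-protocol-shaped classifier for this setting,
aimed at decision support with case-based explanations:

- **Two CBR subsystems** (one per modality), each a k-nearest-neighbor
  retrieve/reuse/revise/retain cycle over its own case memory, with a bounded
  heterogeneous distance d(a,b) = √(Σδᵢ²/m′) over mixed numeric/categorical
  attributes with missing values, and per-label strict-majority voting
  (support > ½) weighted by each stored case's Laplace-smoothed retrieval
  success (c+1)/(r+2).
- **A rule layer** that mines each attribute independently for concrete
  values nearly pure in one label (support ≥ 3, confidence ≥ 0.9) and
  converts rule hits into per-label reliability weights
  1 + α(agree−disagree)/hits, α = 0.5.
- **A protocol combiner**: the confocal verdict is admissible when its best
  match is within distance 0.5, the dermoscopy verdict within 2× the best
  confocal distance; admissible verdicts vote per label with confocal
  priority on every tie, and only a strictly heavier rule-backed dermoscopy
  vote can override.
- **Case-memory reorganization** by supervised Mahalanobis metric learning
  (Xing-style convex program over same-class/different-class pair
  constraints, diagonal-first, trace-normalized), with guardrails that fall
  back to the identity metric when the learned one does not improve
  retrieval.
- **A leave-one-out harness** producing per-class and pooled
  sensitivity/specificity/accuracy tables across the configuration ladder
  (dermoscopy → confocal → collaborative → +rules → +rules+DML) with paired
  t-test significance marks at 95% confidence.
- **A synthetic paired-modality generator** (150 cases, 41 + 83 attributes,
  nonmalignant-skewed prevalences, confocal separation advantage, planted
  deterministic rule markers, label noise, missing values) so the entire
  stack is testable without the private clinical dataset it emulates.

## Worked example

Generate a synthetic benchmark and evaluate the full configuration ladder:

```bash
lesiondx generate --seed 1 --out-dir bench
lesiondx evaluate --dermoscopy bench/dermoscopy.csv --confocal bench/confocal.csv \
    --dermoscopy-schema bench/dermoscopy_schema.yaml \
    --confocal-schema bench/confocal_schema.yaml --seed 1
```

which prints (abridged to the aggregate table):

```
Leave-one-out evaluation over 150 cases (seed 1)

== Multilabel aggregate (%) ==
                        sensitivity specificity accuracy mark
dermoscopy                       94          90       92
confocal                         95          94       94    ↑
collaborative                    95          94       94    —
collaborative+rules              95          94       94    —
collaborative+rules+dml          95          94       94    —
```

Read it as the ladder of the underlying study: the confocal subsystem
significantly beats dermoscopy (the generator plants a 3× centroid-separation
advantage for confocal, mirroring the modality's higher resolution — the `↑`
is a paired t-test at 95% confidence against the previous row), and the
collaborative protocol preserves the confocal level while adding dermoscopy
coverage. On a single 150-case run the rule and metric-learning steps are
within noise of the strict confocal ceiling imposed by 5% label noise (`—`
marks); averaged over seeds they add a further fraction of a percent each
(see the acceptance report below). Per-class tables (sensitivity,
specificity and accuracy for melanoma, BCC and the two nonmalignant classes)
are printed above the aggregate.

Classify new lesions with explanations (one JSON record per query, with the
retrieved cases, distances, per-label supports and provenance):

```bash
lesiondx classify --dermoscopy bench/dermoscopy.csv --confocal bench/confocal.csv \
    --queries-dermoscopy queries_derm.csv --queries-confocal queries_conf.csv
```

`lesiondx extract-rules` and `lesiondx learn-metric` expose the rule layer
and metric learning separately; both serialize to JSON for reuse and audit.

## Library use

```python
from lesiondx import GeneratorConfig, generate, leave_one_out, PipelineSpec
from lesiondx.evaluation import multilabel_metrics

derm, conf, truth = generate(GeneratorConfig(seed=1))
spec = PipelineSpec("full", rules_enabled=True, dml_enabled=True)
results = leave_one_out(derm, conf, spec, seed=1)
print(multilabel_metrics(results))  # (sensitivity %, specificity %, accuracy %)
```

Case bases are plain CSV (case_id, attribute columns, then
`melanocytic,malignant` ∈ {0,1}; empty cells = missing) with an optional YAML
schema declaring each attribute's kind.

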