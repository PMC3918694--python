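# Methods

`lesiondx` implements a collaborative, multilabel case-based-reasoning (CBR)
pipeline for skin-lesion diagnosis from two imaging modalities — dermoscopy
and reflectance confocal microscopy (RCM) — each reduced to a flat attribute
vector per lesion. This note documents the models, the parameters that
matter, the numerical choices, what the synthetic benchmark does and does not
emulate, and the known limitations.

## Labels and diagnoses

Each lesion carries two nondisjunctive binary labels, *melanocytic* and
*malignant*. Their four combinations map bijectively onto the diagnosis
classes: melanoma (melanocytic ∧ malignant), basal cell carcinoma
(¬melanocytic ∧ malignant), and the two nonmalignant classes. Working with
the label pair rather than a single four-way class is the multilabel
formulation: each subsystem votes both labels at once, and no information is
lost by collapsing them.

## Case memories and distance

A case memory is a schema-typed table of solved cases for one modality.
Similarity is a bounded heterogeneous distance

d(a, b) = sqrt( (1/m′) Σᵢ δᵢ² ),

with δᵢ the min–max-scaled difference for numeric attributes, |a−b| for
binary ones, and the 0/1 identity mismatch for categorical ones; m′ counts
attributes observed in *both* vectors, which keeps cases with missing values
commensurable and bounds d in [0, 1]. Normalization statistics are fitted on
the stored cases and applied unchanged to queries (scaled values clipped to
[0, 1]); a constant attribute (range 0) contributes no distance. The bounded
form is what makes the protocol's absolute confocal admissibility threshold
of 0.5 meaningful. (The alternative reading of "normalized Euclidean" —
per-attribute scaling without the 1/m′ factor — changes only the scale, not
any ranking; the bounded form is used throughout.)

## The four CBR phases

**Retrieve** returns the k nearest stored cases, ties broken by case id for
reproducibility. **Reuse** votes each label positive when the weighted
fraction of retrieved cases carrying it exceeds ½ (exactly ½ is negative);
with unit weights this is the strict-majority rule of multilabel k-NN, and
k = 1 degenerates to plain 1-NN label copying. Case weights are
Laplace-smoothed retrieval success rates w = (correct+1)/(retrieved+2), so an
unseen case sits at the neutral prior 0.5 and the >½ threshold stays
meaningful at cold start. **Retain** increments, for every retrieved case and
label, a retrieved counter and — when the case's own stored value matches the
confirmed truth — a correct counter; the query itself is not inserted (an
insertion flag exists but is off, which keeps leave-one-out clean).
**Revise** is an expert-override hook: a provided override replaces the
verdict and feeds retain as truth.

Defaults: k = 1 for single-label-style evaluation, k = 3 for the multilabel
benchmark (odd k avoids split votes; with two labels and weak neighbors,
3-NN voting is also markedly more robust to a sharply concentrated learned
metric than 1-NN).

## Rule layer

A preprocessing pass scans each attribute independently for concrete values —
categorical levels or exactly repeated numeric values, never intervals — that
co-occur almost purely with one label polarity, and freezes each into a rule
with its support (count) and confidence (purity). Defaults min_support = 3,
min_confidence = 0.9 yield few, high-precision rules on a ~150-case memory.
At diagnosis time the rules score each subsystem verdict per label:

weight = 1 + α·(agree − disagree)/max(1, hits), clipped to [1−α, 1+α],

with hits the rules matching the query's attribute values for that label,
and α = 0.5 a moderate influence. A query matching no rule keeps weight 1.
Weights are computed per label (a rule about malignancy weights only the
malignant decision); a pooled verdict-level weight is available. An
alternative hook scales the admissibility thresholds by the rule weights
instead of the votes (`rules_scale_threshold`), since the clinical-protocol
description admits either reading; vote weighting is the default.

## Collaboration protocol

RCM is the reference modality. Its verdict is admissible when its best-case
distance is ≤ 0.5 (the consensus threshold); the dermoscopy verdict is
admissible within 2× the best confocal distance. Admissible verdicts vote
per label; agreement stands, and a disagreement goes to confocal — including
every exact tie — unless dermoscopy carries strictly higher rule-backed
reliability. When only one verdict is admissible it decides alone; when
neither is, the confocal vote is used but flagged low-confidence (an
abstention mode exists), reflecting the protocol's aversion to missed
malignancies.

Two designs were tried and rejected for the disagreement arbiter before
settling on reliability-with-confocal-priority. A vote mass of
weight × (1 − best_distance) lets the lower-dimensional modality win almost
every disagreement, because nearest-neighbor distances concentrate
differently in 41- and 83-attribute spaces (the dermoscopy minimum is
systematically smaller at equal information); a self-normalized contrast
1 − best/median removes the scale artifact but carries no empirical signal
about which subsystem is right on genuinely ambiguous cases. Distances
therefore decide admissibility only, exactly as the protocol states them,
and gating always uses the plain normalized-Euclidean scale even when
retrieval runs under a learned metric — the consensus thresholds were agreed
on that scale, and within-class distances legitimately shrink after metric
learning.

## Metric learning

The case memory is reorganized by a supervised global Mahalanobis metric in
the convex formulation of Xing et al.: minimize the summed squared distances
over same-class pairs S while keeping different-class pairs D spread, via

f(M) = Σ_{S} d²_M − log Σ_{D} d_M,   M ⪰ 0,

over min–max-scaled, one-hot-encoded vectors (a categorical mismatch
contributes exactly 1). Supervision defaults to the four-class diagnosis so
same-class pairs agree on both labels; a metric supervised on malignancy
alone collapses the attributes that separate melanocytic from nonmelanocytic
lesions within a malignancy stratum and degrades the second label. Diagonal
mode is the default (one weight per encoded dimension); full-matrix mode uses
projected gradient with eigenvalue clipping.

Numerics: along every ray M = cV the optimal scale is closed-form
(c* = 1/(2 Σ_S d²_V)), so the diagonal solver minimizes the scale-free
profile ½·log(vᵀA) − log Σ_D d_v with bound-constrained L-BFGS-B (analytic
gradient, cap 300 iterations); the exact constraint sets are used by default
(subsampling of D pairs is available for very large memories). The result is
rescaled to trace(M) = dim, the trace of the identity, so distances stay on
a comparable scale. Two guardrails apply: the learned metric is discarded
for the identity (with a warning) if it worsens the within/between contrast
on the constraints, or if training-set leave-one-out k-NN accuracy under the
supervision labels (at the deployment k) drops below the identity's — the
latter catches the degenerate sparse optimum on weak-signal data, where all
mass lands on a near-constant dimension and almost all distances become
zero.

Training-set checks cannot catch a subtler failure: under label noise the
mislabeled same-class pairs dominate the equivalence term on exactly the
informative dimensions (their penalty grows with the centroid separation
squared), and the resulting metric looks excellent on the cases it was
fitted to. The pipeline therefore uses *validated* selection
(`learn_metric_validated`): the training cases are split into stratified
halves, a metric learned on each half predicts the other by k-NN, and the
full-memory metric is fitted and used only when the held-out comparison
strictly favors it over the identity; otherwise retrieval keeps the plain
metric. Inside leave-one-out the solver is warm-started from the
neighboring fold's solution — the objective is convex, so this affects speed
only.

## Evaluation

Leave-one-out: each case is predicted by a pipeline rebuilt from the other
n−1 cases; normalization, rules, and the metric are refitted inside every
fold by default (no leakage; a fit-once mode exists for comparison). Metrics
are sensitivity tp/(tp+fn), specificity tn/(tn+fp) and accuracy, reported
per diagnosis class (one-vs-rest) and pooled over the two label decisions,
as rounded percentages; undefined ratios are reported as not applicable,
never as 0 or 100. Adjacent configurations of the standard ladder
(dermoscopy-only → confocal-only → collaborative → +rules → +rules+DML) are
compared with a paired t-test at 95% confidence on per-case 0/1 correctness,
marked ↑ when the later configuration is significantly better and — when
equivalent. A paired t-test on binary outcomes is fragile (McNemar's test
would be the textbook choice); the t-test is the implemented protocol and
the per-case correctness the pairing unit.

## Synthetic benchmark

The generator emulates the shape of the clinical dataset the platform
targets: 150 paired cases, 41 dermoscopy and 83 confocal attributes, class
prevalences 0.35/0.25/0.25/0.15 (nonmalignant-melanocytic /
nonmalignant-nonmelanocytic / melanoma / BCC — skewed nonmalignant, as in
practice). 30% of attributes are informative class-conditional Gaussians
(unit noise), split evenly between the two labels so each label owns a
subspace; 20% are categoricals with weak class-conditional frequency skews;
the rest are noise. The dermoscopy centroid gap is 6σ, chosen so the
dermoscopy-only subsystem operates in the published accuracy band for that
modality relative to confocal under 5% label noise; the confocal gap is 3×
larger (`confocal_advantage`), encoding the resolution advantage that
justifies the protocol's confocal priority. Label noise (default 5%) flips
stored labels after attributes are drawn from the true labels, so flipped
cases genuinely contradict their own attribute vectors and cap attainable
stored-label accuracy at ≈91% for 1-NN; 2% of cells are missing. Four
deterministic markers (one per label per modality, support 6) are planted
into stored-label-positive cases and nowhere else — the "data oddities" the
rule layer exists to catch; because they are planted after noise, the rules
remain consistent with stored labels and can recover exactly the cases the
noise makes otherwise unpredictable.

What passing tests on this benchmark show: the protocol machinery —
retrieval, voting, gating, rule recovery, metric recovery, the ladder's
qualitative ordering — behaves as designed under a known generative model.
What they do not show: performance on real dermoscopy/RCM feature
distributions, which are not Gaussian, not independent across attributes,
and not missing-at-random; the published clinical numbers require the
original private hospital dataset.

An 8-case worked fixture (two per class, three attributes per modality)
accompanies the generator; every distance, ranking, rule, gated combination
and leave-one-out prediction is committed in the test suite as a hand trace,
including one designed case whose confocal neighborhood is misleading and
which only the rule layer corrects.

## Known limitations

- The combiner supports exactly the two modalities of the protocol; n-way
  collaboration would need a generalization of the confocal-priority rule.
- Experience weighting matters only after retain feedback accumulates; the
  leave-one-out harness deliberately leaves it at the cold-start prior.
- Rule extraction treats attributes independently by design; correlated
  oddities spanning several attributes are invisible to it.
- The Xing diagonal optimum is sparse by nature; on weak-signal memories the
  guardrails frequently (and correctly) fall back to the identity metric.
- Problem sizes in tests and the acceptance script (n = 150, ≤ 5 seeds)
  match the emulated clinical dataset; all components are O(n²) or better
  and handle memories of a few hundred cases comfortably.
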