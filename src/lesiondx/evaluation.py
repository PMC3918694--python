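"""Leave-one-out evaluation of the diagnosis pipeline.

Each case is predicted by a pipeline rebuilt from the remaining n-1 cases:
normalization statistics, extracted rules, and the learned metric are all
refitted inside every fold by default, so nothing about the held-out case
leaks into its own prediction (a fit-once mode exists for comparison).

Reported metrics follow the clinical convention: per diagnosis class
(one-vs-rest) and pooled over the two labels, each as sensitivity tp/(tp+fn),
specificity tn/(tn+fp) and accuracy, in percent.  Adjacent pipeline
configurations in the standard ladder (dermoscopy-only, confocal-only,
collaborative, +rules, +rules+DML) are compared with a paired t-test on
per-case correctness at 95% confidence, marked with an up-arrow when the
later configuration is significantly better.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .case_model import (
    Case,
    CaseMemory,
    DiagnosisClass,
    LABEL_NAMES,
    LabelSet,
    fit_normalization,
    labels_to_class,
)
from .collaboration import CollaborationConfig, diagnose
from .dml import DMLConfig, learn_metric_validated, transform_memory
from .rules import DEFAULT_MIN_CONFIDENCE, DEFAULT_MIN_SUPPORT, extract_rules

MODES = ("dermoscopy", "confocal", "collaborative")

SIG_BETTER = "↑"   # significantly better than the previous configuration
SIG_SAME = "—"     # statistically equivalent


@dataclass
class PipelineSpec:
    """One evaluated configuration of the platform."""

    name: str
    mode: str = "collaborative"
    rules_enabled: bool = False
    dml_enabled: bool = False
    k: int = 1
    min_support: int = DEFAULT_MIN_SUPPORT
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    collaboration: CollaborationConfig = field(default_factory=CollaborationConfig)
    dml: DMLConfig = field(default_factory=DMLConfig)
    refit_per_fold: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def default_ladder(k: int = 3) -> list[PipelineSpec]:
    """The standard configuration ladder for the multilabel evaluation.

    Multilabel reuse defaults to k = 3 (an odd k avoids split votes and is
    robust to a sharply concentrated learned metric); pass k = 1 for the
    single-label-style 1-NN configuration.
    """
    return [
        PipelineSpec("dermoscopy", mode="dermoscopy", k=k),
        PipelineSpec("confocal", mode="confocal", k=k),
        PipelineSpec("collaborative", k=k),
        PipelineSpec("collaborative+rules", rules_enabled=True, k=k),
        PipelineSpec("collaborative+rules+dml", rules_enabled=True, dml_enabled=True, k=k),
    ]


def _prepare_fold(memory: CaseMemory, spec: PipelineSpec, seed: int, warm: dict | None = None):
    fit_normalization(memory)
    ruleset = None
    if spec.rules_enabled:
        ruleset = extract_rules(memory, spec.min_support, spec.min_confidence)
    if spec.dml_enabled:
        metric = learn_metric_validated(
            memory, replace(spec.dml, seed=seed, guard_k=spec.k), warm_start=warm
        )
        transform_memory(memory, metric)
    return memory, ruleset


def leave_one_out(
    dermoscopy: CaseMemory, confocal: CaseMemory, spec: PipelineSpec, seed: int = 0
) -> pd.DataFrame:
    """Per-case LOO predictions under one configuration.

    Returns a frame indexed by case_id with predicted/true label columns and
    the predicted/true diagnosis class.
    """
    ids_d, ids_c = set(dermoscopy.case_ids), set(confocal.case_ids)
    if ids_d != ids_c:
        raise ValueError(f"unpaired case ids: {sorted(ids_d ^ ids_c)}")
    if len(dermoscopy) < 2:
        raise ValueError("leave-one-out needs at least two cases")

    collab = replace(
        spec.collaboration, rules_enabled=spec.rules_enabled, dml_enabled=spec.dml_enabled,
        k=spec.k,
    )
    full = {"dermoscopy": dermoscopy, "confocal": confocal}
    modalities = ["dermoscopy", "confocal"] if spec.mode == "collaborative" else [spec.mode]

    prepared_once = {}
    if not spec.refit_per_fold:
        for m in modalities:
            mem = full[m]
            fit_normalization(mem)
            prepared_once[m] = _prepare_fold(
                CaseMemory(mem.modality, mem.schema, mem.data, mem.labels, mem.experience),
                spec,
                seed,
            )

    records = []
    warm = {m: {} for m in modalities}  # solver warm starts shared across folds
    for cid in dermoscopy.case_ids:
        memories, rulesets, queries = {}, {}, {}
        for m in modalities:
            if spec.refit_per_fold:
                mem, ruleset = _prepare_fold(full[m].drop(cid), spec, seed, warm[m])
            else:
                base, ruleset = prepared_once[m]
                mem = base.drop(cid)
                mem.normalization = base.normalization
                mem.metric = base.metric
            memories[m] = mem
            if ruleset is not None:
                rulesets[m] = ruleset
            queries[m] = Case(case_id=cid, modality=m, values=full[m].data.loc[cid])
        final = diagnose(queries, memories, rulesets, collab)
        truth = full[modalities[0]].case(cid).labels
        records.append(
            {
                "case_id": cid,
                "pred_melanocytic": final.labels.melanocytic,
                "pred_malignant": final.labels.malignant,
                "true_melanocytic": truth.melanocytic,
                "true_malignant": truth.malignant,
                "pred_class": final.diagnosis_class.value,
                "true_class": labels_to_class(truth).value,
            }
        )
    return pd.DataFrame(records).set_index("case_id")


# ---------------------------------------------------------------------------------
# metrics


def confusion_metrics(predictions, truths):
    """(sensitivity, specificity, accuracy) in percent from boolean vectors.

    A ratio with a zero denominator is returned as ``None`` (not applicable),
    never as 0 or 100.
    """
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(truths, dtype=bool)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and truths must be nonempty and aligned")
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    acc = 100.0 * (tp + tn) / pred.size
    return sens, spec, acc


def per_class_metrics(results: pd.DataFrame) -> dict:
    """One-vs-rest metric triple for each of the four diagnosis classes."""
    out = {}
    for cls in DiagnosisClass:
        pred = results["pred_class"] == cls.value
        true = results["true_class"] == cls.value
        out[cls.value] = confusion_metrics(pred, true)
    return out


def multilabel_metrics(results: pd.DataFrame):
    """Metric triple pooled over the two label decisions of every case."""
    pred = np.concatenate(
        [results[f"pred_{l}"].to_numpy(bool) for l in LABEL_NAMES]
    )
    true = np.concatenate(
        [results[f"true_{l}"].to_numpy(bool) for l in LABEL_NAMES]
    )
    return confusion_metrics(pred, true)


def case_correctness(results: pd.DataFrame) -> np.ndarray:
    """1 when the full diagnosis class is right, else 0 (paired-test unit)."""
    return (results["pred_class"] == results["true_class"]).to_numpy(dtype=float)


def paired_significance(scores_a, scores_b, confidence: float = 0.95) -> str:
    """Paired t-test mark comparing configuration b against a.

    Returns the up-arrow when b is significantly better at the given
    confidence, else the em-dash.  Identical vectors (zero-variance, zero-mean
    differences) are equivalent by definition.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("score vectors must be aligned with length >= 2")
    diff = b - a
    if np.all(diff == 0):
        return SIG_SAME
    t, p = stats.ttest_rel(b, a)
    return SIG_BETTER if (p < 1.0 - confidence and diff.mean() > 0) else SIG_SAME


def mcnemar_significance(scores_a, scores_b, confidence: float = 0.95) -> str:
    """Exact McNemar mark on paired 0/1 correctness (alternative comparison).

    A paired t-test on binary outcomes is the implemented protocol, but for
    paired proportions the textbook test is McNemar's: an exact binomial test
    on the discordant pairs (cases one configuration gets right and the other
    wrong).  Marks b as better when the discordance is significantly skewed
    its way.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("score vectors must be aligned with length >= 2")
    b_only = int(np.sum((b == 1) & (a == 0)))
    a_only = int(np.sum((a == 1) & (b == 0)))
    n_disc = a_only + b_only
    if n_disc == 0:
        return SIG_SAME
    p = stats.binomtest(b_only, n_disc, 0.5).pvalue
    return SIG_BETTER if (p < 1.0 - confidence and b_only > a_only) else SIG_SAME


# ---------------------------------------------------------------------------------
# ladder report


@dataclass
class EvaluationReport:
    rows: list           # per configuration: name, per_class, multilabel, mark
    n_cases: int
    seed: int

    def per_class_frame(self, metric: str) -> pd.DataFrame:
        idx = {"sensitivity": 0, "specificity": 1, "accuracy": 2}[metric]
        data = {}
        for row in self.rows:
            data[row["name"]] = {
                cls: (None if v[idx] is None else round(v[idx]))
                for cls, v in row["per_class"].items()
            }
        return pd.DataFrame(data).T

    def multilabel_frame(self) -> pd.DataFrame:
        recs = {}
        for row in self.rows:
            s, p, a = row["multilabel"]
            recs[row["name"]] = {
                "sensitivity": None if s is None else round(s),
                "specificity": None if p is None else round(p),
                "accuracy": None if a is None else round(a),
                "mark": row["mark"],
            }
        return pd.DataFrame(recs).T

    def render_text(self) -> str:
        parts = [f"Leave-one-out evaluation over {self.n_cases} cases (seed {self.seed})", ""]
        for metric in ("sensitivity", "specificity", "accuracy"):
            parts.append(f"== Per-class {metric} (%) ==")
            parts.append(self.per_class_frame(metric).to_string())
            parts.append("")
        parts.append("== Multilabel aggregate (%) ==")
        parts.append(self.multilabel_frame().to_string())
        return "\n".join(parts)


def evaluate_ladder(
    dermoscopy: CaseMemory,
    confocal: CaseMemory,
    specs: list[PipelineSpec] | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Run LOO for every configuration and mark adjacent-pair significance."""
    specs = specs if specs is not None else default_ladder()
    rows, prev_scores = [], None
    for spec in specs:
        results = leave_one_out(dermoscopy, confocal, spec, seed=seed)
        scores = case_correctness(results)
        mark = paired_significance(prev_scores, scores) if prev_scores is not None else ""
        rows.append(
            {
                "name": spec.name,
                "per_class": per_class_metrics(results),
                "multilabel": multilabel_metrics(results),
                "mark": mark,
                "results": results,
            }
        )
        prev_scores = scores
    return EvaluationReport(rows=rows, n_cases=len(dermoscopy), seed=seed)
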