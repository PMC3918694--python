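"""Combination of the two modality verdicts under the medical protocol.

Confocal microscopy is the reference modality: its verdict is admissible when
its nearest-case distance is at most an absolute threshold (consensus value
0.5 on the bounded distance scale), while the dermoscopy verdict is admissible
only within a multiple (default 2x) of the best confocal distance.  Admissible
verdicts then vote per label by weighted plurality, where a subsystem's
weight is its rule-based reliability for that label (neutral 1 without rule
evidence).  With two voters this means: agreement stands; on disagreement the
confocal vote wins — including every exact tie — unless the dermoscopy
verdict carries strictly higher rule-backed reliability.  Distances decide
admissibility, not the vote: nearest-neighbor distances are not commensurable
across attribute spaces of different dimension, so the protocol's stated
confocal primacy is the arbiter and the rule layer the only override.  When
neither verdict passes its gate the confocal vote is still used (flagged
low-confidence) rather than abstaining, reflecting the protocol's aversion to
missed malignancies; an abstention mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .case_model import Case, CaseMemory, DiagnosisClass, LABEL_NAMES, LabelSet, labels_to_class
from .multilabel_cbr import SubsystemVerdict, classify_query
from .rules import DEFAULT_ALPHA, RuleSet, reliability_weight


@dataclass
class CollaborationConfig:
    confocal_threshold: float = 0.5
    dermoscopy_factor: float = 2.0
    rules_enabled: bool = True
    dml_enabled: bool = True
    alpha: float = DEFAULT_ALPHA
    k: int = 1
    abstain_when_inadmissible: bool = False
    rules_scale_threshold: bool = False  # alternative hook: rules widen/narrow the gates

    def __post_init__(self):
        if not (0.0 < self.confocal_threshold <= 1.0):
            raise ValueError("confocal_threshold must lie in (0, 1]")
        if self.dermoscopy_factor <= 0:
            raise ValueError("dermoscopy_factor must be positive")


@dataclass
class FinalDiagnosis:
    labels: LabelSet
    diagnosis_class: DiagnosisClass
    provenance: dict                      # label -> which subsystem(s) decided it
    explanation: dict = field(default_factory=dict)
    abstained: bool = False

    def to_record(self) -> dict:
        rec = {
            "melanocytic": int(self.labels.melanocytic),
            "malignant": int(self.labels.malignant),
            "diagnosis_class": self.diagnosis_class.value,
            "provenance": dict(self.provenance),
            "abstained": self.abstained,
        }
        for modality, verdict in self.explanation.items():
            if isinstance(verdict, SubsystemVerdict):
                rec[modality] = {
                    "best_distance": round(verdict.best_distance, 4),
                    "retrieved": [
                        {"case_id": r.case.case_id, "distance": round(r.distance, 4)}
                        for r in verdict.retrieved
                    ],
                    "support": {l: round(verdict.per_label_support[l], 4) for l in LABEL_NAMES},
                }
        return rec


def _gate_distance(verdict: SubsystemVerdict) -> float:
    return verdict.best_distance if verdict.gate_distance is None else verdict.gate_distance


def gate(
    verdict: SubsystemVerdict,
    config: CollaborationConfig,
    confocal_best_distance: float | None = None,
    threshold_scale: float = 1.0,
) -> bool:
    """Admissibility of a verdict under the protocol's distance gates.

    Gating uses the plain normalized-Euclidean distance of the best case (the
    scale the consensus thresholds were agreed on), which equals
    ``best_distance`` unless retrieval ran under a learned metric.
    """
    d = _gate_distance(verdict)
    if verdict.modality == "confocal":
        return d <= config.confocal_threshold * threshold_scale
    if confocal_best_distance is None:
        raise ValueError("dermoscopy gating requires the best confocal distance as reference")
    return d <= config.dermoscopy_factor * confocal_best_distance * threshold_scale


def _weight_for(weight, label: str) -> float:
    """Accept one scalar reliability per verdict or a per-label mapping."""
    if isinstance(weight, dict):
        return float(weight[label])
    return float(weight)


def combine(
    confocal: SubsystemVerdict,
    dermoscopy: SubsystemVerdict,
    weights: tuple = (1.0, 1.0),
    config: CollaborationConfig | None = None,
) -> FinalDiagnosis:
    """Per-label reliability-weighted plurality with confocal priority.

    ``weights`` are the (confocal, dermoscopy) reliability weights, each a
    scalar or a per-label mapping.  On disagreement the heavier vote wins and
    every exact tie goes to confocal; when neither verdict is admissible the
    confocal vote is used and flagged (or, in abstention mode, marked
    abstained).
    """
    config = config or CollaborationConfig()
    if confocal.modality == dermoscopy.modality:
        raise ValueError("combine needs one verdict per modality")
    if confocal.modality != "confocal":
        confocal, dermoscopy = dermoscopy, confocal
        weights = (weights[1], weights[0])
    w_conf, w_derm = weights
    if config.rules_scale_threshold:
        scale_c = min(_weight_for(w_conf, l) for l in LABEL_NAMES)
        scale_d = min(_weight_for(w_derm, l) for l in LABEL_NAMES)
        conf_ok = gate(confocal, config, threshold_scale=scale_c)
        derm_ok = gate(dermoscopy, config, _gate_distance(confocal), threshold_scale=scale_d)
        w_conf = w_derm = 1.0
    else:
        conf_ok = gate(confocal, config)
        derm_ok = gate(dermoscopy, config, _gate_distance(confocal))

    decided, provenance = {}, {}
    abstained = False
    for label in LABEL_NAMES:
        v_conf = bool(getattr(confocal.predicted_labels, label))
        v_derm = bool(getattr(dermoscopy.predicted_labels, label))
        if conf_ok and derm_ok:
            if v_conf == v_derm:
                decided[label], provenance[label] = v_conf, "both"
            elif _weight_for(w_derm, label) > _weight_for(w_conf, label):
                decided[label], provenance[label] = v_derm, "dermoscopy"
            else:  # heavier confocal vote, or exact tie: confocal priority
                decided[label], provenance[label] = v_conf, "confocal"
        elif conf_ok:
            decided[label], provenance[label] = v_conf, "confocal"
        elif derm_ok:
            decided[label], provenance[label] = v_derm, "dermoscopy"
        else:
            decided[label], provenance[label] = v_conf, "confocal-low-confidence"
            abstained = config.abstain_when_inadmissible
    labels = LabelSet(decided["melanocytic"], decided["malignant"])
    return FinalDiagnosis(
        labels=labels,
        diagnosis_class=labels_to_class(labels),
        provenance=provenance,
        explanation={"confocal": confocal, "dermoscopy": dermoscopy},
        abstained=abstained,
    )


def diagnose(
    queries: dict,
    memories: dict,
    rulesets: dict | None = None,
    config: CollaborationConfig | None = None,
) -> FinalDiagnosis:
    """Full two-subsystem diagnosis of one lesion.

    ``queries`` maps modality -> Case (either may be absent/None, in which
    case the available subsystem decides alone); ``memories`` maps modality ->
    CaseMemory; ``rulesets`` maps modality -> RuleSet when rules are enabled.
    Deterministic given memories, query and config.
    """
    config = config or CollaborationConfig()
    rulesets = rulesets or {}
    verdicts, weights = {}, {}
    for modality in ("confocal", "dermoscopy"):
        query = queries.get(modality)
        if query is None:
            continue
        memory = memories[modality]
        verdicts[modality] = classify_query(memory, query, k=config.k)
        if config.rules_enabled and modality in rulesets:
            weights[modality] = {
                label: reliability_weight(
                    verdicts[modality], query, rulesets[modality],
                    alpha=config.alpha, label=label,
                )
                for label in LABEL_NAMES
            }
        else:
            weights[modality] = 1.0
    if not verdicts:
        raise ValueError("query provides no modality")
    if len(verdicts) == 1:
        modality, verdict = next(iter(verdicts.items()))
        provenance = {l: f"{modality}-only" for l in LABEL_NAMES}
        return FinalDiagnosis(
            labels=verdict.predicted_labels,
            diagnosis_class=labels_to_class(verdict.predicted_labels),
            provenance=provenance,
            explanation={modality: verdict},
        )
    return combine(
        verdicts["confocal"],
        verdicts["dermoscopy"],
        weights=(weights["confocal"], weights["dermoscopy"]),
        config=config,
    )
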