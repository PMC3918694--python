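"""Attribute-value -> label rules and reliability weighting.

A preprocessing pass scans each attribute *independently* for concrete values
(categorical levels, binary values, or exactly repeated numeric values — no
interval discretization) that co-occur almost purely with one label polarity.
Each such oddity is frozen into a rule with its support (occurrence count)
and confidence (label purity among those occurrences).

At diagnosis time the rules act as a reliability layer: rules whose
attribute/value match the query and whose direction agrees with a subsystem's
verdict raise that verdict's weight, contradicting rules lower it:

    weight = 1 + alpha * (agree - disagree) / max(1, hits),  clipped to [1-alpha, 1+alpha]

A query matching no rule keeps the neutral weight 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .case_model import BINARY, CATEGORICAL, LABEL_NAMES, Case, CaseMemory
from .multilabel_cbr import SubsystemVerdict

DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_CONFIDENCE = 0.9
DEFAULT_ALPHA = 0.5


@dataclass(frozen=True)
class Rule:
    modality: str
    attribute: str
    value: object
    label: str                 # 'melanocytic' or 'malignant'
    direction: str             # 'positive' or 'negative'
    confidence: float
    support: int

    def render(self) -> str:
        sense = "is" if self.direction == "positive" else "is NOT"
        return (
            f"{self.modality}: {self.attribute} = {self.value!r}  =>  lesion {sense} "
            f"{self.label}  (confidence {self.confidence:.2f}, support {self.support})"
        )


@dataclass
class RuleSet:
    modality: str
    rules: list[Rule] = field(default_factory=list)
    min_support: int = DEFAULT_MIN_SUPPORT
    min_confidence: float = DEFAULT_MIN_CONFIDENCE

    def __len__(self):
        return len(self.rules)

    def matching(self, query: Case) -> list[Rule]:
        hits = []
        for r in self.rules:
            v = query.values.get(r.attribute)
            if _values_equal(v, r.value):
                hits.append(r)
        return hits

    def render(self) -> str:
        if not self.rules:
            return f"({self.modality}: no rules extracted)"
        return "\n".join(r.render() for r in self.rules)


def _values_equal(a, b) -> bool:
    if a is None or (isinstance(a, float) and np.isnan(a)):
        return False
    if isinstance(a, (int, float, np.floating, np.integer)) and isinstance(
        b, (int, float, np.floating, np.integer)
    ):
        return float(a) == float(b)
    return a == b


def extract_rules(
    memory: CaseMemory,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> RuleSet:
    """Per-attribute, per-value frequency scan for high-purity associations.

    For every concrete value occurring at least ``min_support`` times and every
    label, a positive (negative) rule is emitted when the fraction of those
    cases with the label positive (negative) reaches ``min_confidence``.
    An empty rule set is a valid outcome.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    if not (0.5 < min_confidence <= 1.0):
        raise ValueError("min_confidence must lie in (0.5, 1]")
    label_arrays = {l: memory.labels[l].to_numpy(dtype=float) for l in LABEL_NAMES}
    rules: list[Rule] = []
    for attr in memory.schema:
        col = memory.data[attr.name]
        if attr.kind in (BINARY,):
            col = pd.to_numeric(col, errors="coerce")
        codes, uniques = pd.factorize(col, use_na_sentinel=True)
        if len(uniques) == 0:
            continue
        counts = np.bincount(codes[codes >= 0], minlength=len(uniques))
        for label in LABEL_NAMES:
            pos = np.bincount(
                codes[codes >= 0], weights=label_arrays[label][codes >= 0], minlength=len(uniques)
            )
            for vi in np.flatnonzero(counts >= min_support):
                frac_pos = pos[vi] / counts[vi]
                value = uniques[vi]
                if isinstance(value, np.generic):
                    value = value.item()
                if frac_pos >= min_confidence:
                    rules.append(
                        Rule(memory.modality, attr.name, value, label, "positive",
                             float(frac_pos), int(counts[vi]))
                    )
                elif 1.0 - frac_pos >= min_confidence:
                    rules.append(
                        Rule(memory.modality, attr.name, value, label, "negative",
                             float(1.0 - frac_pos), int(counts[vi]))
                    )
    return RuleSet(memory.modality, rules, min_support, min_confidence)


def reliability_weight(
    verdict: SubsystemVerdict,
    query: Case,
    ruleset: RuleSet,
    alpha: float = DEFAULT_ALPHA,
    label: str | None = None,
) -> float:
    """Rule-based reliability of one subsystem's verdict for this query.

    With ``label`` given, only rules speaking to that label are counted, so
    each of the two label decisions carries its own reliability; otherwise all
    matching rules are pooled into one verdict-level weight.
    """
    if ruleset.modality != verdict.modality:
        raise ValueError(
            f"ruleset modality {ruleset.modality!r} does not match verdict {verdict.modality!r}"
        )
    hits = ruleset.matching(query)
    if label is not None:
        hits = [r for r in hits if r.label == label]
    if not hits:
        return 1.0
    agree = disagree = 0
    for r in hits:
        predicted_positive = bool(getattr(verdict.predicted_labels, r.label))
        rule_positive = r.direction == "positive"
        if predicted_positive == rule_positive:
            agree += 1
        else:
            disagree += 1
    w = 1.0 + alpha * (agree - disagree) / max(1, len(hits))
    return float(np.clip(w, 1.0 - alpha, 1.0 + alpha))


def ruleset_to_json(ruleset: RuleSet, path) -> None:
    payload = {
        "modality": ruleset.modality,
        "min_support": ruleset.min_support,
        "min_confidence": ruleset.min_confidence,
        "rules": [
            {
                "attribute": r.attribute,
                "value": r.value,
                "label": r.label,
                "direction": r.direction,
                "confidence": r.confidence,
                "support": r.support,
            }
            for r in ruleset.rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def ruleset_from_json(path) -> RuleSet:
    with open(path) as fh:
        payload = json.load(fh)
    rules = [
        Rule(payload["modality"], d["attribute"], d["value"], d["label"], d["direction"],
             d["confidence"], d["support"])
        for d in payload["rules"]
    ]
    return RuleSet(payload["modality"], rules, payload["min_support"], payload["min_confidence"])
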