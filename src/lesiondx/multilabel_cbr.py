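"""The four CBR phases adapted to multilabel diagnosis.

Retrieve finds the k most similar stored cases (delegated to
:mod:`metric_retrieval`).  Reuse votes each label positive when the
(experience-weighted) fraction of retrieved cases carrying it exceeds one
half — with unit weights this is exactly the strict-majority rule of
multilabel k-NN, and with k = 1 it degenerates to plain 1-NN label copying.
Retain feeds back success counters onto the retrieved cases; a case's weight
in later reuse is its Laplace-smoothed success rate, so a never-retrieved
case sits at the neutral prior 0.5 and the >0.5 vote threshold stays
meaningful at cold start.  Revise is an expert-override hook only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .case_model import LABEL_NAMES, Case, CaseMemory, ExperienceRecord, LabelSet
from .metric_retrieval import RetrievedCase, retrieve


@dataclass
class SubsystemVerdict:
    """One subsystem's per-label decision with its retrieval evidence.

    ``median_distance`` — the median distance from the query to the whole
    memory — calibrates the match quality: a best match far below it signals
    an unusually similar stored case, on a scale comparable across modalities
    with different attribute counts.
    """

    modality: str
    predicted_labels: LabelSet
    per_label_support: dict
    best_distance: float
    retrieved: list[RetrievedCase] = field(default_factory=list)
    median_distance: float | None = None
    # distance of the best case on the plain normalized-Euclidean scale; the
    # protocol's admissibility thresholds are defined on that scale even when
    # retrieval itself runs under a learned metric
    gate_distance: float | None = None

    def explain(self) -> str:
        lines = [f"[{self.modality}] nearest distance {self.best_distance:.4f}"]
        for r in self.retrieved:
            lab = r.case.labels
            lines.append(
                f"  case {r.case.case_id}  d={r.distance:.4f}  "
                f"melanocytic={int(lab.melanocytic)} malignant={int(lab.malignant)}"
            )
        for l in LABEL_NAMES:
            lines.append(f"  support({l}) = {self.per_label_support[l]:.4f}")
        return "\n".join(lines)


def case_weight(exp: ExperienceRecord, label: str) -> float:
    """Laplace-smoothed retrieval success rate, (correct+1)/(retrieved+2)."""
    exp.validate()
    return (exp.times_correct[label] + 1.0) / (exp.times_retrieved[label] + 2.0)


def reuse_multilabel(
    retrieved: list[RetrievedCase], weights: dict | None = None
) -> SubsystemVerdict:
    """Weighted strict-majority vote per label over the retrieved cases.

    ``weights`` is a per-case weight sequence aligned with ``retrieved`` (or a
    dict mapping label -> sequence for per-label weights); ``None`` uses the
    cases' own experience weights.  A label is positive iff its weighted
    support exceeds 0.5 (exactly half is negative).
    """
    if not retrieved:
        raise ValueError("reuse needs a nonempty retrieval list")
    support = {}
    for label in LABEL_NAMES:
        if weights is None:
            w = [case_weight(r.case.experience, label) for r in retrieved]
        elif isinstance(weights, dict):
            w = list(weights[label])
        else:
            w = list(weights)
        if len(w) != len(retrieved):
            raise ValueError("weights not aligned with retrieved cases")
        if any(x < 0 for x in w):
            raise ValueError("weights must be nonnegative")
        tot = sum(w)
        if tot == 0:
            raise ValueError("all case weights are zero")
        pos = sum(
            wi for wi, r in zip(w, retrieved) if getattr(r.case.labels, label)
        )
        support[label] = pos / tot
    predicted = LabelSet(support["melanocytic"] > 0.5, support["malignant"] > 0.5)
    return SubsystemVerdict(
        modality=retrieved[0].case.modality,
        predicted_labels=predicted,
        per_label_support=support,
        best_distance=min(r.distance for r in retrieved),
        retrieved=list(retrieved),
    )


def reuse_single(retrieved: list[RetrievedCase], target_label: str) -> bool:
    """1-NN single-label reuse: copy the nearest case's value for one label."""
    if not retrieved:
        raise ValueError("reuse needs a nonempty retrieval list")
    if target_label not in LABEL_NAMES:
        raise ValueError(f"unknown label {target_label!r}")
    return bool(getattr(retrieved[0].case.labels, target_label))


def classify_query(memory: CaseMemory, query: Case, k: int = 1) -> SubsystemVerdict:
    """Retrieve + reuse for one query against one modality's memory.

    Also records the median query-to-memory distance on the verdict, used by
    the collaborative layer as the scale of a typical (non-)match.
    """
    import numpy as np

    from .metric_retrieval import RetrievedCase, distances_to_memory, normalized_euclidean

    if k < 1:
        raise ValueError("k must be >= 1")
    if len(memory) == 0:
        raise ValueError("cannot retrieve from an empty case memory")
    dists = distances_to_memory(memory, query.values)
    ids = memory.case_ids
    order = sorted(range(len(ids)), key=lambda i: (dists[i], ids[i]))[:k]
    retrieved = [RetrievedCase(case=memory.case(ids[i]), distance=float(dists[i])) for i in order]
    verdict = reuse_multilabel(retrieved)
    verdict.median_distance = float(np.median(dists))
    if memory.metric is None:
        verdict.gate_distance = verdict.best_distance
    else:
        # admissibility is judged on the consensus (plain) distance scale:
        # the gate asks whether the memory holds any sufficiently similar
        # case, regardless of which case the learned metric retrieves
        from .metric_retrieval import _euclidean_rows

        verdict.gate_distance = float(np.min(_euclidean_rows(memory, query.values)))
    return verdict


def retain(
    memory: CaseMemory,
    retrieved: list[RetrievedCase],
    predicted: LabelSet,
    truth: LabelSet,
    query: Case | None = None,
    insert_query: bool = False,
) -> CaseMemory:
    """Update success counters of the retrieved cases against the true labels.

    A retrieved case is counted correct on a label when *its own* stored value
    equals the truth.  By default the query itself is not inserted into the
    memory (which keeps leave-one-out evaluation clean); pass
    ``insert_query=True`` with the query case to store it under the confirmed
    truth labels.
    """
    for r in retrieved:
        cid = r.case.case_id
        for label in LABEL_NAMES:
            memory.experience.loc[cid, f"{label}_retrieved"] += 1
            if bool(getattr(r.case.labels, label)) == bool(getattr(truth, label)):
                memory.experience.loc[cid, f"{label}_correct"] += 1
    if insert_query:
        if query is None:
            raise ValueError("insert_query requires the query case")
        if query.case_id in memory.data.index:
            raise ValueError(f"case_id {query.case_id!r} already stored")
        memory.data.loc[query.case_id] = query.values
        memory.labels.loc[query.case_id] = [truth.melanocytic, truth.malignant]
        memory.experience.loc[query.case_id] = 0
    return memory


def revise(verdict: SubsystemVerdict, expert_override: LabelSet | None = None) -> LabelSet:
    """Expert revision hook: the override wins when provided."""
    return expert_override if expert_override is not None else verdict.predicted_labels
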