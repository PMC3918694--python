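"""Case representation shared by every subsystem.

A *case* is one lesion observed through one imaging modality (dermoscopy or
reflectance confocal microscopy), reduced to a flat attribute vector plus two
nondisjunctive binary labels: *melanocytic* (does the lesion arise from
melanocytes?) and *malignant*.  The 2x2 label combinations map bijectively
onto the four diagnosis classes handled by the medical protocol: melanoma
(melanocytic and malignant), basal cell carcinoma (malignant only), and the
two nonmalignant classes.

Cases live in a :class:`CaseMemory`, the store that k-NN retrieval searches.
Memories carry per-attribute min-max normalization statistics (fitted on the
stored cases, applied unchanged to queries) and, optionally, a learned
Mahalanobis metric (see :mod:`lesiondx.dml`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

MODALITIES = ("dermoscopy", "confocal")
LABEL_NAMES = ("melanocytic", "malignant")

NUMERIC = "numeric"
CATEGORICAL = "categorical"
BINARY = "binary"
KINDS = (NUMERIC, CATEGORICAL, BINARY)


@dataclass(frozen=True)
class AttributeSchema:
    """Declared type of one attribute column."""

    name: str
    kind: str
    categories: tuple | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise ValueError(f"categorical attribute {self.name!r} needs a nonempty category set")
            object.__setattr__(self, "categories", tuple(self.categories))
        elif self.categories is not None:
            raise ValueError(f"{self.kind} attribute {self.name!r} must not declare categories")


class LabelSet(NamedTuple):
    """The two nondisjunctive diagnosis labels. All four combinations are legal."""

    melanocytic: bool
    malignant: bool


class DiagnosisClass(enum.Enum):
    MELANOMA = "melanoma"
    BCC = "bcc"
    NONMALIGNANT_MELANOCYTIC = "nonmalignant_melanocytic"
    NONMALIGNANT_NONMELANOCYTIC = "nonmalignant_nonmelanocytic"


def labels_to_class(labels: LabelSet) -> DiagnosisClass:
    """Map the (melanocytic, malignant) pair to its diagnosis class.

    Total over the four combinations: melanoma is the malignant melanocytic
    tumor, BCC the malignant nonmelanocytic one.
    """
    if labels.malignant:
        return DiagnosisClass.MELANOMA if labels.melanocytic else DiagnosisClass.BCC
    return (
        DiagnosisClass.NONMALIGNANT_MELANOCYTIC
        if labels.melanocytic
        else DiagnosisClass.NONMALIGNANT_NONMELANOCYTIC
    )


_CLASS_TO_LABELS = {
    DiagnosisClass.MELANOMA: LabelSet(True, True),
    DiagnosisClass.BCC: LabelSet(False, True),
    DiagnosisClass.NONMALIGNANT_MELANOCYTIC: LabelSet(True, False),
    DiagnosisClass.NONMALIGNANT_NONMELANOCYTIC: LabelSet(False, False),
}


def class_to_labels(cls: DiagnosisClass) -> LabelSet:
    """Inverse of :func:`labels_to_class`."""
    return _CLASS_TO_LABELS[cls]


@dataclass
class ExperienceRecord:
    """Retrieval-success counters per label, filled by the retain phase."""

    times_retrieved: dict = field(default_factory=lambda: {l: 0 for l in LABEL_NAMES})
    times_correct: dict = field(default_factory=lambda: {l: 0 for l in LABEL_NAMES})

    def validate(self) -> None:
        for l in LABEL_NAMES:
            if not 0 <= self.times_correct[l] <= self.times_retrieved[l]:
                raise ValueError(f"experience counters inconsistent for label {l}")


@dataclass
class Case:
    """One lesion's attribute vector for one modality.

    ``labels`` is ``None`` for a query whose diagnosis is unknown.  Missing
    attribute values are NaN (numeric/binary) or ``None``/NaN (categorical).
    """

    case_id: str
    modality: str
    values: pd.Series
    labels: LabelSet | None = None
    experience: ExperienceRecord = field(default_factory=ExperienceRecord)


@dataclass
class CaseMemory:
    """A schema-typed collection of labeled cases for one modality.

    ``data`` is indexed by case_id with one column per schema attribute;
    ``labels`` is a boolean frame with ``melanocytic``/``malignant`` columns;
    ``experience`` holds the four retain counters per case.
    """

    modality: str
    schema: list[AttributeSchema]
    data: pd.DataFrame
    labels: pd.DataFrame
    experience: pd.DataFrame | None = None
    normalization: pd.DataFrame | None = None
    metric: "object | None" = None  # LearnedMetric, set by dml.transform_memory

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique within a modality")
        if list(self.data.columns) != names:
            raise ValueError("data columns do not match schema")
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate case_ids: {dupes}")
        if self.experience is None:
            self.experience = pd.DataFrame(
                0,
                index=self.data.index,
                columns=[f"{l}_{c}" for l in LABEL_NAMES for c in ("retrieved", "correct")],
            )

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)

    def case(self, case_id: str) -> Case:
        row = self.labels.loc[case_id]
        exp_row = self.experience.loc[case_id]
        exp = ExperienceRecord(
            times_retrieved={l: int(exp_row[f"{l}_retrieved"]) for l in LABEL_NAMES},
            times_correct={l: int(exp_row[f"{l}_correct"]) for l in LABEL_NAMES},
        )
        return Case(
            case_id=case_id,
            modality=self.modality,
            values=self.data.loc[case_id],
            labels=LabelSet(bool(row["melanocytic"]), bool(row["malignant"])),
            experience=exp,
        )

    def query(self, case_id: str) -> Case:
        """The case as an unlabeled query (for leave-one-out)."""
        return Case(case_id=case_id, modality=self.modality, values=self.data.loc[case_id])

    def drop(self, case_id: str) -> "CaseMemory":
        """A new memory without ``case_id``; normalization/metric are reset."""
        keep = self.data.index != case_id
        return CaseMemory(
            modality=self.modality,
            schema=self.schema,
            data=self.data.loc[keep],
            labels=self.labels.loc[keep],
            experience=self.experience.loc[keep],
        )

    def label_array(self, label: str) -> np.ndarray:
        return self.labels[label].to_numpy(dtype=bool)

    def diagnosis_classes(self) -> list[DiagnosisClass]:
        return [
            labels_to_class(LabelSet(bool(m), bool(g)))
            for m, g in zip(self.labels["melanocytic"], self.labels["malignant"])
        ]


def fit_normalization(memory: CaseMemory) -> CaseMemory:
    """Fit per-attribute min-max statistics on the stored cases (in place).

    Only numeric attributes get min/max; an attribute whose non-missing values
    are all equal is flagged constant (range 0) and contributes no distance.
    Raises if the memory is empty or a numeric attribute is entirely missing.
    """
    if len(memory) == 0:
        raise ValueError("cannot fit normalization on an empty case memory")
    rows = []
    for attr in memory.schema:
        if attr.kind != NUMERIC:
            continue
        col = pd.to_numeric(memory.data[attr.name], errors="coerce")
        if col.notna().sum() == 0:
            raise ValueError(f"attribute {attr.name!r} has no observed values")
        lo, hi = float(col.min()), float(col.max())
        rows.append({"attribute": attr.name, "min": lo, "max": hi, "constant": lo == hi})
    memory.normalization = pd.DataFrame(rows).set_index("attribute") if rows else pd.DataFrame(
        columns=["min", "max", "constant"]
    )
    return memory


# -- file formats ------------------------------------------------------------------
#
# Case-base CSV: first column case_id, then attribute columns, last two columns
# melanocytic,malignant in {0,1}; empty cell = missing.  Companion schema YAML is a
# list of {name, kind, categories?}; if absent, kinds are inferred (numeric when all
# non-missing values parse as numbers, else categorical).


def schema_to_yaml(schema: Sequence[AttributeSchema], path) -> None:
    out = []
    for a in schema:
        d = {"name": a.name, "kind": a.kind}
        if a.categories is not None:
            d["categories"] = list(a.categories)
        out.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def schema_from_yaml(path) -> list[AttributeSchema]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        AttributeSchema(d["name"], d["kind"], tuple(d["categories"]) if "categories" in d else None)
        for d in raw
    ]


def infer_schema(df: pd.DataFrame) -> list[AttributeSchema]:
    schema = []
    for name in df.columns:
        col = df[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().sum() == col.notna().sum():
            vals = set(numeric.dropna().unique())
            if vals <= {0.0, 1.0}:
                schema.append(AttributeSchema(name, BINARY))
            else:
                schema.append(AttributeSchema(name, NUMERIC))
        else:
            cats = tuple(sorted(col.dropna().astype(str).unique()))
            schema.append(AttributeSchema(name, CATEGORICAL, cats))
    return schema


def load_case_base(csv_path, modality: str, schema_path=None) -> CaseMemory:
    """Read a case-base CSV (and optional schema YAML) into a fitted CaseMemory."""
    df = pd.read_csv(csv_path, dtype={"case_id": str})
    if df.columns[0] != "case_id" or list(df.columns[-2:]) != list(LABEL_NAMES):
        raise ValueError(
            "case base must have case_id first and melanocytic,malignant as the last two columns"
        )
    df = df.set_index("case_id")
    labels = df[list(LABEL_NAMES)].astype(int).astype(bool)
    attrs = df.drop(columns=list(LABEL_NAMES))
    if schema_path is not None:
        schema = schema_from_yaml(schema_path)
    else:
        schema = infer_schema(attrs)
    # coerce columns to their declared kind
    for a in schema:
        if a.kind in (NUMERIC, BINARY):
            attrs[a.name] = pd.to_numeric(attrs[a.name], errors="coerce")
        else:
            attrs[a.name] = attrs[a.name].where(attrs[a.name].notna(), None)
    mem = CaseMemory(modality=modality, schema=schema, data=attrs, labels=labels)
    return fit_normalization(mem)


def save_case_base(memory: CaseMemory, csv_path, schema_path=None) -> None:
    out = memory.data.copy()
    for l in LABEL_NAMES:
        out[l] = memory.labels[l].astype(int)
    out.to_csv(csv_path, index_label="case_id")
    if schema_path is not None:
        schema_to_yaml(memory.schema, schema_path)
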