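"""Paired-modality synthetic case bases.

The generator emulates the statistical shape of the clinical setting the
platform targets: ~150 suspicious lesions, each observed as a 41-attribute
dermoscopy vector and an 83-attribute confocal vector sharing one latent
diagnosis; mixed numeric/categorical attributes with missing values; a
prevalence skew toward nonmalignant lesions; class signal carried by a
minority of informative attributes, with confocal centroids separated more
strongly than dermoscopy ones (the modality's higher resolution, and the
reason the protocol trusts it more); and a handful of deterministic
attribute-value markers planted into cases of one label, the "data oddities"
the rule layer is built to catch.

Informative numeric attributes are class-conditional Gaussians (unit noise,
centroid gap = ``separation``, times ``confocal_advantage`` for confocal),
split evenly between the two labels so each label owns a subspace.
Categorical attributes carry weak class-conditional frequency skews.  Label
noise flips the *stored* labels; the pre-noise truth is returned separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .case_model import (
    BINARY,
    CATEGORICAL,
    LABEL_NAMES,
    NUMERIC,
    AttributeSchema,
    CaseMemory,
    DiagnosisClass,
    LabelSet,
    class_to_labels,
    fit_normalization,
)

DEFAULT_PREVALENCES = {
    DiagnosisClass.NONMALIGNANT_MELANOCYTIC: 0.35,
    DiagnosisClass.NONMALIGNANT_NONMELANOCYTIC: 0.25,
    DiagnosisClass.MELANOMA: 0.25,
    DiagnosisClass.BCC: 0.15,
}

_BASE_CATEGORIES = ("a", "b", "c")


@dataclass(frozen=True)
class PlantedRule:
    modality: str
    attribute: str
    value: object
    label: str
    direction: str = "positive"
    support: int = 6


def default_planted_rules() -> list[PlantedRule]:
    # one marker per label per modality, on the first two categorical columns
    return [
        PlantedRule("dermoscopy", "d_cat00", "flag_mal", "malignant"),
        PlantedRule("dermoscopy", "d_cat01", "flag_mel", "melanocytic"),
        PlantedRule("confocal", "c_cat00", "flag_mal", "malignant"),
        PlantedRule("confocal", "c_cat01", "flag_mel", "melanocytic"),
    ]


@dataclass
class GeneratorConfig:
    n_cases: int = 150
    n_dermoscopy_attrs: int = 41
    n_confocal_attrs: int = 83
    class_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    informative_fraction: float = 0.3
    categorical_fraction: float = 0.2
    separation: float = 6.0
    confocal_advantage: float = 3.0
    categorical_signal: float = 0.15
    planted_rules: list = field(default_factory=default_planted_rules)
    label_noise: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_prevalences.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class prevalences must sum to 1 (got {total})")
        for name, rate in (("label_noise", self.label_noise), ("missing_rate", self.missing_rate),
                           ("informative_fraction", self.informative_fraction),
                           ("categorical_fraction", self.categorical_fraction)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.confocal_advantage <= 0:
            raise ValueError("confocal_advantage must be positive")


@dataclass
class SyntheticTruth:
    true_labels: pd.DataFrame            # pre-noise labels, indexed by case_id
    planted_rules: list
    informative: dict                    # modality -> {label: [attribute names]}
    separations: dict                    # modality -> centroid gap used

    def to_json(self, path) -> None:
        payload = {
            "true_labels": {
                cid: {l: bool(row[l]) for l in LABEL_NAMES}
                for cid, row in self.true_labels.iterrows()
            },
            "planted_rules": [
                {"modality": r.modality, "attribute": r.attribute, "value": r.value,
                 "label": r.label, "direction": r.direction, "support": r.support}
                for r in self.planted_rules
            ],
            "informative": self.informative,
            "separations": self.separations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _modality_layout(prefix: str, n_attrs: int, informative_fraction, categorical_fraction):
    n_cat = int(round(categorical_fraction * n_attrs))
    n_num = n_attrs - n_cat
    n_inf = min(n_num, max(2, int(round(informative_fraction * n_attrs))))
    num_names = [f"{prefix}_num{i:02d}" for i in range(n_num)]
    cat_names = [f"{prefix}_cat{i:02d}" for i in range(n_cat)]
    inf_mel = num_names[: n_inf // 2]
    inf_mal = num_names[n_inf // 2 : n_inf]
    return num_names, cat_names, inf_mel, inf_mal


def _generate_modality(
    rng, modality, prefix, n_attrs, true_labels: pd.DataFrame, stored_labels: pd.DataFrame,
    config: GeneratorConfig
):
    sep = config.separation * (config.confocal_advantage if modality == "confocal" else 1.0)
    num_names, cat_names, inf_mel, inf_mal = _modality_layout(
        prefix, n_attrs, config.informative_fraction, config.categorical_fraction
    )
    n = len(true_labels)
    data = {}
    mel = true_labels["melanocytic"].to_numpy(dtype=float)
    mal = true_labels["malignant"].to_numpy(dtype=float)
    for name in num_names:
        x = rng.normal(0.0, 1.0, size=n)
        if name in inf_mel:
            x += sep * mel
        elif name in inf_mal:
            x += sep * mal
        data[name] = x
    cls = np.where(mel > 0, 2, 0) + np.where(mal > 0, 1, 0)  # 4-class index
    for name in cat_names:
        base = rng.dirichlet([2.0, 2.0, 2.0])
        probs = np.empty((4, 3))
        for c in range(4):
            probs[c] = (1 - config.categorical_signal) * base + config.categorical_signal * rng.dirichlet(
                [1.0, 1.0, 1.0]
            )
            probs[c] /= probs[c].sum()
        draws = np.array(
            [rng.choice(3, p=probs[cls[i]]) for i in range(n)]
        )
        data[name] = [_BASE_CATEGORIES[d] for d in draws]
    df = pd.DataFrame(data, index=true_labels.index)[num_names + cat_names]

    # missing values (planted markers are written afterwards and stay observed)
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        for j, col in enumerate(df.columns):
            rows = np.flatnonzero(mask[:, j])
            if len(rows):
                df.iloc[rows, j] = np.nan if col in num_names else None

    extra_cats: dict[str, set] = {}
    for rule in [r for r in config.planted_rules if r.modality == modality]:
        if rule.attribute not in df.columns:
            raise ValueError(f"planted rule references unknown attribute {rule.attribute!r}")
        want_positive = rule.direction == "positive"
        eligible = np.flatnonzero(stored_labels[rule.label].to_numpy(bool) == want_positive)
        if len(eligible) < rule.support:
            raise ValueError(
                f"cannot plant rule on {rule.attribute}: only {len(eligible)} eligible cases"
            )
        chosen = rng.choice(eligible, size=rule.support, replace=False)
        df.iloc[chosen, df.columns.get_loc(rule.attribute)] = rule.value
        if rule.attribute.startswith(f"{prefix}_cat"):
            extra_cats.setdefault(rule.attribute, set()).add(rule.value)

    schema = [AttributeSchema(nm, NUMERIC) for nm in num_names] + [
        AttributeSchema(
            nm, CATEGORICAL, _BASE_CATEGORIES + tuple(sorted(extra_cats.get(nm, ())))
        )
        for nm in cat_names
    ]
    mem = CaseMemory(modality=modality, schema=schema, data=df, labels=stored_labels.copy())
    informative = {"melanocytic": inf_mel, "malignant": inf_mal}
    return fit_normalization(mem), informative, sep


def generate(config: GeneratorConfig) -> tuple[CaseMemory, CaseMemory, SyntheticTruth]:
    """Draw paired dermoscopy/confocal memories and their ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    case_ids = [f"L{i:03d}" for i in range(config.n_cases)]

    classes = list(config.class_prevalences.keys())
    probs = np.array([config.class_prevalences[c] for c in classes])
    drawn = rng.choice(len(classes), size=config.n_cases, p=probs)
    true_rows = [class_to_labels(classes[i]) for i in drawn]
    true_labels = pd.DataFrame(
        {
            "melanocytic": [l.melanocytic for l in true_rows],
            "malignant": [l.malignant for l in true_rows],
        },
        index=pd.Index(case_ids, name="case_id"),
    )

    # attributes follow the *true* labels; noise then flips only the stored
    # labels, so a flipped case genuinely contradicts its own attribute vector
    stored = true_labels.copy()
    if config.label_noise > 0:
        for l in LABEL_NAMES:
            flips = rng.random(config.n_cases) < config.label_noise
            stored[l] = stored[l] ^ flips

    derm, inf_d, sep_d = _generate_modality(
        rng, "dermoscopy", "d", config.n_dermoscopy_attrs, true_labels, stored, config
    )
    conf, inf_c, sep_c = _generate_modality(
        rng, "confocal", "c", config.n_confocal_attrs, true_labels, stored, config
    )
    truth = SyntheticTruth(
        true_labels=true_labels,
        planted_rules=list(config.planted_rules),
        informative={"dermoscopy": inf_d, "confocal": inf_c},
        separations={"dermoscopy": sep_d, "confocal": sep_c},
    )
    return derm, conf, truth


# ---------------------------------------------------------------------------------
# worked fixture: 8 cases, 3 attributes per modality, every number hand-checkable


def worked_fixture() -> tuple[CaseMemory, CaseMemory, SyntheticTruth]:
    """A tiny paired memory whose distances and protocol trace fit on paper.

    Two cases per diagnosis class.  d1/c1 carry the malignant signal, d2/c2
    the melanocytic one, d3/c3 mirror melanocytic status categorically.  Case
    P6 is the designed reliability case: its confocal vector (c1 = 6) sits
    next to the melanoma P2, so the confocal subsystem calls it malignant and
    the plain protocol follows confocal; with rules on, the pure dermoscopy
    marker d1 = 1 (all four nonmalignant cases, no others) backs the
    dermoscopy verdict on the malignant label and flips the diagnosis back.
    """
    ids = pd.Index([f"P{i}" for i in range(1, 9)], name="case_id")
    labels = pd.DataFrame(
        {
            "melanocytic": [True, True, False, False, True, True, False, False],
            "malignant": [True, True, True, True, False, False, False, False],
        },
        index=ids,
    )
    derm_data = pd.DataFrame(
        {
            "d1": [9.0, 8.0, 9.0, 8.0, 1.0, 1.0, 1.0, 1.0],
            "d2": [4.0, 4.0, 0.0, 0.0, 4.0, 4.0, 0.0, 0.0],
            "d3": ["a", "a", "b", "b", "a", "a", "b", "b"],
        },
        index=ids,
    )
    conf_data = pd.DataFrame(
        {
            "c1": [8.0, 7.0, 8.0, 7.0, 1.0, 6.0, 1.0, 0.0],
            "c2": [2.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0],
            "c3": ["x", "x", "y", "y", "x", "x", "y", "y"],
        },
        index=ids,
    )
    derm_schema = [
        AttributeSchema("d1", NUMERIC),
        AttributeSchema("d2", NUMERIC),
        AttributeSchema("d3", CATEGORICAL, ("a", "b")),
    ]
    conf_schema = [
        AttributeSchema("c1", NUMERIC),
        AttributeSchema("c2", NUMERIC),
        AttributeSchema("c3", CATEGORICAL, ("x", "y")),
    ]
    derm = fit_normalization(
        CaseMemory("dermoscopy", derm_schema, derm_data, labels.copy())
    )
    conf = fit_normalization(
        CaseMemory("confocal", conf_schema, conf_data, labels.copy())
    )
    truth = SyntheticTruth(
        true_labels=labels.copy(),
        planted_rules=[],
        informative={
            "dermoscopy": {"melanocytic": ["d2"], "malignant": ["d1"]},
            "confocal": {"melanocytic": ["c2"], "malignant": ["c1"]},
        },
        separations={"dermoscopy": 1.0, "confocal": 1.0},
    )
    return derm, conf, truth
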