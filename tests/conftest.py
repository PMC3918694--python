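import warnings

import numpy as np
import pandas as pd
import pytest

from lesiondx.case_model import (
    NUMERIC,
    AttributeSchema,
    CaseMemory,
    fit_normalization,
)
from lesiondx.synthetic_data import GeneratorConfig, generate, worked_fixture

# metric-learning fallback warnings are expected on signal-free random data
warnings.filterwarnings("ignore", message=".*learned metric did not improve.*")
warnings.filterwarnings("ignore", message=".*iteration cap.*")


@pytest.fixture(scope="session")
def fixture_pair():
    return worked_fixture()


@pytest.fixture()
def derm_fixture(fixture_pair):
    import copy

    return copy.deepcopy(fixture_pair[0])


@pytest.fixture()
def conf_fixture(fixture_pair):
    import copy

    return copy.deepcopy(fixture_pair[1])


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced default-structure benchmark for fast integration tests."""
    cfg = GeneratorConfig(n_cases=40, n_dermoscopy_attrs=12, n_confocal_attrs=20, seed=11)
    return generate(cfg)


def make_numeric_memory(X, mal, modality="confocal", mel=None):
    """Wrap a plain numeric matrix as a fitted CaseMemory (test helper)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    ids = pd.Index([f"S{i:03d}" for i in range(n)], name="case_id")
    data = pd.DataFrame(X, index=ids, columns=[f"a{j}" for j in range(d)])
    labels = pd.DataFrame(
        {
            "melanocytic": np.zeros(n, dtype=bool) if mel is None else np.asarray(mel, bool),
            "malignant": np.asarray(mal, dtype=bool),
        },
        index=ids,
    )
    schema = [AttributeSchema(f"a{j}", NUMERIC) for j in range(d)]
    return fit_normalization(CaseMemory(modality, schema, data, labels))


@pytest.fixture()
def planted_subspace_memory():
    """Two classes split on axis 0 (sigma 0.1); axis 1 is pure noise."""
    rng = np.random.default_rng(7)
    n = 50
    x0 = np.concatenate([rng.normal(0, 0.1, n), rng.normal(1, 0.1, n)])
    x1 = rng.normal(0, 1.0, 2 * n)
    mal = np.array([False] * n + [True] * n)
    return make_numeric_memory(np.column_stack([x0, x1]), mal)
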