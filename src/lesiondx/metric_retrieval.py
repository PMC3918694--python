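"""Distances and k-NN retrieval over a case memory.

The baseline similarity is a bounded normalized Euclidean distance over
heterogeneous attributes:

    d(a, b) = sqrt( (1/m') * sum_i delta_i^2 )

where delta_i is the min-max-scaled difference for numeric attributes, |a-b|
for binary ones, the 0/1 mismatch for categorical ones, and m' counts the
attributes observed in *both* vectors.  Dividing by m' keeps cases with
missing values commensurable and bounds d in [0, 1], which is what makes the
protocol's absolute confocal gate (0.5) meaningful.

For a memory reorganized by metric learning, retrieval instead uses the
Mahalanobis form sqrt(u^T M u / m) on a purely numeric encoding u of the
attribute vector (numeric attributes min-max scaled, categoricals one-hot with
a 1/sqrt(2) factor so one mismatch contributes exactly 1 to the squared sum).
With M = I this reduces to the normalized Euclidean distance on fully
observed vectors, so thresholds keep their scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_model import BINARY, CATEGORICAL, NUMERIC, Case, CaseMemory

_PSD_TOL = 1e-9


@dataclass
class RetrievedCase:
    case: Case
    distance: float


# ---------------------------------------------------------------------------------
# scalar distances


def _scale_numeric(value, lo, hi, constant):
    if constant:
        return 0.0
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def normalized_euclidean(a, b, schema, normalization, form: str = "mean") -> float:
    """Bounded heterogeneous distance between two attribute vectors.

    ``a``/``b`` are sequences or Series aligned with ``schema``;
    ``normalization`` is the frame fitted by :func:`case_model.fit_normalization`.
    ``form="mean"`` (default) divides the squared sum by the number of
    attributes compared, bounding the distance in [0, 1] — the scale the
    protocol thresholds assume; ``form="sum"`` is the plain root-sum-square
    over the scaled attributes (same ranking on fully observed vectors).
    Raises if no attribute is observed in both vectors or normalization is unfitted.
    """
    if form not in ("mean", "sum"):
        raise ValueError("form must be 'mean' or 'sum'")
    if normalization is None:
        raise ValueError("normalization statistics are not fitted")
    a = pd.Series(list(a), index=[s.name for s in schema]) if not isinstance(a, pd.Series) else a
    b = pd.Series(list(b), index=[s.name for s in schema]) if not isinstance(b, pd.Series) else b
    total, m_used = 0.0, 0
    for attr in schema:
        va, vb = a[attr.name], b[attr.name]
        if _is_missing(va) or _is_missing(vb):
            continue
        m_used += 1
        if attr.kind == NUMERIC:
            row = normalization.loc[attr.name]
            sa = _scale_numeric(float(va), row["min"], row["max"], bool(row["constant"]))
            sb = _scale_numeric(float(vb), row["min"], row["max"], bool(row["constant"]))
            total += (sa - sb) ** 2
        elif attr.kind == BINARY:
            total += (float(va) - float(vb)) ** 2
        else:
            total += 0.0 if va == vb else 1.0
    if m_used == 0:
        raise ValueError("no attribute observed in both vectors")
    return float(np.sqrt(total / m_used if form == "mean" else total))


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False


def mahalanobis_distance(a, b, metric_matrix: np.ndarray) -> float:
    """sqrt((a-b)^T M (a-b)) for a symmetric PSD M over numeric vectors."""
    M = np.asarray(metric_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("metric matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("metric matrix must be symmetric")
    eigmin = float(np.linalg.eigvalsh(M)[0])
    if eigmin < -_PSD_TOL:
        raise ValueError(f"metric matrix is not PSD (min eigenvalue {eigmin:.3e})")
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if diff.shape[0] != M.shape[0]:
        raise ValueError("vector dimension does not match metric matrix")
    return float(np.sqrt(max(diff @ M @ diff, 0.0)))


# ---------------------------------------------------------------------------------
# numeric encoding (for metric learning and Mahalanobis retrieval)


@dataclass
class EncodedMemory:
    """Min-max scaled, one-hot encoded view of a memory's attribute table."""

    X: np.ndarray                 # n_cases x n_dims, missing values imputed
    dims_attr: np.ndarray         # encoded dim -> schema attribute index
    n_attrs: int                  # m, divisor of the normalized distance
    schema: list
    normalization: pd.DataFrame

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    def encode_values(self, values: pd.Series) -> np.ndarray:
        return _encode_rows(pd.DataFrame([values]), self.schema, self.normalization)[0][0]


def _encode_rows(df: pd.DataFrame, schema, normalization):
    cols, dims_attr = [], []
    for j, attr in enumerate(schema):
        col = df[attr.name]
        if attr.kind == NUMERIC:
            row = normalization.loc[attr.name]
            if bool(row["constant"]):
                x = np.zeros(len(df))
            else:
                x = np.clip(
                    (pd.to_numeric(col, errors="coerce").to_numpy(float) - row["min"])
                    / (row["max"] - row["min"]),
                    0.0,
                    1.0,
                )
            x = np.where(np.isnan(x), 0.5, x)  # midpoint imputation for missing
            cols.append(x)
            dims_attr.append(j)
        elif attr.kind == BINARY:
            x = pd.to_numeric(col, errors="coerce").to_numpy(float)
            cols.append(np.where(np.isnan(x), 0.5, x))
            dims_attr.append(j)
        else:
            # one-hot / sqrt(2): a category mismatch contributes exactly 1
            vals = col.to_numpy(object)
            for cat in attr.categories:
                onehot = np.array([(v == cat) for v in vals], dtype=float) / np.sqrt(2.0)
                cols.append(onehot)
                dims_attr.append(j)
    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return X, np.asarray(dims_attr, dtype=int)


def encode_memory(memory: CaseMemory) -> EncodedMemory:
    if memory.normalization is None:
        raise ValueError("fit normalization before encoding")
    X, dims_attr = _encode_rows(memory.data, memory.schema, memory.normalization)
    return EncodedMemory(
        X=X,
        dims_attr=dims_attr,
        n_attrs=len(memory.schema),
        schema=memory.schema,
        normalization=memory.normalization,
    )


# ---------------------------------------------------------------------------------
# vectorized distances to a whole memory


def distances_to_memory(memory: CaseMemory, query_values: pd.Series) -> np.ndarray:
    """Distance from the query to every stored case, under the memory's metric.

    Uses the learned Mahalanobis metric when the memory carries one, otherwise
    the masked normalized Euclidean distance.  Returns an array aligned with
    ``memory.case_ids``.
    """
    if memory.metric is not None:
        enc = encode_memory(memory)
        q = enc.encode_values(query_values)
        return _mahalanobis_rows(enc.X, q, memory.metric.matrix, enc.n_attrs)
    return _euclidean_rows(memory, query_values)


def _mahalanobis_rows(X: np.ndarray, q: np.ndarray, M: np.ndarray, m: int) -> np.ndarray:
    diff = X - q[None, :]
    if M.ndim == 1 or (M.ndim == 2 and np.count_nonzero(M - np.diag(np.diagonal(M))) == 0):
        w = np.diagonal(M) if M.ndim == 2 else M
        sq = (diff * diff) @ w
    else:
        sq = np.einsum("nd,de,ne->n", diff, M, diff)
    return np.sqrt(np.maximum(sq, 0.0) / m)


def _euclidean_rows(memory: CaseMemory, query_values: pd.Series) -> np.ndarray:
    if memory.normalization is None:
        raise ValueError("normalization statistics are not fitted")
    n = len(memory)
    total = np.zeros(n)
    m_used = np.zeros(n, dtype=int)
    for attr in memory.schema:
        qv = query_values[attr.name]
        q_missing = _is_missing(qv)
        col = memory.data[attr.name]
        if attr.kind in (NUMERIC, BINARY):
            x = pd.to_numeric(col, errors="coerce").to_numpy(float)
            present = ~np.isnan(x)
            if q_missing:
                continue
            if attr.kind == NUMERIC:
                row = memory.normalization.loc[attr.name]
                if bool(row["constant"]):
                    d2 = np.zeros(n)
                else:
                    span = row["max"] - row["min"]
                    xs = np.clip((x - row["min"]) / span, 0.0, 1.0)
                    qs = _scale_numeric(float(qv), row["min"], row["max"], False)
                    d2 = (xs - qs) ** 2
            else:
                d2 = (x - float(qv)) ** 2
        else:
            vals = col.to_numpy(object)
            present = np.array([not _is_missing(v) for v in vals])
            if q_missing:
                continue
            d2 = np.array([0.0 if v == qv else 1.0 for v in vals])
        total += np.where(present, np.nan_to_num(d2), 0.0)
        m_used += present.astype(int)
    if np.any(m_used == 0):
        bad = [memory.case_ids[i] for i in np.flatnonzero(m_used == 0)]
        raise ValueError(f"no comparable attributes with stored cases: {bad}")
    return np.sqrt(total / m_used)


def pairwise_distances_matrix(memory: CaseMemory) -> np.ndarray:
    """Full n x n distance matrix under the memory's active metric."""
    if memory.metric is not None:
        enc = encode_memory(memory)
        M = memory.metric.matrix
        n = enc.X.shape[0]
        out = np.zeros((n, n))
        for i in range(n):
            out[i] = _mahalanobis_rows(enc.X, enc.X[i], M, enc.n_attrs)
        return out
    n = len(memory)
    out = np.zeros((n, n))
    for i, cid in enumerate(memory.case_ids):
        out[i] = _euclidean_rows(memory, memory.data.loc[cid])
    return (out + out.T) / 2.0  # enforce exact symmetry against float noise


# ---------------------------------------------------------------------------------
# retrieval


def retrieve(memory: CaseMemory, query: Case, k: int = 1) -> list[RetrievedCase]:
    """The k nearest stored cases, ascending distance, ties broken by case_id.

    Returns all cases when the memory holds fewer than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(memory) == 0:
        raise ValueError("cannot retrieve from an empty case memory")
    dists = distances_to_memory(memory, query.values)
    ids = memory.case_ids
    order = sorted(range(len(ids)), key=lambda i: (dists[i], ids[i]))[:k]
    return [RetrievedCase(case=memory.case(ids[i]), distance=float(dists[i])) for i in order]
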