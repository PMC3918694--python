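"""Supervised global distance-metric learning for case-memory reorganization.

Given class-equivalence constraints S (pairs that should be close) and
inequivalence constraints D (pairs that should be far), a Mahalanobis metric
M is learned in the convex formulation of Xing et al.: minimize the summed
squared within-class distances while keeping the between-class distances
large, here via the equivalent unconstrained objective

    f(M) = sum_{(i,j) in S} d_M^2(x_i, x_j)  -  log( sum_{(i,j) in D} d_M(x_i, x_j) )

minimized over the PSD cone: bound-constrained quasi-Newton (L-BFGS-B,
nonnegative diagonal) in the default diagonal mode, projected gradient with
eigenvalue clipping in full-matrix mode.  Inputs are the min-max scaled,
one-hot encoded case vectors of :func:`metric_retrieval.encode_memory`.

The learned matrix is rescaled to trace(M) = n_dims, the trace of the
identity, so distances stay on the same scale as the plain normalized
Euclidean metric and the protocol's gating thresholds remain comparable
before and after reorganization.  If the optimizer fails to improve the
within/between contrast over the identity (possible on signal-free data),
the identity is returned with a warning instead of a worse metric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .case_model import CaseMemory
from .metric_retrieval import encode_memory

SUPERVISION_CHOICES = ("class", "malignant", "melanocytic")


@dataclass
class ConstraintSets:
    """Equivalence (S) / inequivalence (D) case-id pairs, unordered."""

    S: list[tuple[str, str]]
    D: list[tuple[str, str]]
    supervision_label: str = "class"


@dataclass
class DMLConfig:
    mode: str = "diagonal"        # 'diagonal' or 'full'
    max_iter: int = 300
    tol: float = 1e-6
    max_d_pairs: int | None = None  # optional seeded subsample cap on inequivalence pairs
    seed: int = 0
    supervision_label: str = "class"
    guard_k: int = 1  # neighbors used by the acceptance guard; match deployment k


@dataclass
class LearnedMetric:
    matrix: np.ndarray            # symmetric PSD, trace = n_dims
    objective_trace: list[float] = field(default_factory=list)
    config: DMLConfig = field(default_factory=DMLConfig)
    converged: bool = True

    @property
    def n_dims(self) -> int:
        return self.matrix.shape[0]


def _supervision_values(memory: CaseMemory, label: str):
    if label == "class":
        return [c.value for c in memory.diagnosis_classes()]
    if label not in ("malignant", "melanocytic"):
        raise ValueError(f"unknown supervision label {label!r}")
    return list(memory.labels[label].astype(bool))


def build_constraints(memory: CaseMemory, supervision_label: str = "class") -> ConstraintSets:
    """All within-class pairs as S and between-class pairs as D.

    Raises when the memory holds a single class: no inequivalence constraint
    exists and the metric objective is unbounded toward the zero matrix.
    """
    ids = memory.case_ids
    y = _supervision_values(memory, supervision_label)
    S, D = [], []
    for i, j in combinations(range(len(ids)), 2):
        (S if y[i] == y[j] else D).append((ids[i], ids[j]))
    if not D:
        raise ValueError("all cases share one class: no inequivalence constraints")
    return ConstraintSets(S=S, D=D, supervision_label=supervision_label)


def _pair_diffs(X: np.ndarray, index: dict, pairs, rng, cap):
    if cap is not None and len(pairs) > cap:
        sel = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[i] for i in sel]
    ii = np.fromiter((index[a] for a, b in pairs), dtype=int, count=len(pairs))
    jj = np.fromiter((index[b] for a, b in pairs), dtype=int, count=len(pairs))
    return X[ii] - X[jj]


def learn_metric(
    memory: CaseMemory,
    constraints: ConstraintSets,
    config: DMLConfig | None = None,
    x0: np.ndarray | None = None,
    enc=None,
) -> LearnedMetric:
    """Learn a trace-normalized Mahalanobis metric from the constraint sets.

    ``x0`` optionally warm-starts the diagonal solver (the objective is
    convex, so this changes speed, not the solution); ``enc`` optionally
    supplies the memory's precomputed encoding.
    """
    config = config or DMLConfig()
    if not constraints.S or not constraints.D:
        raise ValueError("both constraint sets must be nonempty")
    enc = enc if enc is not None else encode_memory(memory)
    if enc.n_dims < 1:
        raise ValueError("encoded attribute space is empty")
    index = {cid: i for i, cid in enumerate(memory.case_ids)}
    rng = np.random.default_rng(config.seed)
    Sd = _pair_diffs(enc.X, index, constraints.S, rng, None)
    Dd = _pair_diffs(enc.X, index, constraints.D, rng, config.max_d_pairs)
    if not np.any(Dd):
        raise ValueError("zero between-class scatter: inequivalent pairs coincide")

    d = enc.n_dims
    if config.mode == "diagonal":
        M, trace, converged = _solve_diagonal(Sd, Dd, config, x0=x0)
    elif config.mode == "full":
        M, trace, converged = _solve_full(Sd, Dd, config)
    else:
        raise ValueError(f"unknown DML mode {config.mode!r}")

    # scale indeterminacy: fix trace(M) = trace(I) = d
    tr = float(np.trace(M))
    M = np.eye(d) if tr <= 0 else M * (d / tr)

    if not converged:
        warnings.warn("metric learning hit the iteration cap; returning best iterate")

    # guardrails: never hand back a metric with worse within/between contrast,
    # or worse training-set 1-NN retrieval, than the identity.  On weak-signal
    # data the sparse solution can collapse onto a near-constant dimension
    # (zero distances almost everywhere); retrieval quality catches that.
    y = _supervision_values(memory, constraints.supervision_label)
    k = max(1, config.guard_k)
    if _contrast_worse_than_identity(M, Sd, Dd) or (
        _train_nn_accuracy(enc.X, y, M, k) < _train_nn_accuracy(enc.X, y, np.eye(d), k)
    ):
        warnings.warn("learned metric did not improve retrieval contrast; using identity")
        M = np.eye(d)
    return LearnedMetric(matrix=M, objective_trace=trace, config=config, converged=converged)


def _train_nn_accuracy(X: np.ndarray, y, M: np.ndarray, k: int = 1) -> float:
    """Training-set LOO k-NN accuracy under metric M (majority of k, ties to
    the nearest neighbor's class) — the acceptance check for a learned metric."""
    if np.count_nonzero(M - np.diag(np.diagonal(M))) == 0:
        Xw = X * np.sqrt(np.maximum(np.diagonal(M), 0.0))
    else:
        vals, vecs = np.linalg.eigh(M)
        Xw = X @ (vecs * np.sqrt(np.maximum(vals, 0.0)))
    sq = np.einsum("nd,nd->n", Xw, Xw)
    D = sq[:, None] + sq[None, :] - 2.0 * (Xw @ Xw.T)
    np.fill_diagonal(D, np.inf)
    y = np.asarray(y, dtype=object)
    n = len(y)
    k = min(k, n - 1)
    order = np.argsort(D, axis=1)[:, :k]
    correct = 0
    for i in range(n):
        votes = list(y[order[i]])
        counts = {v: votes.count(v) for v in set(votes)}
        top = max(counts.values())
        leaders = [v for v, c in counts.items() if c == top]
        pred = votes[0] if len(leaders) > 1 else leaders[0]
        correct += pred == y[i]
    return correct / n


def _contrast_worse_than_identity(M, Sd, Dd, tol=1e-9):
    def stats(mat):
        if np.count_nonzero(mat - np.diag(np.diagonal(mat))) == 0:
            w = np.diagonal(mat)
            ws = (Sd * Sd) @ w
            bs = (Dd * Dd) @ w
        else:
            ws = np.einsum("nd,de,ne->n", Sd, mat, Sd)
            bs = np.einsum("nd,de,ne->n", Dd, mat, Dd)
        within_sq = float(np.mean(ws))
        ratio = float(np.mean(np.sqrt(np.maximum(ws, 0.0))) / max(np.mean(np.sqrt(np.maximum(bs, 0.0))), 1e-300))
        return within_sq, ratio

    I = np.eye(M.shape[0])
    w_m, r_m = stats(M)
    w_i, r_i = stats(I)
    return (w_m > w_i + tol) or (r_m > r_i + tol)


def _solve_diagonal(Sd, Dd, config, x0=None):
    """Diagonal metric by bound-constrained quasi-Newton.

    The raw objective f(w) = w.A - log(sum_D d_w) has an analytically optimal
    scale c*(v) = 1/(2 v.A) along every ray w = c v, so the solver minimizes
    the scale-free profile F(v) = (1/2) log(v.A) - log(sum_D d_v) over v >= 0
    and the final trace normalization restores the scale.
    """
    from scipy import optimize

    A = (Sd * Sd).sum(axis=0)          # linear coefficients of the S term
    B = Dd * Dd                        # n_D x d, rows give squared per-dim diffs
    d = A.shape[0]

    def fun_grad(v):
        va = float(v @ A)
        dist = np.sqrt(np.maximum(B @ v, 0.0))
        s = dist.sum()
        if va <= 0 or s <= 0:
            return np.inf, np.zeros(d)
        safe = np.maximum(dist, 1e-12)
        grad = A / (2.0 * va) - (B.T @ (0.5 / safe)) / s
        return 0.5 * np.log(va) - np.log(s), grad

    # the objective is convex, so a warm start (e.g. the neighboring fold's
    # solution in leave-one-out) reaches the same optimum in far fewer steps
    start = np.ones(d)
    if x0 is not None and np.shape(x0) == (d,) and np.all(np.asarray(x0) >= 0) and np.any(x0):
        start = np.asarray(x0, dtype=float)
    f_identity = fun_grad(np.ones(d))[0]
    trace = [min(f_identity, fun_grad(start)[0])]
    res = optimize.minimize(
        fun_grad,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * d,
        callback=lambda vk: trace.append(fun_grad(vk)[0]),
        options={"maxiter": config.max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    converged = bool(res.success) or res.status == 0
    w = np.maximum(res.x, 0.0)
    if not np.any(w) or fun_grad(w)[0] > f_identity:  # never worse than the identity
        w = np.ones(d)
    return np.diag(w), trace, converged


def _solve_full(Sd, Dd, config):
    d = Sd.shape[1]
    S_scatter = Sd.T @ Sd
    M = np.eye(d)

    def objective(mat):
        dist = np.sqrt(np.maximum(np.einsum("nd,de,ne->n", Dd, mat, Dd), 0.0))
        s = dist.sum()
        if s <= 0:
            return np.inf, dist
        return float(np.sum(S_scatter * mat) - np.log(s)), dist

    def project_psd(mat):
        mat = (mat + mat.T) / 2.0
        vals, vecs = np.linalg.eigh(mat)
        vals = np.maximum(vals, 0.0)
        return (vecs * vals) @ vecs.T

    f, dist = objective(M)
    trace = [f]
    step = 1.0 / max(np.abs(S_scatter).max(), 1e-12)
    converged = False
    for _ in range(config.max_iter):
        safe = np.maximum(dist, 1e-12)
        grad = S_scatter - np.einsum("n,nd,ne->de", 1.0 / (2.0 * safe), Dd, Dd) / safe.sum()
        improved = False
        t = step
        for _bt in range(40):
            M_new = project_psd(M - t * grad)
            f_new, dist_new = objective(M_new)
            if f_new < f:
                improved = True
                break
            t *= 0.5
        if not improved:
            converged = True
            break
        if abs(f - f_new) <= config.tol * max(1.0, abs(f)):
            M, f, dist = M_new, f_new, dist_new
            trace.append(f)
            converged = True
            break
        M, f, dist = M_new, f_new, dist_new
        trace.append(f)
        step = t * 2.0
    return M, trace, converged


def learn_metric_validated(
    memory: CaseMemory,
    config: DMLConfig | None = None,
    warm_start: dict | None = None,
) -> LearnedMetric:
    """Learn a metric, but only keep it when held-out validation supports it.

    The training cases are split into two halves (stratified by supervision
    label, seeded); a metric learned on each half predicts the other half by
    k-NN, and the full-memory metric is fitted and returned only when the two
    half-metrics classify strictly more held-out cases correctly than the
    identity does.  This catches the failure mode that no training-set check
    can: under label noise the convex objective is dominated by mislabeled
    same-class pairs, which penalize exactly the informative dimensions, and
    the resulting metric looks excellent on the cases it was fitted to.
    Memories too small to split (or with a single class in a half) fall back
    to the plain guarded fit.  ``warm_start`` is an optional mutable dict
    carrying solver starting points between successive calls (e.g. across
    leave-one-out folds, which share almost all constraints).
    """
    from .case_model import fit_normalization

    config = config or DMLConfig()
    warm = warm_start if warm_start is not None else {}

    def plain_fit(mem, key, enc=None):
        metric = learn_metric(
            mem, build_constraints(mem, config.supervision_label), config,
            x0=warm.get(key), enc=enc,
        )
        warm[key] = np.diagonal(metric.matrix).copy() if config.mode == "diagonal" else None
        return metric

    n = len(memory)
    if n < 20:
        return plain_fit(memory, "full")

    y_all = _supervision_values(memory, config.supervision_label)
    rng = np.random.default_rng(config.seed)
    halves = [[], []]
    for value in sorted(set(map(str, y_all))):
        idx = [i for i, y in enumerate(y_all) if str(y) == value]
        idx = list(rng.permutation(idx))
        halves[0].extend(idx[: len(idx) // 2])
        halves[1].extend(idx[len(idx) // 2 :])

    ids = memory.case_ids
    enc_full = encode_memory(memory)
    k = max(1, config.guard_k)
    gain = 0
    try:
        for hi, (train_half, test_half) in enumerate(
            ((halves[0], halves[1]), (halves[1], halves[0]))
        ):
            rows = sorted(train_half)
            sub = CaseMemory(
                modality=memory.modality,
                schema=memory.schema,
                data=memory.data.iloc[rows],
                labels=memory.labels.iloc[rows],
            )
            fit_normalization(sub)
            from .metric_retrieval import _encode_rows

            enc_sub = encode_memory(sub)
            half_metric = plain_fit(sub, f"half{hi}", enc=enc_sub)
            # predict the held-out half with the training half as memory
            test_rows = sorted(test_half)
            X_test = _encode_rows(memory.data.iloc[test_rows], memory.schema, sub.normalization)[0]
            y_train = [y_all[i] for i in rows]
            y_test = [y_all[i] for i in test_rows]
            for M in (half_metric.matrix, np.eye(half_metric.n_dims)):
                correct = _knn_accuracy(enc_sub.X, y_train, X_test, y_test, M, k)
                gain += correct if M is half_metric.matrix else -correct
    except ValueError:
        return plain_fit(memory, "full")

    if gain <= 0:
        return LearnedMetric(matrix=np.eye(enc_full.n_dims), config=config)
    return plain_fit(memory, "full", enc=enc_full)


def _knn_accuracy(X_train, y_train, X_test, y_test, M, k):
    if np.count_nonzero(M - np.diag(np.diagonal(M))) == 0:
        w = np.sqrt(np.maximum(np.diagonal(M), 0.0))
        A, B = X_train * w, X_test * w
    else:
        vals, vecs = np.linalg.eigh(M)
        T = vecs * np.sqrt(np.maximum(vals, 0.0))
        A, B = X_train @ T, X_test @ T
    D = (
        np.einsum("nd,nd->n", B, B)[:, None]
        + np.einsum("nd,nd->n", A, A)[None, :]
        - 2.0 * (B @ A.T)
    )
    y_train = np.asarray(y_train, dtype=object)
    kk = min(k, len(y_train))
    order = np.argsort(D, axis=1)[:, :kk]
    correct = 0
    for i, yt in enumerate(y_test):
        votes = list(y_train[order[i]])
        counts = {v: votes.count(v) for v in set(votes)}
        top = max(counts.values())
        leaders = [v for v, c in counts.items() if c == top]
        pred = votes[0] if len(leaders) > 1 else leaders[0]
        correct += pred == yt
    return correct


def transform_memory(memory: CaseMemory, metric: LearnedMetric) -> CaseMemory:
    """Attach the learned metric to the memory; retrieval then uses it.

    Stored attribute values are unchanged; re-applying the same metric is a
    no-op.  Raises on an encoded-dimension mismatch.
    """
    enc = encode_memory(memory)
    if metric.n_dims != enc.n_dims:
        raise ValueError(
            f"metric dimension {metric.n_dims} does not match encoded space {enc.n_dims}"
        )
    memory.metric = metric
    return memory


def metric_to_json(metric: LearnedMetric, path) -> None:
    payload = {
        "n_dims": metric.n_dims,
        "mode": metric.config.mode,
        "matrix": metric.matrix.ravel().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def metric_from_json(path) -> LearnedMetric:
    with open(path) as fh:
        payload = json.load(fh)
    n = payload["n_dims"]
    M = np.asarray(payload["matrix"], dtype=float).reshape(n, n)
    return LearnedMetric(matrix=M, config=DMLConfig(mode=payload["mode"]))
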