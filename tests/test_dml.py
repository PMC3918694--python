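import numpy as np
import pytest

from lesiondx.dml import (
    DMLConfig,
    build_constraints,
    learn_metric,
    metric_from_json,
    metric_to_json,
    transform_memory,
)
from lesiondx.metric_retrieval import encode_memory, pairwise_distances_matrix, retrieve
from tests.conftest import make_numeric_memory


class TestBuildConstraints:
    def test_pair_counts_two_vs_two(self):
        mem = make_numeric_memory(np.arange(8).reshape(4, 2), [True, True, False, False])
        cs = build_constraints(mem, "malignant")
        assert (len(cs.S), len(cs.D)) == (2, 4)

    def test_pair_counts_one_vs_two(self):
        mem = make_numeric_memory(np.arange(6).reshape(3, 2), [True, False, False])
        cs = build_constraints(mem, "malignant")
        assert (len(cs.S), len(cs.D)) == (1, 2)

    def test_partition_covers_all_pairs(self):
        rng = np.random.default_rng(2)
        n = 12
        mem = make_numeric_memory(rng.normal(size=(n, 3)), rng.random(n) < 0.5)
        cs = build_constraints(mem, "malignant")
        assert len(cs.S) + len(cs.D) == n * (n - 1) // 2
        assert not set(cs.S) & set(cs.D)

    def test_single_class_memory_rejected(self):
        mem = make_numeric_memory(np.arange(4).reshape(2, 2), [True, True])
        with pytest.raises(ValueError, match="one class"):
            build_constraints(mem, "malignant")


class TestLearnMetric:
    def test_planted_subspace_concentrates_on_informative_axis(self, planted_subspace_memory):
        mem = planted_subspace_memory
        cs = build_constraints(mem, "malignant")
        metric = learn_metric(mem, cs, DMLConfig(seed=0, supervision_label="malignant"))
        w = np.diag(metric.matrix)
        assert w[0] / w.sum() >= 0.9

        # independent oracle: grid search over diagonal metrics confirms the
        # informative axis should dominate (within/between contrast improves
        # monotonically as mass moves to axis 0)
        enc = encode_memory(mem)
        mal = mem.labels["malignant"].to_numpy(bool)
        def contrast(frac0):
            wv = np.array([frac0, 1 - frac0])
            D = np.sqrt(((enc.X[:, None, :] - enc.X[None, :, :]) ** 2 @ wv))
            same = mal[:, None] == mal[None, :]
            iu = np.triu_indices(len(mal), 1)
            within = D[iu][same[iu]].mean()
            between = D[iu][~same[iu]].mean()
            return within / between
        grid = [contrast(f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert np.argmin(grid) == len(grid) - 1

    def test_symmetric_classes_give_near_uniform_metric(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        mem = make_numeric_memory(X, [True] * 30 + [False] * 30)
        cs = build_constraints(mem, "malignant")
        metric = learn_metric(mem, cs, DMLConfig(seed=0, supervision_label="malignant"))
        w = np.diag(metric.matrix)
        # no informative axis: either the identity fallback or a near-balanced metric
        assert w.max() / w.sum() <= 0.75

    def test_one_dimensional_input_gives_positive_scalar(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 0.2, 20), rng.normal(2, 0.2, 20)])[:, None]
        mem = make_numeric_memory(X, [False] * 20 + [True] * 20)
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        assert metric.matrix.shape == (1, 1)
        assert metric.matrix[0, 0] == pytest.approx(1.0)  # trace-normalized

    def test_objective_trace_monotone_nonincreasing(self, planted_subspace_memory):
        mem = planted_subspace_memory
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        t = np.asarray(metric.objective_trace)
        assert np.all(np.diff(t) <= 1e-9)

    def test_matrix_is_psd_and_trace_normalized(self, planted_subspace_memory):
        mem = planted_subspace_memory
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        eigs = np.linalg.eigvalsh(metric.matrix)
        assert eigs.min() >= -1e-9
        assert np.trace(metric.matrix) == pytest.approx(metric.n_dims)

    def test_within_between_ratio_no_worse_than_identity(self, planted_subspace_memory):
        mem = planted_subspace_memory
        cs = build_constraints(mem, "malignant")
        metric = learn_metric(mem, cs, DMLConfig(seed=0))
        enc = encode_memory(mem)
        idx = {cid: i for i, cid in enumerate(mem.case_ids)}
        def ratio(M):
            def mean_dist(pairs):
                diffs = np.array([enc.X[idx[a]] - enc.X[idx[b]] for a, b in pairs])
                return np.mean(np.sqrt(np.einsum("nd,de,ne->n", diffs, M, diffs)))
            return mean_dist(cs.S) / mean_dist(cs.D)
        assert ratio(metric.matrix) <= ratio(np.eye(metric.n_dims)) + 1e-6

    def test_full_mode_also_separates_planted_subspace(self, planted_subspace_memory):
        mem = planted_subspace_memory
        cs = build_constraints(mem, "malignant")
        metric = learn_metric(mem, cs, DMLConfig(mode="full", seed=0, max_iter=150))
        assert metric.matrix[0, 0] > metric.matrix[1, 1]

    def test_empty_constraints_rejected(self, planted_subspace_memory):
        from lesiondx.dml import ConstraintSets

        with pytest.raises(ValueError):
            learn_metric(planted_subspace_memory, ConstraintSets(S=[], D=[("S000", "S001")]))


class TestTransformMemory:
    def test_identity_metric_preserves_ranking(self, planted_subspace_memory):
        from lesiondx.dml import LearnedMetric

        mem = planted_subspace_memory
        q = mem.query(mem.case_ids[0])
        before = [r.case.case_id for r in retrieve(mem, q, k=10)]
        transform_memory(mem, LearnedMetric(matrix=np.eye(encode_memory(mem).n_dims)))
        after = [r.case.case_id for r in retrieve(mem, q, k=10)]
        assert before == after
        mem.metric = None

    def test_loo_accuracy_improves_or_matches_plain(self, planted_subspace_memory):
        mem = planted_subspace_memory
        mal = mem.labels["malignant"].to_numpy(bool)

        def loo_acc():
            D = pairwise_distances_matrix(mem)
            np.fill_diagonal(D, np.inf)
            return (mal[D.argmin(axis=1)] == mal).mean()

        plain = loo_acc()
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        transform_memory(mem, metric)
        learned = loo_acc()
        mem.metric = None
        assert learned >= plain

    def test_transform_idempotent_and_dimension_checked(self, planted_subspace_memory):
        mem = planted_subspace_memory
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        transform_memory(mem, metric)
        transform_memory(mem, metric)
        assert mem.metric is metric
        mem.metric = None
        from lesiondx.dml import LearnedMetric

        with pytest.raises(ValueError, match="dimension"):
            transform_memory(mem, LearnedMetric(matrix=np.eye(5)))

    def test_metric_json_roundtrip(self, tmp_path, planted_subspace_memory):
        mem = planted_subspace_memory
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=0))
        path = tmp_path / "metric.json"
        metric_to_json(metric, path)
        back = metric_from_json(path)
        np.testing.assert_allclose(back.matrix, metric.matrix)


def test_planted_subspace_improvement_across_replicates():
    """Learned metric beats or ties plain Euclidean in >= 18 of 20 replicates."""
    wins = 0
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        n = 25
        x0 = np.concatenate([rng.normal(0, 0.1, n), rng.normal(1, 0.1, n)])
        x1 = rng.normal(0, 1.0, 2 * n)
        mal = np.array([False] * n + [True] * n)
        mem = make_numeric_memory(np.column_stack([x0, x1]), mal)

        def loo_acc():
            D = pairwise_distances_matrix(mem)
            np.fill_diagonal(D, np.inf)
            return (mal[D.argmin(axis=1)] == mal).mean()

        plain = loo_acc()
        metric = learn_metric(mem, build_constraints(mem, "malignant"), DMLConfig(seed=rep))
        transform_memory(mem, metric)
        wins += loo_acc() >= plain
    assert wins >= 18
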