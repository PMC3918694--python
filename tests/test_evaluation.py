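import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesiondx.evaluation import (
    PipelineSpec,
    SIG_BETTER,
    SIG_SAME,
    confusion_metrics,
    case_correctness,
    default_ladder,
    evaluate_ladder,
    leave_one_out,
    multilabel_metrics,
    paired_significance,
    per_class_metrics,
)


class TestConfusionMetrics:
    def test_hand_counts(self):
        pred = [1] * 4 + [0] + [0] * 4 + [1]
        true = [1] * 5 + [0] * 5
        sens, spec, acc = confusion_metrics(pred, true)
        assert (sens, spec, acc) == (80.0, 80.0, 80.0)

    def test_perfect_predictions(self):
        pred = true = [1, 0, 1, 0]
        assert confusion_metrics(pred, true) == (100.0, 100.0, 100.0)

    def test_undefined_ratio_reported_as_none(self):
        sens, spec, acc = confusion_metrics([0, 0], [0, 0])
        assert sens is None and spec == 100.0 and acc == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_agrees_with_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            pred = rng.random(n) < 0.5
            true = rng.random(n) < 0.5
            sens, spec, acc = confusion_metrics(pred, true)
            tp = sum(p and t for p, t in zip(pred, true))
            tn = sum((not p) and (not t) for p, t in zip(pred, true))
            fp = sum(p and not t for p, t in zip(pred, true))
            fn = sum((not p) and t for p, t in zip(pred, true))
            assert acc == pytest.approx(100 * (tp + tn) / n)
            if tp + fn:
                assert sens == pytest.approx(100 * tp / (tp + fn))
            else:
                assert sens is None
            if tn + fp:
                assert spec == pytest.approx(100 * tn / (tn + fp))
            else:
                assert spec is None


def _closed_form_paired_t(a, b):
    """Independent oracle: textbook paired t statistic and two-sided p."""
    d = np.asarray(b, float) - np.asarray(a, float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return t, p


class TestPairedSignificance:
    def test_identical_vectors_are_equivalent(self):
        assert paired_significance([1, 0, 1, 1], [1, 0, 1, 1]) == SIG_SAME

    def test_uniform_improvement_is_significant(self):
        a = [1] * 10 + [0] * 10
        b = [1] * 20
        assert paired_significance(a, b) == SIG_BETTER

    def test_textbook_difference_vector(self):
        # differences (1,0,1,1,0,1,1,1,0,1): t = mean / (sd/sqrt(10))
        diff = np.array([1, 0, 1, 1, 0, 1, 1, 1, 0, 1], dtype=float)
        a = np.zeros(10)
        t, p = _closed_form_paired_t(a, diff)
        mark = paired_significance(a, diff)
        assert mark == (SIG_BETTER if (p < 0.05 and diff.mean() > 0) else SIG_SAME)
        assert mark == SIG_BETTER  # t ~ 4.58, p ~ 0.0013

    def test_matches_closed_form_oracle_on_random_samples(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            a = (rng.random(n) < 0.6).astype(float)
            b = (rng.random(n) < 0.7).astype(float)
            if np.all(a == b):
                continue
            t_oracle, p_oracle = _closed_form_paired_t(a, b)
            t_pkg, p_pkg = stats.ttest_rel(b, a)
            assert t_pkg == pytest.approx(t_oracle, abs=1e-9)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-9)
            expected = SIG_BETTER if (p_oracle < 0.05 and (b - a).mean() > 0) else SIG_SAME
            assert paired_significance(a, b) == expected

    def test_degradation_never_marked_better(self):
        a = [1] * 15 + [0] * 5
        b = [0] * 15 + [0] * 5
        assert paired_significance(a, b) == SIG_SAME


class TestLeaveOneOut:
    def test_one_prediction_per_case(self, fixture_pair):
        derm, conf, _ = fixture_pair
        res = leave_one_out(derm, conf, PipelineSpec("plain"))
        assert len(res) == 8
        assert set(res.index) == set(derm.case_ids)

    def test_duplicate_in_memory_forces_correct_prediction(self, fixture_pair):
        # P5 and P6 share identical dermoscopy vectors: each is the other's
        # zero-distance neighbor, so dermoscopy-only LOO must get both right
        derm, conf, _ = fixture_pair
        res = leave_one_out(derm, conf, PipelineSpec("d", mode="dermoscopy"))
        for cid in ("P5", "P6"):
            assert res.loc[cid, "pred_class"] == res.loc[cid, "true_class"]

    def test_unpaired_ids_rejected(self, fixture_pair):
        derm, conf, _ = fixture_pair
        with pytest.raises(ValueError, match="P8"):
            leave_one_out(derm.drop("P8"), conf, PipelineSpec("plain"))

    def test_leakage_check_own_label_never_influences_prediction(self, fixture_pair):
        derm, conf, _ = fixture_pair
        base = leave_one_out(derm, conf, PipelineSpec("r", rules_enabled=True))
        flipped_derm = derm
        flipped_conf = conf
        import copy

        flipped_derm = copy.deepcopy(derm)
        flipped_conf = copy.deepcopy(conf)
        for mem in (flipped_derm, flipped_conf):
            mem.labels.loc["P1", ["melanocytic", "malignant"]] = [False, False]
        res = leave_one_out(flipped_derm, flipped_conf, PipelineSpec("r", rules_enabled=True))
        assert res.loc["P1", "pred_melanocytic"] == base.loc["P1", "pred_melanocytic"]
        assert res.loc["P1", "pred_malignant"] == base.loc["P1", "pred_malignant"]

    def test_fit_once_mode_runs_and_differs_only_in_fitting(self, fixture_pair):
        derm, conf, _ = fixture_pair
        refit = leave_one_out(derm, conf, PipelineSpec("r", rules_enabled=True))
        once = leave_one_out(
            derm, conf, PipelineSpec("r", rules_enabled=True, refit_per_fold=False)
        )
        assert set(once.columns) == set(refit.columns)
        assert len(once) == len(refit)


class TestLadderReport:
    def test_report_shape_and_marks(self, small_benchmark):
        derm, conf, _ = small_benchmark
        specs = [
            PipelineSpec("dermoscopy", mode="dermoscopy"),
            PipelineSpec("confocal", mode="confocal"),
            PipelineSpec("collaborative"),
        ]
        report = evaluate_ladder(derm, conf, specs, seed=11)
        assert [r["name"] for r in report.rows] == [s.name for s in specs]
        assert report.rows[0]["mark"] == ""
        assert all(r["mark"] in (SIG_BETTER, SIG_SAME) for r in report.rows[1:])
        frame = report.per_class_frame("sensitivity")
        assert frame.shape == (3, 4)
        ml = report.multilabel_frame()
        assert list(ml.columns) == ["sensitivity", "specificity", "accuracy", "mark"]
        text = report.render_text()
        assert "Per-class sensitivity" in text and "Multilabel aggregate" in text

    def test_single_configuration_has_no_mark(self, small_benchmark):
        derm, conf, _ = small_benchmark
        report = evaluate_ladder(derm, conf, [PipelineSpec("collaborative")], seed=11)
        assert report.rows[0]["mark"] == ""

    def test_reports_are_deterministic(self, fixture_pair):
        derm, conf, _ = fixture_pair
        r1 = evaluate_ladder(derm, conf, [PipelineSpec("c")], seed=3)
        r2 = evaluate_ladder(derm, conf, [PipelineSpec("c")], seed=3)
        assert r1.render_text() == r2.render_text()


def test_per_class_and_multilabel_metrics_consistency(fixture_pair):
    derm, conf, _ = fixture_pair
    res = leave_one_out(derm, conf, PipelineSpec("rules", rules_enabled=True))
    per_class = per_class_metrics(res)
    assert set(per_class) == {
        "melanoma", "bcc", "nonmalignant_melanocytic", "nonmalignant_nonmelanocytic"
    }
    # all 8 fixture predictions correct under rules: everything 100
    for triple in per_class.values():
        assert all(v == 100.0 for v in triple)
    assert multilabel_metrics(res) == (100.0, 100.0, 100.0)
    assert case_correctness(res).mean() == 1.0


class TestMcNemarAlternative:
    def test_matches_exact_binomial_oracle(self):
        from scipy import stats as ss

        from lesiondx.evaluation import mcnemar_significance

        rng = np.random.default_rng(30)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            a = (rng.random(n) < 0.6).astype(float)
            b = (rng.random(n) < 0.75).astype(float)
            b_only = int(np.sum((b == 1) & (a == 0)))
            a_only = int(np.sum((a == 1) & (b == 0)))
            if a_only + b_only == 0:
                assert mcnemar_significance(a, b) == SIG_SAME
                continue
            p = ss.binomtest(b_only, a_only + b_only, 0.5).pvalue
            expected = SIG_BETTER if (p < 0.05 and b_only > a_only) else SIG_SAME
            assert mcnemar_significance(a, b) == expected

    def test_identical_vectors_equivalent(self):
        from lesiondx.evaluation import mcnemar_significance

        assert mcnemar_significance([1, 0, 1], [1, 0, 1]) == SIG_SAME
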