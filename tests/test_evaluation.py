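import itertools

import numpy as np
import pytest

from tradervote import (ConfusionMatrix, ObjectiveConfig, PipelineConfig,
                        SearchResult, CandidateSolution, TraderConfig,
                        confusion, cross_validated_run, metrics_report,
                        multiclass_curves, run_set_summary,
                        wilcoxon_rank_sum)
from tradervote.synth import SyntheticSpec, generate


class TestConfusion:
    def test_diagonal_for_perfect_predictions(self):
        y = np.array([0, 1, 2, 1])
        cm = confusion(y, y, 3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_counting(self):
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert cm.counts.tolist() == [[1, 1], [0, 2]]

    @pytest.mark.parametrize("t,p,C", [
        ([], [], 2), ([0, 3], [0, 1], 2), ([0, 1], [0], 2),
    ])
    def test_bad_inputs_rejected(self, t, p, C):
        with pytest.raises(ValueError):
            confusion(t, p, C)


class TestMetricsReport:
    def test_perfect_predictions_all_ones(self):
        rep = metrics_report(ConfusionMatrix(np.diag([3, 4, 5])))
        for v in (rep.accuracy, rep.precision, rep.sensitivity,
                  rep.specificity, rep.f_score):
            assert v == 1.0

    def test_hand_computed_binary_case(self):
        rep = metrics_report(ConfusionMatrix([[3, 1], [2, 4]]))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.per_class["sensitivity"][0] == pytest.approx(0.75)
        assert rep.per_class["sensitivity"][1] == pytest.approx(2 / 3)
        assert rep.sensitivity == pytest.approx((0.75 + 2 / 3) / 2)

    def test_single_class_predictions_zero_spc_for_that_class(self):
        rep = metrics_report(ConfusionMatrix([[5, 0], [5, 0]]))
        assert rep.per_class["specificity"][0] == 0.0

    def test_macro_equals_per_class_mean(self, rng):
        for _ in range(100):
            C = int(rng.integers(2, 6))
            counts = rng.integers(0, 20, size=(C, C))
            if counts.sum() == 0:
                continue
            rep = metrics_report(ConfusionMatrix(counts))
            # independent per-class one-vs-rest recount
            N = counts.sum()
            pre, sen, spc = [], [], []
            for i in range(C):
                tp = counts[i, i]
                fp = counts[:, i].sum() - tp
                fn = counts[i, :].sum() - tp
                tn = N - tp - fp - fn
                pre.append(tp / (tp + fp) if tp + fp else 0.0)
                sen.append(tp / (tp + fn) if tp + fn else 0.0)
                spc.append(tn / (tn + fp) if tn + fp else 0.0)
            assert rep.precision == pytest.approx(np.mean(pre))
            assert rep.sensitivity == pytest.approx(np.mean(sen))
            assert rep.specificity == pytest.approx(np.mean(spc))
            assert rep.accuracy == pytest.approx(np.trace(counts) / N)

    def test_micro_averaging_flag(self):
        rep = metrics_report(ConfusionMatrix([[3, 1], [2, 4]]),
                             average="micro")
        assert rep.precision == pytest.approx(0.7)
        assert rep.sensitivity == pytest.approx(0.7)


class TestCurves:
    def test_perfect_scorer_roc_auc_is_exactly_one(self, rng):
        y = rng.integers(0, 3, 120)
        scores = np.eye(3)[y]
        assert multiclass_curves(scores, y, "ROC").auc == 1.0

    def test_roc_endpoints_and_monotone_x(self, rng):
        y = rng.integers(0, 2, 50)
        cs = multiclass_curves(rng.random((50, 2)), y, "ROC")
        assert np.allclose(cs.points[0], (0, 0))
        assert np.allclose(cs.points[-1], (1, 1))
        assert np.all(np.diff(cs.points[:, 0]) >= 0)

    def test_label_independent_scores_near_half_auc(self, rng):
        y = rng.integers(0, 2, 1000)
        scores = rng.random((1000, 2))
        assert 0.45 <= multiclass_curves(scores, y, "ROC").auc <= 0.55

    def test_null_pr_auc_near_prevalence(self, rng):
        y = rng.integers(0, 2, 1000)
        scores = rng.random((1000, 2))
        prevalence = 0.5  # balanced binary, macro over both classes
        assert multiclass_curves(scores, y, "PR").auc == pytest.approx(
            prevalence, abs=0.05)

    def test_absent_class_skipped_with_warning(self, rng):
        y = np.array([0, 1] * 20)  # class 2 never occurs
        scores = rng.random((40, 3))
        with pytest.warns(UserWarning, match="class 2"):
            cs = multiclass_curves(scores, y, "ROC")
        assert 0.0 <= cs.auc <= 1.0

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            multiclass_curves(np.array([[np.inf, 0.0]]), [0], "ROC")


class TestWilcoxon:
    def test_fully_tied_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_separated_triples_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.random(8), rng.random(6)
        assert wilcoxon_rank_sum(a, b)[1] == pytest.approx(
            wilcoxon_rank_sum(b, a)[1])

    def test_exact_mode_matches_full_enumeration(self):
        # every split of 8 distinct values into |a| = |b| = 4
        vals = np.array([3.0, 1.4, 2.2, 9.1, 5.5, 7.0, 0.3, 4.8])
        ranks = {v: r for r, v in enumerate(sorted(vals), 1)}

        def enum_p(sel):
            n1 = 4
            r_obs = sum(ranks[vals[i]] for i in sel)
            rs = [sum(ranks[vals[i]] for i in c)
                  for c in itertools.combinations(range(8), n1)]
            rs = np.array(rs)
            lo = (rs <= r_obs).mean()
            hi = (rs >= r_obs).mean()
            return min(1.0, 2 * min(lo, hi))

        for sel in itertools.combinations(range(8), 4):
            a = vals[list(sel)]
            b = vals[[i for i in range(8) if i not in sel]]
            assert wilcoxon_rank_sum(a, b)[1] == pytest.approx(enum_p(sel))

    def test_large_or_tied_samples_use_approximation(self, rng):
        a = rng.integers(0, 5, 50).astype(float)
        b = rng.integers(1, 6, 50).astype(float)
        _, p = wilcoxon_rank_sum(a, b)
        assert 0.0 <= p <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestRunSetSummary:
    def _result(self, trace, seed=0):
        best = CandidateSolution(np.array([1]), trace[-1])
        return SearchResult(best, list(trace), len(trace), seed)

    def test_identical_runs_zero_iqr(self):
        rs = [self._result([0.2, 0.4, 0.6])] * 5
        s = run_set_summary(rs)
        assert s.q1 == s.q3 == s.median == 0.6
        assert s.outliers.size == 0

    def test_median_of_nine_runs(self):
        rs = [self._result([0.1 * i]) for i in range(1, 10)]
        assert run_set_summary(rs).median == pytest.approx(0.5)

    def test_mean_trace_of_monotone_traces_is_monotone(self, rng):
        rs = []
        for s in range(10):
            t = np.sort(rng.random(6))
            rs.append(self._result(list(t), s))
        mt = run_set_summary(rs).mean_trace
        assert all(a <= b for a, b in zip(mt, mt[1:]))

    def test_ragged_traces_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            run_set_summary([self._result([0.1]), self._result([0.1, 0.2])])


@pytest.fixture(scope="module")
def tiny_config():
    return PipelineConfig(
        trader=TraderConfig(pop_size=8, iterations=3, subset_size=2,
                            n_groups=2),
        objective=ObjectiveConfig(inner_folds=3),
        ensemble_size=2, outer_folds=3, seed=5)


@pytest.fixture(scope="module")
def tiny_table():
    table, _ = generate(SyntheticSpec(
        n_samples=48, n_features=8, n_informative=3, class_sep=6.0,
        missing_rate=0.02, seed=9))
    return table


class TestCrossValidatedRun:
    def test_every_sample_predicted_once(self, tiny_table, tiny_config):
        res = cross_validated_run(tiny_table, tiny_config)
        assert np.all(res.y_pred >= 0)
        covered = np.concatenate([f.test_idx for f in res.folds])
        assert sorted(covered) == list(range(tiny_table.n_samples))

    def test_deterministic_given_seed(self, tiny_table, tiny_config):
        a = cross_validated_run(tiny_table, tiny_config)
        b = cross_validated_run(tiny_table, tiny_config)
        assert a.metrics.to_dict() == b.metrics.to_dict()
        assert np.array_equal(a.y_pred, b.y_pred)

    def test_selection_never_sees_held_out_rows(self, tiny_table,
                                                tiny_config, monkeypatch):
        import tradervote.evaluation as ev
        seen = []
        real = ev.trader_search

        def spy(table, objective, config):
            seen.append(table.n_samples)
            return real(table, objective, config)

        monkeypatch.setattr(ev, "trader_search", spy)
        cross_validated_run(tiny_table, tiny_config)
        assert seen  # selector ran inside folds
        assert all(n < tiny_table.n_samples for n in seen)

    def test_high_separation_accuracy(self):
        table, _ = generate(SyntheticSpec(
            n_samples=120, n_features=12, n_informative=3, class_sep=8.0,
            seed=13))
        cfg = PipelineConfig(
            trader=TraderConfig(pop_size=10, iterations=5, subset_size=3,
                                n_groups=2),
            objective=ObjectiveConfig(inner_folds=3),
            ensemble_size=2, outer_folds=5, seed=1)
        res = cross_validated_run(table, cfg)
        assert res.metrics.accuracy >= 0.9
        assert res.roc.auc >= 0.9

    def test_leak_compat_mode_runs(self, tiny_table, tiny_config):
        cfg = PipelineConfig(**{**tiny_config.__dict__, "leak_compat": True})
        res = cross_validated_run(tiny_table, cfg)
        # selection happened once: all folds share the same member subsets
        subsets = {tuple(map(tuple, f.member_subsets)) for f in res.folds}
        assert len(subsets) == 1
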