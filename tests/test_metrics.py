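import math

import numpy as np
import pytest

from varfx import metrics as met
from varfx.io import EFFECT, NEUTRAL, UNLABELED, PredictionResult
from varfx.metrics import ConfusionCounts
from varfx.synthetic import worked_confusion_tables


def pairwise_auc_oracle(scores, y):
    """O(n^2) Mann-Whitney oracle: ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1][:, None]
    neg = scores[y == 0][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return wins / ((y == 1).sum() * (y == 0).sum())


class TestConfusionCounts:
    def test_all_correct_effect(self):
        c = met.confusion_counts([(EFFECT, EFFECT)] * 7)
        assert (c.TP, c.FP, c.TN, c.FN) == (7, 0, 0, 0)

    def test_counts_partition_input(self):
        pairs = [(EFFECT, EFFECT), (EFFECT, NEUTRAL), (NEUTRAL, NEUTRAL),
                 (NEUTRAL, EFFECT)] * 3
        c = met.confusion_counts(pairs)
        assert c.total == len(pairs)

    def test_unlabeled_excluded(self):
        c = met.confusion_counts([(EFFECT, EFFECT), (EFFECT, UNLABELED)])
        assert c.total == 1


class TestWorkedTables:
    """Metric implementations against directly computed arithmetic."""

    @pytest.mark.parametrize("counts,expected", worked_confusion_tables(seed=0))
    def test_all_measures(self, counts, expected):
        acc_e, cov_e, acc_n, cov_n = met.class_metrics(counts)
        assert acc_e == pytest.approx(expected["accuracy_effect"])
        assert cov_e == pytest.approx(expected["coverage_effect"])
        assert acc_n == pytest.approx(expected["accuracy_neutral"])
        assert cov_n == pytest.approx(expected["coverage_neutral"])
        assert met.q2(counts) == pytest.approx(expected["q2"])
        assert met.mcc(counts) == pytest.approx(expected["mcc"])
        if "f_effect" in expected:
            f_e, f_n = met.f_measures(counts)
            assert f_e == pytest.approx(expected["f_effect"])
            assert f_n == pytest.approx(expected["f_neutral"])

    def test_canonical_table_values(self):
        c = ConfusionCounts(TP=40, FP=20, TN=30, FN=10)
        assert met.q2(c) == pytest.approx(0.70)
        assert met.mcc(c) == pytest.approx(1000 / math.sqrt(6_000_000))

    def test_f_measure_worked_example(self):
        # precision 0.8, recall 0.5 -> F = 2*0.4/1.3
        c = ConfusionCounts(TP=40, FP=10, TN=0, FN=40)
        f_e, _ = met.f_measures(c)
        assert f_e == pytest.approx(2 * 0.8 * 0.5 / 1.3)


class TestZeroDivisionPolicy:
    def test_undefined_is_none_not_zero(self):
        c = ConfusionCounts(TP=0, FP=0, TN=5, FN=5)
        acc_e, cov_e, acc_n, cov_n = met.class_metrics(c)
        assert acc_e is None
        assert cov_e == 0.0
        f_e, _ = met.f_measures(c)
        assert f_e is None

    def test_mcc_zero_marginal_undefined(self):
        assert met.mcc(ConfusionCounts(TP=0, FP=0, TN=10, FN=10)) is None

    def test_q2_empty_errors(self):
        with pytest.raises(ValueError):
            met.q2(ConfusionCounts())


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [NEUTRAL] * 3 + [EFFECT] * 3
        _, auc = met.roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            met.roc_auc([1, 2], [EFFECT, EFFECT])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80)
        labels = [EFFECT if rng.random() < 0.5 else NEUTRAL for _ in range(80)]
        _, a = met.roc_auc(scores, labels)
        _, b = met.roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(10, 100))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            labels = [EFFECT if t else NEUTRAL for t in y]
            _, auc = met.roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc_oracle(scores, y))


class TestBootstrap:
    def test_constant_metric_zero_sd(self):
        est = met.bootstrap_errors(list(range(100)), lambda items: 1.0,
                                   n_sets=50, seed=0)
        assert est.sd == 0.0 and est.se == 0.0

    def test_se_formula(self):
        est = met.bootstrap_errors(list(range(50)),
                                   lambda items: float(np.mean(items)),
                                   n_sets=200, seed=1)
        assert est.se == pytest.approx(est.sd / math.sqrt(199))

    def test_undefined_sets_skipped(self):
        def metric(items):
            return None if sum(items) % 2 else float(len(items))
        est = met.bootstrap_errors(list(range(20)), metric, n_sets=100, seed=2)
        assert est.n_skipped > 0
        assert len(est.values) + est.n_skipped == 100

    def test_subsample_is_half_without_replacement(self):
        seen = []
        met.bootstrap_errors(list(range(10)),
                             lambda items: seen.append(sorted(items)) or 0.0,
                             n_sets=5, seed=3)
        for subsample in seen:
            assert len(subsample) == 5
            assert len(set(subsample)) == 5


class TestCurves:
    def test_accuracy_coverage_endpoints(self):
        scores = [-50, -10, 10, 50]
        labels = [NEUTRAL, NEUTRAL, EFFECT, EFFECT]
        curve = met.accuracy_coverage_curve(scores, labels, [-100, 0, 100])
        assert curve[0]["coverage_effect"] == pytest.approx(1.0)  # all called effect
        assert curve[-1]["coverage_effect"] == pytest.approx(0.0)
        covs = [row["coverage_effect"] for row in curve]
        assert covs == sorted(covs, reverse=True)

    def make_results(self, scores):
        out = []
        for s in scores:
            diff = s / 100
            eff, neu = (1 + diff) / 2, (1 - diff) / 2
            ri = min(int(abs(diff) * 10), 10)
            out.append(PredictionResult("p", 1, "A", "V", eff, neu, s,
                                        EFFECT if diff > -0.05 else NEUTRAL,
                                        ri, min(ri, 9)))
        return out

    def test_reliability_curve_cumulative(self):
        results = self.make_results([90, 70, -80, -20, 10])
        labels = [EFFECT, EFFECT, NEUTRAL, NEUTRAL, NEUTRAL]
        curve = met.reliability_curve(results, labels)
        assert curve[0]["n_retained"] == 5
        ns = [row["n_retained"] for row in curve]
        assert ns == sorted(ns, reverse=True)
        covs = [row["coverage_effect"] for row in curve if row["coverage_effect"] is not None]
        assert covs == sorted(covs, reverse=True)


class TestTriage:
    def test_all_correct_everything_easy(self):
        labels = {i: EFFECT if i % 2 else NEUTRAL for i in range(10)}
        methods = {"m1": dict(labels), "m2": dict(labels)}
        out = met.triage_difficulty(methods, labels)
        assert len(out["partition"]["easy"]) == 10
        assert not out["partition"]["difficult"]

    def test_complementary_methods_all_difficult(self):
        labels = {i: EFFECT for i in range(6)}
        m1 = {i: EFFECT for i in range(6)}
        m2 = {i: NEUTRAL for i in range(6)}
        out = met.triage_difficulty({"m1": m1, "m2": m2}, labels)
        assert len(out["partition"]["difficult"]) == 6
        assert out["difficult_q2"]["m1"] == 1.0
        assert out["difficult_q2"]["m2"] == 0.0

    def test_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(4)
        labels = {i: EFFECT if rng.random() < 0.6 else NEUTRAL for i in range(200)}
        methods = {
            m: {i: EFFECT if rng.random() < 0.7 else NEUTRAL for i in range(200)}
            for m in ("a", "b", "c")
        }
        out = met.triage_difficulty(methods, labels)
        parts = out["partition"]
        union = set(parts["easy"]) | set(parts["unsolvable"]) | set(parts["difficult"])
        assert union == set(labels)
        assert len(parts["easy"]) + len(parts["unsolvable"]) + \
            len(parts["difficult"]) == 200

    def test_random_baseline_closed_form(self):
        """60:40 background on a 15,121 effect / 7,504 neutral set -> Q2 ~ 0.53."""
        q2 = met.random_baseline_q2(15121, 7504, 0.6)
        assert q2 == pytest.approx(0.6 * (15121 / 22625) + 0.4 * (7504 / 22625))
        assert abs(q2 - 0.53) < 0.01
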