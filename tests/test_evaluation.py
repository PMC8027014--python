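"""Confusion counting, the benchmark metric block, ROC/AUC and the
robustness studies."""

from itertools import permutations

import numpy as np
import pytest

import oipcq
from oipcq import (
    ConfusionCounts,
    Skeleton,
    complete_skeleton,
    confusion,
    make_method,
    metrics,
    permutation_study,
    roc_auc,
    subsample_stability,
    threshold_sd_study,
)


class TestConfusion:
    def test_perfect_prediction(self):
        gold = Skeleton(["A", "B", "C"], [("A", "B")])
        c = confusion(gold, gold)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_exhaustive_three_gene_case(self):
        gold = Skeleton(["A", "B", "C"], [("A", "B"), ("B", "C")])
        pred = Skeleton(["A", "B", "C"], [("A", "B"), ("A", "C")])
        c = confusion(pred, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 0)

    def test_empty_prediction(self):
        gold = Skeleton(["A", "B", "C"], [("A", "B"), ("B", "C")])
        pred = Skeleton(["A", "B", "C"])
        c = confusion(pred, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 2, 1)

    def test_counts_partition_all_pairs(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(9)]
        pairs = list(permutations(ids, 2))
        pick = lambda: {tuple(sorted(pairs[i])) for i in rng.choice(len(pairs), 12)}
        c = confusion(Skeleton(ids, pick()), Skeleton(ids, pick()))
        assert c.total == 9 * 8 // 2

    def test_direction_collapsed(self, tmp_path):
        """A reversed duplicate edge list scores identically."""
        ids = ["A", "B", "C"]
        fwd = tmp_path / "f.tsv"
        fwd.write_text("A\tB\t1\nB\tC\t1\n")
        rev = tmp_path / "r.tsv"
        rev.write_text("B\tA\t1\nC\tB\t1\nA\tB\t1\n")
        gold = Skeleton(ids, [("A", "B")])
        a = confusion(oipcq.read_gold_standard(fwd, ids), gold)
        b = confusion(oipcq.read_gold_standard(rev, ids), gold)
        assert a == b

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gene set"):
            confusion(Skeleton(["A", "B"]), Skeleton(["A", "C"]))


class TestMetrics:
    def test_ten_gene_benchmark_rows(self):
        """The two 10-gene rows derivable from (TP, FP) and the network size
        (10 genes, 10 gold edges): the quantile algorithm's row and the
        classical baseline's row."""
        m = metrics(ConfusionCounts(tp=9, fp=0, tn=35, fn=1))
        assert m.ppv == 1.0
        assert m.tpr == pytest.approx(0.9)
        assert m.acc == pytest.approx(0.97778, abs=5e-6)
        assert m.f_measure == pytest.approx(0.94737, abs=5e-6)
        assert m.fpr == 0.0 and m.fdr == 0.0
        assert m.mcc == pytest.approx(0.93541, abs=5e-6)

        m = metrics(ConfusionCounts(tp=9, fp=1, tn=34, fn=1))
        assert m.acc == pytest.approx(0.95556, abs=5e-6)
        assert m.fpr == pytest.approx(0.02857, abs=5e-6)
        assert m.mcc == pytest.approx(0.87143, abs=5e-6)

    def test_perfect_prediction_metrics(self):
        m = metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert (m.tpr, m.ppv, m.acc, m.f_measure, m.mcc) == (1, 1, 1, 1, 1)
        assert (m.fpr, m.fdr) == (0, 0)

    def test_degenerate_counts_use_zero_conventions(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert m.ppv == 0.0 and m.f_measure == 0.0 and m.mcc == 0.0

    def test_mcc_uses_square_rooted_denominator(self):
        # 305/sqrt(...) - the unrooted denominator would give a value ~1e-3
        m = metrics(ConfusionCounts(tp=9, fp=1, tn=34, fn=1))
        den = (9 + 1) * (9 + 1) * (34 + 1) * (34 + 1)
        assert m.mcc == pytest.approx((9 * 34 - 1 * 1) / np.sqrt(den), abs=1e-12)


class TestRocAuc:
    def _data(self):
        m = oipcq.random_model(8, 2.0, seed=40)
        e = oipcq.sample(m, 150, seed=41)
        return e, oipcq.gold_skeleton(m)

    def test_oracle_method_has_auc_one(self):
        e, gold = self._data()
        curve = roc_auc(e, gold, lambda expr, theta: gold, [0.01, 0.05, 0.1])
        assert curve.auc == pytest.approx(1.0)

    def test_complete_graph_method_is_chance(self):
        e, gold = self._data()
        curve = roc_auc(
            e, gold, lambda expr, theta: complete_skeleton(expr.gene_ids),
            [0.01, 0.05],
        )
        assert curve.auc == pytest.approx(0.5)

    def test_single_theta_curve(self):
        e, gold = self._data()
        curve = roc_auc(e, gold, make_method("oipcq"), [0.05])
        assert len(curve.points) >= 2
        assert 0.0 <= curve.auc <= 1.0
        fprs = [p[0] for p in curve.points]
        assert fprs == sorted(fprs)
        assert (0.0, 0.0) in curve.points and (1.0, 1.0) in curve.points

    def test_duplicate_grid_points_do_not_change_auc(self):
        e, gold = self._data()
        a = roc_auc(e, gold, make_method("oipcq"), [0.02, 0.08])
        b = roc_auc(e, gold, make_method("oipcq"), [0.02, 0.02, 0.08, 0.08])
        assert a.auc == b.auc

    def test_empty_grid_rejected(self):
        e, gold = self._data()
        with pytest.raises(ValueError):
            roc_auc(e, gold, make_method("oipcq"), [])


class TestPermutationStudy:
    def test_order_independent_control_is_constant(self):
        m = oipcq.random_model(10, 2.0, seed=50)
        e = oipcq.sample(m, 200, seed=51)
        gold = oipcq.gold_skeleton(m)
        res = permutation_study(e, gold, "oipcq", n_perms=5, theta=0.05, seed=1)
        assert len(set(res.tp_fp)) == 1
        assert res.sd_tp == 0.0 and res.sd_fp == 0.0

    def test_single_perm_equals_direct_run(self):
        m = oipcq.random_model(6, 2.0, seed=52)
        e = oipcq.sample(m, 120, seed=53)
        gold = oipcq.gold_skeleton(m)
        perm = list(reversed(e.gene_ids))
        res = permutation_study(
            e, gold, "pca-cmi", n_perms=1, theta=0.05, seed=0,
            permutations=[perm],
        )
        direct = oipcq.pca_cmi(e, 0.05, gene_order=perm)
        c = confusion(direct, gold)
        assert res.tp_fp == ((c.tp, c.fp),)

    def test_exhaustive_crafted_dataset_shows_spread(self, order_sensitive_data):
        e, theta = order_sensitive_data
        m4 = oipcq.random_model(4, expected_degree=2.0, noise_sd=0.5, seed=0)
        gold = oipcq.gold_skeleton(m4)
        perms = [list(p) for p in permutations(e.gene_ids)]
        res = permutation_study(
            e, gold, "pca-cmi", n_perms=24, theta=theta, seed=0,
            permutations=perms,
        )
        assert res.n_distinct >= 2

    def test_sd_matches_two_pass_oracle(self):
        m = oipcq.random_model(8, 2.0, seed=54)
        e = oipcq.sample(m, 100, seed=55)
        gold = oipcq.gold_skeleton(m)
        res = permutation_study(e, gold, "pca-cmi", n_perms=10, theta=0.05, seed=2)
        tps = [t for t, _ in res.tp_fp]
        mean = sum(tps) / len(tps)
        var = sum((t - mean) ** 2 for t in tps) / len(tps)
        assert res.sd_tp == pytest.approx(var**0.5, abs=1e-12)


class TestThresholdSweep:
    def test_theta_insensitive_method_has_zero_sd(self):
        m = oipcq.random_model(6, 2.0, seed=60)
        e = oipcq.sample(m, 100, seed=61)
        gold = oipcq.gold_skeleton(m)
        sd_tp, sd_fp, seq = threshold_sd_study(
            e, gold, lambda expr, theta: gold, grid=[0.01, 0.05, 0.1]
        )
        assert sd_tp == 0.0 and sd_fp == 0.0
        assert len(seq) == 3

    def test_sd_matches_independent_recomputation(self):
        m = oipcq.random_model(8, 2.0, seed=62)
        e = oipcq.sample(m, 120, seed=63)
        gold = oipcq.gold_skeleton(m)
        grid = list(np.linspace(0.01, 0.3, 15))
        sd_tp, sd_fp, seq = threshold_sd_study(e, gold, make_method("oipcq"), grid=grid)
        tps = np.array([t for t, _ in seq], dtype=float)
        fps = np.array([f for _, f in seq], dtype=float)
        assert sd_tp == pytest.approx(tps.std(ddof=0), abs=1e-12)
        assert sd_fp == pytest.approx(fps.std(ddof=0), abs=1e-12)

    def test_quantile_sweep_calls_method_with_k(self):
        m = oipcq.random_model(6, 2.0, seed=64)
        e = oipcq.sample(m, 100, seed=65)
        gold = oipcq.gold_skeleton(m)
        seen = []

        def fn(expr, k):
            seen.append(k)
            return make_method("oipcq", quantile_k=k)(expr, 0.05)

        threshold_sd_study(e, gold, fn, grid=[50.0, 70.0, 90.0], sweep="quantile")
        assert seen == [50.0, 70.0, 90.0]


class TestSubsampleStability:
    def _setup(self):
        m = oipcq.random_model(8, 2.0, seed=70)
        e = oipcq.sample(m, 100, seed=71)
        return e, oipcq.gold_skeleton(m)

    def test_single_rep_warns_and_returns_zero(self):
        e, gold = self._setup()
        method = lambda expr: make_method("oipcq")(expr, 0.05)
        with pytest.warns(UserWarning, match="single replicate"):
            sd, fs = subsample_stability(e, gold, method, reps=1, seed=0)
        assert sd == 0.0 and len(fs) == 1

    def test_sd_agrees_with_stored_f_list(self):
        e, gold = self._setup()
        method = lambda expr: make_method("oipcq")(expr, 0.05)
        sd, fs = subsample_stability(e, gold, method, reps=15, seed=3)
        assert sd == pytest.approx(np.array(fs).std(ddof=1), abs=1e-12)

    def test_too_few_remaining_samples_rejected(self):
        m = oipcq.random_model(4, 2.0, seed=72)
        e = oipcq.sample(m, 5, seed=73)
        gold = oipcq.gold_skeleton(m)
        with pytest.raises(ValueError, match="remain"):
            subsample_stability(e, gold, lambda x: gold, drop_fraction=0.4, reps=2)

    def test_seeded_runs_reproduce(self):
        e, gold = self._setup()
        method = lambda expr: make_method("oipcq")(expr, 0.05)
        a = subsample_stability(e, gold, method, reps=5, seed=9)
        b = subsample_stability(e, gold, method, reps=5, seed=9)
        assert a == b
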