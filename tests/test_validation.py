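import numpy as np
import pytest

from ftirdx.errors import PlanError
from ftirdx.qda import ShrinkageQDA, make_pca_qda
from ftirdx.validation import (ConfusionMatrix, MonteCarloPlan,
                               bootstrap_misclassification, figures_of_merit,
                               fscore, make_splits, mann_whitney_bands,
                               run_mccv, _largest_remainder_rows)

PAPER_CLASSES = ("normal", "inflammatory", "barretts", "lgd", "hgd", "oac")
PAPER_SIZES = (35, 13, 26, 4, 9, 22)


class TestSplits:
    def test_per_class_holdout_counts_for_study_sizes(self):
        y = np.repeat(PAPER_CLASSES, PAPER_SIZES)
        plan = MonteCarloPlan(iterations=5, seed=0)
        for tr, va in make_splits(y, plan):
            held = {c: int(np.sum(y[va] == c)) for c in PAPER_CLASSES}
            assert held == dict(zip(PAPER_CLASSES, (7, 3, 5, 1, 2, 4)))
            assert np.intersect1d(tr, va).size == 0
            assert np.union1d(tr, va).size == y.size

    def test_same_seed_reproduces_the_split_sequence(self):
        y = np.repeat(["a", "b"], 10)
        p = MonteCarloPlan(iterations=4, seed=7)
        s1 = make_splits(y, p)
        s2 = make_splits(y, p)
        for (t1, v1), (t2, v2) in zip(s1, s2):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2)

    def test_vanishing_fraction_is_a_plan_error(self):
        y = np.repeat(["a", "b"], 10)
        with pytest.raises(PlanError, match="empty validation"):
            make_splits(y, MonteCarloPlan(hold_out_fraction=0.001, iterations=1))

    def test_singleton_class_is_a_plan_error(self):
        y = np.array(["a", "a", "b"])
        with pytest.raises(PlanError, match="single"):
            make_splits(y, MonteCarloPlan(iterations=1))


class TestFiguresOfMerit:
    def test_printed_confusion_rows_reproduce_sensitivities(self):
        """A 25/10 normal->inflammatory split of 35 specimens gives 71.4%
        normal sensitivity; a 10/25 split gives 28.6%."""
        pca_counts = np.diag(PAPER_SIZES).astype(float)
        pca_counts[0, 0], pca_counts[0, 1] = 25, 10
        fom = figures_of_merit(ConfusionMatrix(PAPER_CLASSES, pca_counts))
        assert round(fom.sensitivity[0], 1) == 71.4
        # 86 true negatives of 96 -> 89.58%; printed as 89.5 (one-decimal)
        assert abs(fom.specificity[1] - 89.5) <= 0.1
        ga_counts = np.diag(PAPER_SIZES).astype(float)
        ga_counts[0, 0], ga_counts[0, 1] = 10, 25
        ga_counts[1, 0], ga_counts[1, 1] = 13, 0
        fom = figures_of_merit(ConfusionMatrix(PAPER_CLASSES, ga_counts))
        assert round(fom.sensitivity[0], 1) == 28.6
        assert round(fom.sensitivity[1], 1) == 0.0

    @pytest.mark.parametrize("sens,spec,expected", [
        (71.4, 100.0, 83.3),
        (100.0, 89.5, 94.5),
        (100.0, 80.0, 88.9),
        (28.6, 80.0, 42.1),
    ])
    def test_fscore_worked_examples(self, sens, spec, expected):
        assert round(fscore(sens, spec), 1) == expected

    def test_fscore_endpoints_and_idempotence(self):
        assert fscore(100.0, 100.0) == 100.0
        assert fscore(0.0, 80.0) == 0.0
        assert fscore(0.0, 0.0) == 0.0
        for s in (12.5, 50.0, 99.9):
            assert np.isclose(fscore(s, s), s)

    def test_identity_permutation_scores_100(self):
        cm = ConfusionMatrix(("a", "b", "c"), np.diag([5, 3, 2]).astype(float))
        fom = figures_of_merit(cm)
        assert np.allclose(fom.sensitivity, 100.0)
        assert np.allclose(fom.specificity, 100.0)
        assert fom.accuracy == 100.0

    def test_empty_denominators_are_undefined_not_zero(self):
        counts = np.array([[3.0, 0.0], [0.0, 0.0]])
        fom = figures_of_merit(ConfusionMatrix(("a", "b"), counts))
        assert np.isnan(fom.sensitivity[1])  # class b never evaluated


class TestLargestRemainder:
    def test_row_sums_conserved_exactly(self):
        rng = np.random.default_rng(0)
        counts = rng.random((4, 4)) * 100
        targets = np.array([35, 13, 4, 22])
        out = _largest_remainder_rows(counts, targets)
        assert np.array_equal(out.sum(axis=1), targets)
        assert np.issubdtype(out.dtype, np.integer)

    def test_proportions_preserved_for_exact_ratios(self):
        counts = np.array([[750.0, 250.0]])
        out = _largest_remainder_rows(counts, np.array([4]))
        assert out.tolist() == [[3, 1]]


class TestMCCV:
    def test_perfectly_separated_classes_give_identity_matrix(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(c, 0.05, size=(12, 3))
                       for c in (0.0, 5.0, 10.0)])
        y = np.repeat(["a", "b", "c"], 12)
        res = run_mccv(X, y, ShrinkageQDA(), MonteCarloPlan(iterations=20, seed=2))
        assert np.array_equal(res.confusion.counts, np.diag([12, 12, 12]))
        assert res.fom_mean.accuracy == 100.0
        assert np.allclose(res.fom_mean.sensitivity, 100.0)

    def test_single_iteration_equals_one_stratified_holdout(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(c, 1.0, size=(10, 2)) for c in (0.0, 4.0)])
        y = np.repeat(["a", "b"], 10)
        plan = MonteCarloPlan(iterations=1, seed=4)
        res = run_mccv(X, y, ShrinkageQDA(), plan)
        tr, va = make_splits(y, plan)[0]
        est = ShrinkageQDA().fit(X[tr], y[tr])
        pred = est.predict(X[va])
        manual = np.zeros((2, 2))
        for t, p in zip(y[va], pred):
            manual[int(t == "b"), int(p == "b")] += 1
        assert np.array_equal(res.raw_counts, manual)

    def test_seed_invariance_of_fom_means_within_monte_carlo_error(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(c, 1.5, size=(15, 2)) for c in (0.0, 3.0)])
        y = np.repeat(["a", "b"], 15)
        accs = []
        for seed in (10, 11):
            res = run_mccv(X, y, ShrinkageQDA(),
                           MonteCarloPlan(iterations=150, seed=seed))
            accs.append((res.fom_mean.accuracy,
                         res.fom_std.accuracy / np.sqrt(res.n_iterations)))
        (a1, se1), (a2, se2) = accs
        assert abs(a1 - a2) <= 2.0 * np.hypot(se1, se2) + 1e-9

    def test_selection_once_mode_runs_head_once(self, specimens_default):
        sp, _ = specimens_default
        res = run_mccv(sp.absorbance, sp.class_label, make_pca_qda(),
                       MonteCarloPlan(iterations=5, seed=6),
                       selection_once=True)
        assert res.n_failures == 0
        assert res.confusion.counts.sum() == 109


class TestBootstrap:
    def test_separable_classes_have_near_zero_probability(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(c, 0.1, size=(15, 2))
                       for c in (0.0, 10.0, 20.0)])  # 10 sigma apart and more
        y = np.repeat(["a", "b", "c"], 15)
        est = bootstrap_misclassification(X, y, ShrinkageQDA(), replicates=60,
                                          seed=8)
        assert est.probability < 0.02

    def test_permuted_labels_sit_at_chance_level(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(72, 3))
        y = rng.permutation(np.repeat([f"c{i}" for i in range(6)], 12))
        est = bootstrap_misclassification(X, y, ShrinkageQDA(), replicates=150,
                                          seed=10)
        assert abs(est.probability - 5.0 / 6.0) <= 0.05

    def test_same_seed_same_estimate(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(c, 1.0, size=(10, 2)) for c in (0.0, 3.0)])
        y = np.repeat(["a", "b"], 10)
        e1 = bootstrap_misclassification(X, y, ShrinkageQDA(), replicates=40,
                                         seed=12)
        e2 = bootstrap_misclassification(X, y, ShrinkageQDA(), replicates=40,
                                         seed=12)
        assert e1.probability == e2.probability


class TestMannWhitney:
    def _ds(self, xa, xb):
        from ftirdx.io import SpectralDataset
        wn = np.array([1700.0, 1200.0])
        vals = np.concatenate([xa, xb])
        absorb = np.column_stack([vals, vals])
        n = len(vals)
        labels = np.array(["normal"] * len(xa) + ["oac"] * len(xb), dtype=object)
        return SpectralDataset(wn, absorb,
                               np.array([f"s{i}" for i in range(n)], dtype=object),
                               np.ones(n, dtype=int), labels)

    def test_fully_separated_small_groups_exact_p(self):
        """{1,2,3} vs {10,11,12}: U = 0, exact two-sided p = 2/20 = 0.1."""
        ds = self._ds(np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0]))
        out = mann_whitney_bands(ds, [0], ("normal", "oac"))
        assert np.isclose(out["p_value"].iloc[0], 0.1)
        assert not out["significant"].iloc[0]

    def test_identical_constant_groups_flagged_with_p_one(self):
        ds = self._ds(np.ones(3), np.ones(3))
        out = mann_whitney_bands(ds, [0, 1], ("normal", "oac"))
        assert np.all(out["p_value"] == 1.0)
        assert np.all(out["degenerate"])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        xa, xb = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        p1 = mann_whitney_bands(self._ds(xa, xb), [0],
                                ("normal", "oac"))["p_value"].iloc[0]
        p2 = mann_whitney_bands(self._ds(np.exp(xa), np.exp(xb)), [0],
                                ("normal", "oac"))["p_value"].iloc[0]
        assert np.isclose(p1, p2, atol=1e-12)
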