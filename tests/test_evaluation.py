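"""Folds, grids, metrics, ROC, permutation machinery, t-maps, CV pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mklpet import evaluation as ev
from mklpet.volumes import Volume


class TestStratifiedKFold:
    def test_study_sized_folds(self):
        labels = np.array(["neg"] * 39 + ["pos"] * 48)  # 87 subjects
        assign = ev.stratified_kfold(labels, k=10, seed=0)
        sizes = np.bincount(assign)
        assert sorted(sizes) == [8, 8, 8, 9, 9, 9, 9, 9, 9, 9]
        for cls in ("neg", "pos"):
            per_fold = np.bincount(assign[labels == cls], minlength=10)
            assert per_fold.max() - per_fold.min() <= 1

    def test_leave_one_out(self):
        labels = ["a", "b"] * 5
        with pytest.warns(UserWarning, match="falling back"):
            assign = ev.stratified_kfold(labels, k=10, seed=1)
        assert sorted(np.bincount(assign)) == [1] * 10

    def test_seed_reproducibility(self):
        labels = ["a"] * 20 + ["b"] * 15
        a = ev.stratified_kfold(labels, k=5, seed=7)
        b = ev.stratified_kfold(labels, k=5, seed=7)
        c = ev.stratified_kfold(labels, k=5, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            ev.stratified_kfold(["a", "b"], k=3)


class TestSimplexGrid:
    def test_known_sizes(self):
        assert ev.enumerate_simplex_grid(2, 0.1).shape == (9, 2)
        assert ev.enumerate_simplex_grid(5, 0.1).shape == (126, 5)  # C(9, 4)

    def test_two_kernel_enumeration(self):
        Q = ev.enumerate_simplex_grid(2, 0.1)
        np.testing.assert_allclose(Q[0], [0.1, 0.9])
        np.testing.assert_allclose(Q[-1], [0.9, 0.1])

    def test_single_kernel(self):
        np.testing.assert_array_equal(ev.enumerate_simplex_grid(1, 0.1), [[1.0]])

    @settings(deadline=None, max_examples=20)
    @given(
        n_k=st.integers(1, 6),
        denom=st.sampled_from([2, 4, 5, 10]),
    )
    def test_sums_to_one_and_on_lattice(self, n_k, denom):
        step = 1.0 / denom
        if n_k > denom:
            with pytest.raises(ValueError):
                ev.enumerate_simplex_grid(n_k, step)
            return
        Q = ev.enumerate_simplex_grid(n_k, step)
        assert np.all(np.abs(Q.sum(axis=1) - 1.0) < 1e-12)
        assert np.all(Q >= step - 1e-12)
        # lexicographically sorted and unique
        as_tuples = [tuple(row) for row in np.round(Q * denom).astype(int)]
        assert as_tuples == sorted(set(as_tuples))


class TestMetrics:
    def test_counting_example(self):
        acc, sens, spec = ev.metrics(
            ["+", "+", "-", "-"], ["+", "-", "-", "-"], positive_class="+"
        )
        assert (acc, sens, spec) == (0.75, 0.5, 1.0)

    def test_study_confusion_consistency(self):
        # 48 positives with 37 detected, 39 negatives with 27 detected
        y_true = ["pos"] * 48 + ["neg"] * 39
        y_pred = ["pos"] * 37 + ["neg"] * 11 + ["neg"] * 27 + ["pos"] * 12
        acc, sens, spec = ev.metrics(y_true, y_pred, "pos")
        assert 100 * acc == pytest.approx(73.56, abs=0.005)
        assert 100 * sens == pytest.approx(77.08, abs=0.005)
        assert 100 * spec == pytest.approx(69.23, abs=0.005)

    def test_perfect(self):
        assert ev.metrics(["a", "b"], ["a", "b"], "a") == (1.0, 1.0, 1.0)

    def test_per_class_accuracy(self):
        out = ev.per_class_accuracy(["a", "a", "b", "c"], ["a", "b", "b", "b"])
        assert out == {"a": 0.5, "b": 1.0, "c": 0.0}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.metrics(["a", "a"], ["a", "a"], "a")


class TestGridSearch:
    def test_single_candidate(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([-1.0, 1.0] * 6)
        Ks = np.stack([X @ X.T])
        grid = ev.GridSpec(c_exponents=(0,), q_step=1.0, inner_folds=3)
        C, q, _ = ev.grid_search_kernels(Ks, y, grid)
        assert C == 1.0
        np.testing.assert_array_equal(q, [1.0])

    def test_informative_block_gets_weight(self):
        """A small informative region must out-weight a large, brighter but
        uninformative one in >= 80% of 20 replicates."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            n = 20
            y = np.array([-1.0, 1.0] * (n // 2))
            X_good = y[:, None] * 1.0 + rng.normal(size=(n, 2))
            X_noise = 3.0 * rng.normal(size=(n, 50))
            Ks = np.stack([X_good @ X_good.T, X_noise @ X_noise.T])
            grid = ev.GridSpec(c_exponents=(-3, -1, 1), q_step=0.1, inner_folds=5)
            _, q, _ = ev.grid_search_kernels(Ks, y, grid, seed=rep)
            hits += q[0] >= 0.5
        assert hits >= 16

    def test_tie_rule_smallest_c_then_lex_q(self, rng):
        # all-zero kernels: every candidate ties -> smallest C, lex-smallest q
        Ks = np.zeros((2, 10, 10))
        y = np.array([-1.0, 1.0] * 5)
        grid = ev.GridSpec(c_exponents=(2, -1, 0), q_step=0.5, inner_folds=2)
        C, q, _ = ev.grid_search_kernels(Ks, y, grid)
        assert C == 0.5
        np.testing.assert_allclose(q, [0.5, 0.5])


class TestPermutationTest:
    def test_boundary_p_values(self):
        calls = {"n": 0}

        def fn(labels, seed):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else 0.5  # observed beats all nulls

        res = ev.permutation_test(fn, ["a", "b"] * 5, n_perm=20, seed=0)
        assert res.p_value == 0.0
        calls["n"] = 0

        def fn_low(labels, seed):
            calls["n"] += 1
            return 0.1 if calls["n"] == 1 else 0.5  # every null >= observed

        res = ev.permutation_test(fn_low, ["a", "b"] * 5, n_perm=20, seed=0)
        assert res.p_value == 1.0

    def test_plus_one_correction(self):
        calls = {"n": 0}

        def fn(labels, seed):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else 0.0

        res = ev.permutation_test(fn, ["a", "b"], n_perm=19, seed=0, plus_one=True)
        assert res.p_value == pytest.approx(1 / 20)

    def test_null_length_and_validation(self):
        res = ev.permutation_test(lambda l, s: 0.5, ["a", "b"], n_perm=7, seed=1)
        assert res.null.shape == (7,)
        with pytest.raises(ValueError):
            ev.permutation_test(lambda l, s: 0.5, ["a", "b"], n_perm=0)


class TestROC:
    def test_toy_cases(self):
        labels = ["n", "n", "p", "p"]
        assert ev.roc_curve([0.1, 0.2, 0.8, 0.9], labels, "p").auc == 1.0
        assert ev.roc_curve([0.9, 0.8, 0.2, 0.1], labels, "p").auc == 0.0
        assert ev.roc_curve([0.5, 0.5, 0.5, 0.5], labels, "p").auc == 0.5

    def test_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=40)
        labels = rng.choice(["p", "n"], size=40)
        labels[:2] = ["p", "n"]
        curve = ev.roc_curve(scores, labels, "p")
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_auc_equals_pairwise_count(self, rng):
        # ties counted one half, n <= 50, with deliberate score ties
        scores = np.round(rng.normal(size=50), 1)
        labels = np.array(["p"] * 20 + ["n"] * 30)
        rng.shuffle(labels)
        auc = ev.roc_curve(scores, labels, "p").auc
        pos = scores[labels == "p"]
        neg = scores[labels == "n"]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_curve([0.1, 0.2], ["p", "p"], "p")


class TestVoxelwiseTTest:
    def _vols(self, arrays, vox=2.0):
        aff = np.diag([vox, vox, vox, 1.0])
        return [Volume(np.asarray(a, dtype=float), aff) for a in arrays]

    def test_identical_groups(self, rng):
        base = rng.random((5, 5, 5))
        A = self._vols([base.copy() for _ in range(3)])
        # groups share identical members -> t = 0 everywhere, no clusters
        tm = ev.voxelwise_ttest(A, A)
        np.testing.assert_array_equal(tm.t.data, 0.0)
        assert len(tm.clusters) == 0
        # exactly constant volumes are flagged as zero-variance
        C = self._vols([np.full((4, 4, 4), 2.0) for _ in range(3)])
        assert ev.voxelwise_ttest(C, C).zero_variance.all()

    def test_hand_computed_pooled_t(self):
        A = self._vols([np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)])
        B = self._vols([np.full((2, 2, 2), v) for v in (3.0, 4.0, 5.0)])
        tm = ev.voxelwise_ttest(A, B)
        assert tm.df == 4
        np.testing.assert_allclose(tm.t.data, -2.449, atol=5e-4)

    def test_matches_scipy_oracle(self, rng):
        from scipy import stats

        A = self._vols(rng.normal(size=(4, 3, 3, 3)))
        B = self._vols(rng.normal(size=(5, 3, 3, 3)))
        tm = ev.voxelwise_ttest(A, B)
        ref = stats.ttest_ind(
            np.stack([v.data for v in A]), np.stack([v.data for v in B]), axis=0
        )
        np.testing.assert_allclose(tm.t.data, ref.statistic, atol=1e-10)

    def test_cluster_volume_and_26_connectivity(self, rng):
        # two voxels touching only diagonally must form one 26-connected cluster
        noise = rng.normal(scale=1e-3, size=(8, 8, 8))
        A = self._vols([noise + 0.0, noise + 1e-3, noise + 2e-3, noise - 1e-3])
        shift = np.zeros((8, 8, 8))
        shift[3, 3, 3] = 5.0
        shift[4, 4, 4] = 5.0
        B = self._vols([noise + shift, noise + shift + 1e-3,
                        noise + shift + 2e-3, noise + shift - 1e-3])
        tm = ev.voxelwise_ttest(A, B, p_thresh=0.001)
        neg = tm.clusters[tm.clusters["sign"] == "-"]
        assert len(neg) == 1
        assert neg.iloc[0]["n_voxels"] == 2
        assert neg.iloc[0]["volume_mm3"] == pytest.approx(2 * 8.0)

    def test_grid_mismatch_and_small_groups(self):
        A = self._vols([np.zeros((3, 3, 3))] * 2)
        B = self._vols([np.zeros((4, 3, 3))] * 2)
        with pytest.raises(ValueError):
            ev.voxelwise_ttest(A, B)
        with pytest.raises(ValueError):
            ev.voxelwise_ttest(A[:1], A)


@pytest.fixture(scope="module")
def report(strong_cohort_small, strong_atlas):
    opts = ev.EvalOptions(
        mode="binary", k=4, seed=2,
        grid=ev.GridSpec(c_exponents=(-2, 0, 2), q_step=0.2, inner_folds=3),
        top_regions=3,
    )
    return ev.run_cv_pipeline(strong_cohort_small, strong_atlas, opts)


class TestCVPipeline:
    def test_every_subject_tested_exactly_once(self, report, strong_cohort_small):
        ids = report.subject_ids
        assert sorted(ids) == sorted(s.id for s in strong_cohort_small)

    def test_aggregate_matches_stored_folds(self, report):
        y_true = np.asarray(report.y_true)
        y_pred = np.asarray(report.y_pred)
        assert report.accuracy == pytest.approx(float(np.mean(y_true == y_pred)))
        acc, sens, spec = report.binary_metrics()
        assert acc == report.accuracy

    def test_fold_records_complete(self, report):
        for fold in report.folds:
            assert len(fold.selected_regions) == 3
            assert fold.C > 0
            assert abs(sum(fold.q) - 1.0) < 1e-9
            assert len(fold.decision) == len(fold.test_ids)

    def test_json_round_trip(self, report, tmp_path):
        import json

        report.to_json(tmp_path / "r.json")
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["accuracy"] == pytest.approx(report.accuracy)
        assert len(back["folds"]) == 4

    def test_deterministic_given_seed(self, strong_cohort_small, strong_atlas):
        opts = ev.EvalOptions(
            mode="binary", k=3, seed=9,
            grid=ev.GridSpec(c_exponents=(0,), q_step=0.5, inner_folds=2),
            top_regions=2,
        )
        a = ev.run_cv_pipeline(strong_cohort_small, strong_atlas, opts)
        b = ev.run_cv_pipeline(strong_cohort_small, strong_atlas, opts)
        assert a.to_dict() == b.to_dict()

    def test_label_override_changes_only_labels(self, strong_cohort_small, strong_atlas):
        """The permutation closure must keep features fixed across calls."""
        opts = ev.EvalOptions(
            mode="binary", k=3, seed=4,
            grid=ev.GridSpec(c_exponents=(0,), q_step=0.5, inner_folds=2),
            top_regions=2,
        )
        fn = ev.cv_accuracy_closure(strong_cohort_small, strong_atlas, opts)
        labels = [s.diagnosis for s in strong_cohort_small]
        direct = ev.run_cv_pipeline(strong_cohort_small, strong_atlas, opts).accuracy
        assert fn(labels, 0) == pytest.approx(direct)

    def test_multiclass_report(self, strong_cohort_small, strong_atlas):
        opts = ev.EvalOptions(
            mode="multiclass", k=3, seed=5,
            grid=ev.GridSpec(c_exponents=(0,), q_step=0.5, inner_folds=2),
            top_regions=2,
        )
        rep = ev.run_cv_pipeline(strong_cohort_small, strong_atlas, opts)
        accs = rep.class_accuracies()
        assert set(accs) == {"PD", "MSA", "PSP"}
        assert rep.positive_class is None
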