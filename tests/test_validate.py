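"""NRMSE, split plans, grid search contracts, aggregation, t-test."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import omgkit as omg
from omgkit.validate import grid_search, make_split_plan


class TestNrmse:
    def test_perfect_prediction_is_zero(self):
        y = np.array([0.0, 0.5, 1.0])
        assert omg.nrmse(y, y) == 0.0

    def test_equals_rmse_for_unit_range(self):
        y = np.array([0.0, 1.0, 0.2, 0.8])
        y_hat = y + 0.1
        assert omg.nrmse(y_hat, y) == pytest.approx(0.1, abs=1e-12)

    def test_closed_form_example(self):
        assert omg.nrmse(np.array([0.5, 0.5]), np.array([0.0, 1.0])) == 0.5

    @given(
        c=st.floats(0.1, 100),
        seed=st.integers(0, 1000),
    )
    def test_scale_consistency(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 1, 20)
        y_hat = y + rng.normal(0, 0.2, 20)
        base = omg.nrmse(y_hat, y, 1.0)
        scaled = omg.nrmse(c * y_hat, c * y, c * 1.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            omg.nrmse(np.array([]), np.array([]))


def _default_mask(n_dofs=1, repetitions=1):
    cfg = omg.ProtocolConfig(
        dof_names=tuple(f"d{i}" for i in range(n_dofs)), repetitions=repetitions
    )
    stim = omg.generate_stimulus(cfg)
    return omg.onoff_mask(stim), stim


class TestSplitPlans:
    def test_scheme1_partitions_all_frames(self):
        plan = make_split_plan(1, T=100, seed=0)
        assert plan.n_folds == 10
        all_test = np.concatenate([test for _, test in plan.folds])
        assert np.array_equal(np.sort(all_test), np.arange(100))
        for train, test in plan.folds:
            assert test.size == 10
            assert np.intersect1d(train, test).size == 0
            assert np.array_equal(np.sort(np.concatenate([train, test])),
                                  np.arange(100))

    def test_scheme2_folds_live_on_plateau_frames(self):
        mask, stim = _default_mask()
        plan = make_split_plan(2, stim.n_frames, mask, dof=0, seed=1)
        plateau = np.flatnonzero(mask.is_plateau[:, 0])
        all_test = np.concatenate([test for _, test in plan.folds])
        assert np.array_equal(np.sort(all_test), plateau)
        sizes = [t.size for _, t in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        for train, test in plan.folds:
            assert np.intersect1d(train, test).size == 0
            assert np.all(mask.is_plateau[train, 0])

    def test_scheme3_single_split_covers_all_frames(self):
        mask, stim = _default_mask()
        plan = make_split_plan(3, stim.n_frames, mask, dof=0)
        assert plan.n_folds == 1
        train, test = plan.folds[0]
        assert np.intersect1d(train, test).size == 0
        assert np.array_equal(np.sort(np.concatenate([train, test])),
                              np.arange(stim.n_frames))
        assert train.size == 90 and test.size == 30  # closed-form counts

    def test_scheme4_contiguous_equal_folds(self):
        plan = make_split_plan(4, T=10)
        tests = [list(t) for _, t in plan.folds]
        assert tests == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]
        for train, test in plan.folds:
            assert np.all(np.diff(test) == 1)  # contiguous
            assert np.intersect1d(train, test).size == 0

    def test_scheme5_trains_on_plateau_of_other_folds(self):
        mask, stim = _default_mask(repetitions=5)
        plan = make_split_plan(5, stim.n_frames, mask, dof=0, seed=0)
        assert plan.n_folds == 5
        all_test = np.concatenate([t for _, t in plan.folds])
        assert np.array_equal(np.sort(all_test), np.arange(stim.n_frames))
        for train, test in plan.folds:
            assert np.all(mask.is_plateau[train, 0])
            assert np.intersect1d(train, test).size == 0
            assert np.all(np.diff(test) == 1)

    def test_missing_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            make_split_plan(2, T=100)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(6, T=100)


class TestGridSearch:
    def test_rrff_grid_has_hundred_pairs(self):
        grid = omg.GridSpec()
        assert len(grid.lambdas) == 10
        assert len(grid.sigmas) == 10
        assert grid.n_pairs == 100

    def test_fit_count_contracts(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 5))
        y = rng.uniform(0, 1, 100)
        plan5 = make_split_plan(4, 100)
        plan10 = make_split_plan(1, 100, seed=0)
        assert grid_search(X, y, plan5, "rr").n_fits == 50
        assert grid_search(X, y, plan10, "rr").n_fits == 100
        assert grid_search(X, y, plan5, "rrff", D=50).n_fits == 500
        assert grid_search(X, y, plan10, "rrff", D=50).n_fits == 1000

    def test_scheme3_single_evaluation_per_grid_point(self):
        mask, stim = _default_mask()
        rng = np.random.default_rng(1)
        X = rng.standard_normal((stim.n_frames, 4))
        plan = make_split_plan(3, stim.n_frames, mask, dof=0)
        assert grid_search(X, stim.values[:, 0], plan, "rr").n_fits == 10

    def test_single_point_grid_returns_it(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 3))
        y = rng.uniform(0, 1, 50)
        grid = omg.GridSpec(lambdas=(0.5,), sigmas=(1.0,))
        res = grid_search(X, y, make_split_plan(4, 50), "rr", grid)
        assert res.lam == 0.5 and res.sigma is None
        assert res.fold_nrmse.shape == (5,)
        assert res.mean_nrmse == pytest.approx(res.fold_nrmse.mean())

    def test_selected_point_is_argmin_of_error_surface(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 4))
        y = (X @ rng.standard_normal(4)) * 0.1 + 0.5
        res = grid_search(X, y, make_split_plan(1, 80, seed=0), "rr")
        assert res.mean_nrmse == pytest.approx(np.min(res.errors))


class TestAggregate:
    def _report(self, value, subject):
        rep = omg.ValidationReport(subject=subject)
        rep.rows.append(
            omg.SchemeResult(
                scheme=1, method="rr", dof="index_flexion", lam=0.1,
                sigma=None, fold_nrmse=np.array([value]), mean_nrmse=value,
                n_fits=10,
            )
        )
        return rep

    def test_identical_subjects_have_zero_spread(self):
        agg = omg.aggregate([self._report(0.2, "a"), self._report(0.2, "b")])
        assert agg["sd"].iloc[0] == 0.0 and agg["sem"].iloc[0] == 0.0

    def test_two_subject_hand_arithmetic(self):
        agg = omg.aggregate([self._report(0.1, "a"), self._report(0.3, "b")])
        assert agg["mean"].iloc[0] == pytest.approx(0.2)
        assert agg["sd"].iloc[0] == pytest.approx(0.14142135, abs=1e-6)
        assert agg["sem"].iloc[0] == pytest.approx(0.1, abs=1e-9)

    def test_sem_definition_for_ten_subjects(self):
        reps = [self._report(0.1 + 0.01 * i, f"s{i}") for i in range(10)]
        agg = omg.aggregate(reps)
        assert agg["sem"].iloc[0] == pytest.approx(
            agg["sd"].iloc[0] / np.sqrt(10)
        )

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            omg.aggregate([self._report(0.1, "a")])


class TestTTest:
    def test_identical_samples_give_p_one(self):
        t, p = omg.ttest_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_samples_significant(self):
        _, p = omg.ttest_two_tailed([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01

    def test_matches_textbook_pooled_formula(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.15, 0.25, 0.35])
        t, p = omg.ttest_two_tailed(a, b)
        # independent pooled-variance computation
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_degenerate_equal_constants_convention(self):
        t, p = omg.ttest_two_tailed([0.5, 0.5], [0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            omg.ttest_two_tailed([1.0], [1.0, 2.0])
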