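"""Closed-form ridge and random-Fourier-feature ridge regression."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import omgkit as omg
from omgkit.regress import draw_rff


class TestFitRR:
    def test_identity_design_unregularized(self):
        # 2x2 identity, no intercept contribution needed: w -> (1, 0)
        model = omg.fit_rr(np.eye(2), np.array([1.0, 0.0]), lam=1e-12)
        y_hat = omg.predict(model, np.eye(2))
        np.testing.assert_allclose(y_hat, [1.0, 0.0], atol=1e-6)

    def test_heavy_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        model = omg.fit_rr(X, y, lam=1e6)
        assert np.linalg.norm(model.w) < 1e-3

    def test_matches_independent_dense_solver(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 1.0, 2.0])
        lam = 0.1
        model = omg.fit_rr(X, y, lam)
        Xa = np.hstack([X, np.ones((3, 1))])
        w_oracle = np.linalg.solve(Xa.T @ Xa + lam * np.eye(3), Xa.T @ y)
        assert np.max(np.abs(model.w - w_oracle)) < 1e-10

    def test_normal_equation_residual_contract(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 7))
        y = rng.standard_normal(80)
        for lam in (1e-6, 1e-2, 1.0):
            model = omg.fit_rr(X, y, lam)
            Xa = np.hstack([X, np.ones((80, 1))])
            resid = Xa.T @ (Xa @ model.w) + lam * model.w - Xa.T @ y
            assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(Xa.T @ y)

    def test_unregularized_residual_matches_qr_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        model = omg.fit_rr(X, y, lam=0.0)
        Xa = np.hstack([X, np.ones((40, 1))])
        q, r = np.linalg.qr(Xa)
        w_qr = np.linalg.solve(r, q.T @ y)
        res_model = np.linalg.norm(y - omg.predict(model, X))
        res_qr = np.linalg.norm(y - Xa @ w_qr)
        assert res_model == pytest.approx(res_qr, abs=1e-10)

    def test_singular_unregularized_system_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="lambda"):
            omg.fit_rr(X, np.ones(5), lam=0.0)

    def test_weight_norm_decreases_with_lambda(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 6))
        y = X @ rng.standard_normal(6) + 0.1 * rng.standard_normal(60)
        norms = [
            np.linalg.norm(omg.fit_rr(X, y, lam).w)
            for lam in (1e-4, 1e-2, 1.0, 1e2)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        perm = rng.permutation(5)
        m = omg.fit_rr(X, y, 0.5)
        mp = omg.fit_rr(X[:, perm], y, 0.5)
        np.testing.assert_allclose(m.w[:-1][perm], mp.w[:-1], atol=1e-10)
        np.testing.assert_allclose(
            omg.predict(m, X), omg.predict(mp, X[:, perm]), atol=1e-10
        )

    def test_dual_and_primal_routes_agree(self):
        # more features than samples exercises the dual identity
        rng = np.random.default_rng(5)
        Xw = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        lam = 0.3
        model = omg.fit_rr(Xw, y, lam)
        Xa = np.hstack([Xw, np.ones((20, 1))])
        w_oracle = np.linalg.solve(Xa.T @ Xa + lam * np.eye(51), Xa.T @ y)
        np.testing.assert_allclose(model.w, w_oracle, atol=1e-8)


class TestRffMap:
    def test_zero_input_zero_phase(self):
        D = 8
        phi = omg.rff_map(np.zeros((1, 3)), np.zeros((3, D)), np.zeros(D), D)
        np.testing.assert_allclose(phi, np.sqrt(2.0 / D))

    @given(st.integers(0, 2**32 - 1))
    def test_entries_bounded_by_scale(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((5, 3)) * 10
        Omega, beta = draw_rff(3, 16, sigma=2.0, seed=seed)
        phi = omg.rff_map(X, Omega, beta, 16)
        assert np.all(np.abs(phi) <= np.sqrt(2.0 / 16) + 1e-15)

    def test_scalar_case(self):
        phi = omg.rff_map(np.array([[np.pi]]), np.array([[1.0]]), np.array([0.0]), 1)
        assert phi[0, 0] == pytest.approx(-np.sqrt(2.0), abs=1e-12)


class TestFitRRFF:
    def test_tiny_bandwidth_predicts_mean(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 4))
        y = rng.uniform(0, 1, 50)
        model = omg.fit_rrff(X, y, lam=1e-6, sigma=1e-6, D=100, seed=0)
        np.testing.assert_allclose(
            omg.predict(model, X), np.full(50, y.mean()), atol=1e-3
        )

    def test_seeded_determinism_and_composition(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        a = omg.fit_rrff(X, y, lam=0.1, sigma=1.0, D=50, seed=5)
        b = omg.fit_rrff(X, y, lam=0.1, sigma=1.0, D=50, seed=5)
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.Omega, b.Omega)
        # fitting plain ridge on the explicit map gives the same model
        phi = omg.rff_map(X, a.Omega, a.beta_phase, 50)
        c = omg.fit_rr(phi, y, 0.1)
        np.testing.assert_allclose(a.w, c.w, atol=1e-12)
        np.testing.assert_allclose(
            omg.predict(a, X), omg.predict(c, phi), atol=1e-12
        )

    def test_invalid_hyperparameters_rejected(self):
        X, y = np.eye(3), np.ones(3)
        with pytest.raises(ValueError):
            omg.fit_rrff(X, y, lam=0.1, sigma=0.0, D=10, seed=0)
        with pytest.raises(ValueError):
            omg.fit_rrff(X, y, lam=0.1, sigma=1.0, D=0, seed=0)


class TestPredict:
    def test_zero_weights_zero_output(self):
        model = omg.RRModel(w=np.zeros(4), lam=1.0)
        np.testing.assert_array_equal(
            omg.predict(model, np.ones((5, 3))), np.zeros(5)
        )

    def test_dimension_mismatch_rejected(self):
        model = omg.RRModel(w=np.zeros(4), lam=1.0)
        with pytest.raises(ValueError, match="dimension"):
            omg.predict(model, np.ones((5, 7)))

    def test_clip_flag_bounds_output(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 2)) * 5
        model = omg.fit_rr(X, rng.uniform(0, 1, 20), 1e-6)
        y = omg.predict(model, X * 10, clip=True)
        assert y.min() >= 0.0 and y.max() <= 1.0


class TestSerialization:
    def test_rr_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20, 3))
        model = omg.fit_rr(X, rng.standard_normal(20), 0.2)
        omg.save_model(tmp_path / "m.json", model)
        back = omg.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.w, model.w, rtol=1e-15)
        assert back.lam == model.lam

    def test_rff_round_trip_regenerates_map_from_seed(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((25, 3))
        model = omg.fit_rrff(X, rng.standard_normal(25), 0.1, 1.5, D=40, seed=3)
        omg.save_model(tmp_path / "m.json", model)
        back = omg.load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(back.Omega, model.Omega)
        np.testing.assert_allclose(
            omg.predict(back, X), omg.predict(model, X), atol=1e-12
        )
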