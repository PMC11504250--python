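import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from nicheshift import (
    EnvStack,
    FeatureCombo,
    make_env_stack,
    predict_logistic,
    predict_raw,
    read_model,
    sample_background,
    train_maxent,
    write_model,
)
from nicheshift.maxent import fit_maxent
from nicheshift.synthetic import default_grid


def lbfgs_oracle(F_p, F_b, beta):
    """Independent convex minimizer for the penalized objective.

    Splits lambda = a - b with a, b >= 0 so the L1 term is smooth-linear and
    the problem is solvable by L-BFGS-B; entirely separate from the package's
    coordinate-descent path.
    """
    from scipy.special import logsumexp

    pbar = F_p.mean(axis=0)
    J = F_p.shape[1]

    def obj(z):
        lam = z[:J] - z[J:]
        return -pbar @ lam + logsumexp(F_b @ lam) + beta @ (z[:J] + z[J:])

    res = minimize(obj, np.zeros(2 * J), method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * J, options={"maxiter": 2000, "ftol": 1e-15})
    return res.fun


def penalized_objective(lam, F_p, F_b, beta):
    from scipy.special import logsumexp

    return -F_p.mean(axis=0) @ lam + logsumexp(F_b @ lam) + beta @ np.abs(lam)


class TestSampleBackground:
    def test_exact_count_on_valid_cells(self):
        stack = make_env_stack(default_grid(50, 50), n_layers=2, seed=0)
        bg = sample_background(stack, n=100, seed=1)
        assert bg.n == 100
        assert np.isfinite(bg.values).all()

    def test_seeded_determinism(self):
        stack = make_env_stack(default_grid(30, 30), n_layers=1, seed=0)
        a = sample_background(stack, n=50, seed=9)
        b = sample_background(stack, n=50, seed=9)
        np.testing.assert_array_equal(a.lon, b.lon)

    def test_quadrant_uniformity_chi_square(self):
        stack = make_env_stack(default_grid(100, 100), n_layers=1, seed=0)
        bg = sample_background(stack, n=10_000, seed=3)
        mid_lon = stack.grid.origin_lon + 50 * stack.grid.cell_size
        mid_lat = stack.grid.origin_lat - 50 * stack.grid.cell_size
        counts = np.array([
            ((bg.lon < mid_lon) & (bg.lat >= mid_lat)).sum(),
            ((bg.lon >= mid_lon) & (bg.lat >= mid_lat)).sum(),
            ((bg.lon < mid_lon) & (bg.lat < mid_lat)).sum(),
            ((bg.lon >= mid_lon) & (bg.lat < mid_lat)).sum(),
        ])
        stat = ((counts - 2500.0) ** 2 / 2500.0).sum()
        assert stat < chi2.ppf(0.999, df=3)

    def test_oversized_request_warns_and_caps(self):
        stack = make_env_stack(default_grid(5, 5), n_layers=1, seed=0)
        with pytest.warns(UserWarning):
            bg = sample_background(stack, n=100, seed=0)
        assert bg.n == 25


class TestFitMaxent:
    def test_full_shrinkage_limit(self, rng):
        F_p = rng.random((20, 3))
        F_b = rng.random((200, 3))
        res = fit_maxent(F_p, F_b, feature_classes=np.array(["linear"] * 3), rm=1e6)
        assert np.count_nonzero(res["coefficients"]) == 0
        assert res["entropy"] == pytest.approx(np.log(200))

    def test_kkt_moment_matching_unpenalized(self, rng):
        F_p = rng.random((50, 3)) * 0.5 + 0.3
        F_b = rng.random((200, 3))
        res = fit_maxent(F_p, F_b, beta_override=0.0)
        q = np.exp(F_b @ res["coefficients"] - res["log_normalizer"])
        np.testing.assert_allclose(q @ F_b, F_p.mean(axis=0), atol=1e-6)

    def test_separable_data_diverges_then_soft_constraint_binds(self):
        # 2-cell background with feature values {0, 1}; all presences at 1
        F_b = np.array([[0.0], [1.0]])
        F_p = np.ones((5, 1))
        res0 = fit_maxent(F_p, F_b, beta_override=0.0)
        # no finite optimum exists: the coefficient runs away until the
        # objective is flat to numerical precision
        assert res0["coefficients"][0] > 20
        q0 = np.exp(F_b @ res0["coefficients"] - res0["log_normalizer"])
        assert q0 @ F_b[:, 0] == pytest.approx(1.0, abs=1e-9)
        res = fit_maxent(F_p, F_b, beta_override=0.05)
        q = np.exp(F_b @ res["coefficients"] - res["log_normalizer"])
        # bisection oracle on the 1-D stationarity condition E_q[f] = 1 - beta
        lo, hi = 0.0, 50.0
        for _ in range(200):
            mid = (lo + hi) / 2
            Eq = np.exp(mid) / (1 + np.exp(mid))
            lo, hi = (mid, hi) if Eq < 1 - 0.05 else (lo, mid)
        assert res["coefficients"][0] == pytest.approx((lo + hi) / 2, abs=1e-5)
        assert abs(q @ F_b[:, 0] - 1.0) <= 0.05 + 1e-9

    def test_objective_matches_independent_minimizer(self, rng):
        """Coordinate descent reaches the same optimum as a generic solver."""
        for trial in range(5):
            J = rng.integers(2, 6)
            F_p = rng.random((15, J))
            F_b = rng.random((50, J))
            beta = rng.random(J) * 0.05
            res = fit_maxent(F_p, F_b, beta_override=beta)
            ours = penalized_objective(res["coefficients"], F_p, F_b, beta)
            oracle = lbfgs_oracle(F_p, F_b, beta)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_nonzero_count_monotone_in_rm(self, recovery_study):
        study = recovery_study
        stack, occ = study["stack"], study["occurrences"]
        bg = sample_background(stack, n=1000, seed=0)
        pres = stack.extract(occ.lon, occ.lat)[:200]
        combo = FeatureCombo({"linear", "quadratic", "hinge"}, n_knots=5)
        nnz = []
        for rm in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            m = train_maxent(pres, bg.values, stack.layer_names, combo, rm=rm)
            nnz.append(m.n_nonzero)
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_scale_invariance_of_predictions(self, rng):
        P = rng.random((40, 2))
        B = rng.random((300, 2))
        combo = FeatureCombo({"linear", "quadratic"})
        m1 = train_maxent(P, B, ["a", "b"], combo, rm=1.0)
        scale = np.array([1000.0, 0.01])
        m2 = train_maxent(P * scale, B * scale, ["a", "b"], combo, rm=1.0)
        np.testing.assert_allclose(
            m1.logistic_from_values(P),
            m2.logistic_from_values(P * scale),
            rtol=1e-6,
        )


@pytest.fixture(scope="module")
def fitted():
    stack = make_env_stack(default_grid(40, 40), n_layers=2, autocorr_length=5, seed=4)
    bg = sample_background(stack, n=400, seed=5)
    rng = np.random.default_rng(6)
    pres = bg.values[rng.choice(400, 60, replace=False)] + 0.1
    model = train_maxent(pres, bg.values, stack.layer_names,
                         FeatureCombo({"linear"}), rm=0.2)
    return stack, bg, pres, model


class TestPrediction:

    def test_uniform_model_constant_raster(self, fitted):
        stack, bg, pres, model = fitted
        uniform = train_maxent(pres, bg.values, stack.layer_names,
                               FeatureCombo({"linear"}), rm=1e9)
        raw = predict_raw(uniform, stack)
        vals = raw[np.isfinite(raw)]
        np.testing.assert_allclose(vals, 1.0 / uniform.n_background)
        logi = predict_logistic(uniform, stack)
        np.testing.assert_allclose(logi[np.isfinite(logi)], 0.5)

    def test_training_rows_sum_to_one(self, fitted):
        stack, bg, pres, model = fitted
        q_bg = model.scores_from_values(bg.values, variable_names=stack.layer_names)
        q_p = model.scores_from_values(pres, variable_names=stack.layer_names)
        assert q_bg.sum() + q_p.sum() == pytest.approx(1.0)

    def test_logistic_half_at_entropy_point(self, fitted):
        stack, bg, pres, model = fitted
        # a raw value of exp(-H) must map to logistic 0.5 by construction
        from nicheshift.maxent import _logistic

        assert _logistic(np.exp(-model.entropy), model.entropy) == pytest.approx(0.5)

    def test_logistic_monotone_in_raw(self, fitted):
        stack, bg, pres, model = fitted
        raw = predict_raw(model, stack)
        logi = predict_logistic(model, stack, clamp=False)
        ok = np.isfinite(raw)
        order = np.argsort(raw[ok])
        assert (np.diff(logi[ok][order]) >= 0).all()

    def test_clamp_differs_only_out_of_range(self, fitted):
        stack, bg, pres, model = fitted
        hot = EnvStack(
            grid=stack.grid,
            layers={k: v.copy() for k, v in stack.layers.items()},
            mask=stack.mask,
        )
        # pick a variable the model actually uses, else clamping is a no-op
        used = [d.variables[0] for d, lam in
                zip(model.expander.feature_defs, model.coefficients) if lam != 0]
        assert used
        name = used[0]
        hot.layers[name][0, 0] = hot.layers[name].max() + 100.0
        on = predict_raw(model, hot, clamp=True)
        off = predict_raw(model, hot, clamp=False)
        differ = ~np.isclose(on, off, equal_nan=True)
        assert differ[0, 0]
        # cells whose variables all lie inside the training range are untouched
        k = model.expander.variable_names.index(name)
        lo, hi = model.expander.mins[k], model.expander.maxs[k]
        in_range = (hot.layers[name] >= lo) & (hot.layers[name] <= hi)
        for v, lo2, hi2 in zip(model.expander.variable_names,
                               model.expander.mins, model.expander.maxs):
            in_range &= (hot.layers[v] >= lo2) & (hot.layers[v] <= hi2)
        assert not differ[in_range].any()

    def test_missing_variable_rejected(self, fitted):
        stack, bg, pres, model = fitted
        partial = EnvStack(grid=stack.grid, layers={"env01": stack.layers["env01"]})
        with pytest.raises(KeyError):
            predict_raw(model, partial)


class TestModelSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        P = rng.random((30, 2)) * 0.6 + 0.2
        B = rng.random((200, 2))
        model = train_maxent(P, B, ["a", "b"], FeatureCombo({"linear", "hinge"}, n_knots=4), rm=1.0)
        path = write_model(model, tmp_path / "model.txt")
        back = read_model(path)
        X = rng.random((20, 2))
        np.testing.assert_allclose(
            back.logistic_from_values(X), model.logistic_from_values(X), rtol=1e-12
        )
        assert back.rm == model.rm and back.combo.code == model.combo.code
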