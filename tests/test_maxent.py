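"""Gibbs model: recovery, normalization, contributions, selection, KDE."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from habmosaic.covariates import CovariateStack, correlation_screen
from habmosaic.maxent import (
    FeatureSet,
    MaxentModel,
    cross_validate,
    fit_maxent,
    kde_polygon,
    percent_contribution,
    predict_maxent,
    sample_background,
    stepwise_select,
)
from habmosaic.raster import Raster


def gibbs_sample(lam_true, n_bg, n_pres, seed, n_cov=None):
    rng = np.random.default_rng(seed)
    n_cov = n_cov or len(lam_true)
    B = rng.normal(size=(n_bg, n_cov))
    w = np.exp(B[:, : len(lam_true)] @ lam_true)
    w /= w.sum()
    return B[rng.choice(n_bg, size=n_pres, p=w)], B


class TestFit:
    def test_matched_means_give_zero_coefficients(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(200, 2))
        model = fit_maxent(B.copy(), B, reg_multiplier=1.0,
                           classes=("linear",))
        assert np.all(model.lam == 0.0)

    def test_gibbs_coefficient_recovery(self):
        lam_true = np.array([0.8, -1.2])
        P, B = gibbs_sample(lam_true, 6000, 5000, seed=1)
        model = fit_maxent(P, B, reg_multiplier=0.0, classes=("linear",))
        coefs = np.array(list(model.covariate_coefficients().values()))
        assert np.all(np.abs(coefs - lam_true) / np.abs(lam_true) < 0.10)

    def test_raw_normalizes_over_background(self):
        P, B = gibbs_sample(np.array([1.0, -0.5]), 3000, 500, seed=2)
        model = fit_maxent(P, B)
        assert model.raw(B).sum() == pytest.approx(1.0, abs=1e-6)

    def test_objective_non_increasing(self):
        P, B = gibbs_sample(np.array([0.7, 0.7]), 2000, 800, seed=3)
        model = fit_maxent(P, B)
        assert np.all(np.diff(model.objective_path) <= 1e-12)

    def test_recovery_error_shrinks_with_sample_size(self):
        lam_true = np.array([1.0, -1.0])

        def rmse(n_pres, seed):
            P, B = gibbs_sample(lam_true, 8000, n_pres, seed=seed)
            m = fit_maxent(P, B, reg_multiplier=0.0, classes=("linear",))
            c = np.array(list(m.covariate_coefficients().values()))
            return float(np.sqrt(np.mean((c - lam_true) ** 2)))

        # average over replicates so a lucky small-sample draw cannot mask
        # the 1/sqrt(n) trend
        errs = [np.mean([rmse(n, s) for s in (4, 5, 6, 7)])
                for n in (200, 1000, 5000)]
        assert errs[2] < errs[1] < errs[0]

    def test_nonfinite_features_raise(self):
        B = np.random.default_rng(5).normal(size=(50, 2))
        P = B[:10].copy()
        P[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_maxent(P, B)


class TestPredict:
    def make_stack(self, arrays):
        return CovariateStack(rasters={
            n: Raster(a, cell_size=120.0) for n, a in arrays.items()})

    def test_constant_covariates_give_constant_output(self):
        rng = np.random.default_rng(6)
        P, B = gibbs_sample(np.array([1.0]), 1000, 200, seed=6)
        model = fit_maxent(P, B, names=["v"])
        stack = self.make_stack({"v": np.full((5, 5), 0.3)})
        out = predict_maxent(model, stack)
        assert np.unique(out.values).size == 1

    def test_cloglog_bounded_and_rank_preserving(self):
        P, B = gibbs_sample(np.array([1.5, -0.7]), 3000, 800, seed=7)
        model = fit_maxent(P, B)
        raw = model.raw(B)
        clog = model.transform_output(raw)
        assert clog.min() >= 0.0 and clog.max() <= 1.0
        rho, _ = spearmanr(raw, clog)
        assert rho == pytest.approx(1.0)

    def test_missing_covariate_raises(self):
        P, B = gibbs_sample(np.array([1.0]), 500, 100, seed=8)
        model = fit_maxent(P, B, names=["v"])
        stack = self.make_stack({"other": np.zeros((3, 3))})
        with pytest.raises(KeyError):
            predict_maxent(model, stack)


class TestContribution:
    def test_single_variable_is_100(self):
        P, B = gibbs_sample(np.array([1.2]), 2000, 500, seed=9)
        pc = percent_contribution(fit_maxent(P, B, names=["v"]), P, B)
        assert pc["v"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self):
        P, B = gibbs_sample(np.array([1.0, -0.8]), 3000, 800, seed=10,
                            n_cov=4)
        model = fit_maxent(P, B)
        pc = percent_contribution(model, P, B)
        assert sum(pc.values()) == pytest.approx(100.0, abs=1e-6)

    def test_noise_variable_contributes_little(self):
        P, B = gibbs_sample(np.array([1.5, -1.5]), 5000, 2000, seed=11,
                            n_cov=3)
        model = fit_maxent(P, B, names=["a", "b", "noise"])
        pc = percent_contribution(model, P, B, seed=1)
        assert pc["noise"] < 5.0


class TestStepwise:
    def make_selection_stack(self, seed=12, with_copy=True):
        rng = np.random.default_rng(seed)
        shape = (40, 40)
        sig = rng.normal(size=shape)
        arrays = {"signal": sig, "noise": rng.normal(size=shape)}
        if with_copy:
            arrays["signal_copy"] = sig.copy()
        stack = CovariateStack(rasters={
            n: Raster(a, cell_size=120.0) for n, a in arrays.items()})
        correlation_screen(stack)
        # presences drawn from cells with high signal
        w = np.exp(2.5 * sig.ravel())
        idx = rng.choice(sig.size, size=400, p=w / w.sum())
        rows, cols = np.unravel_index(idx, shape)
        g = stack.grid
        xy = np.column_stack([
            g.x_origin + (cols + 0.5) * g.cell_size,
            g.y_origin + (shape[0] - rows - 0.5) * g.cell_size])
        return stack, xy

    def test_correlated_duplicate_resolved_to_one(self):
        stack, xy = self.make_selection_stack()
        region = stack.grid.with_values(np.ones(stack.grid.shape, int))
        bg = sample_background(region, 2000, seed=0)
        variables, _ = stepwise_select(stack, xy, bg, seed=0)
        assert sum(v.startswith("signal") for v in variables) == 1

    def test_informative_variable_recovered(self):
        stack, xy = self.make_selection_stack(with_copy=False)
        region = stack.grid.with_values(np.ones(stack.grid.shape, int))
        bg = sample_background(region, 2000, seed=0)
        variables, model = stepwise_select(stack, xy, bg, seed=0)
        assert "signal" in variables
        assert len(variables) <= 2    # at most one extra beyond the truth

    def test_all_noise_terminates(self):
        rng = np.random.default_rng(13)
        stack = CovariateStack(rasters={
            f"n{i}": Raster(rng.normal(size=(30, 30)), cell_size=120.0)
            for i in range(3)})
        correlation_screen(stack)
        g = stack.grid
        xy = sample_background(g.with_values(np.ones(g.shape, int)), 300,
                               seed=1)
        bg = sample_background(g.with_values(np.ones(g.shape, int)), 1500,
                               seed=2)
        try:
            variables, _ = stepwise_select(stack, xy, bg, seed=0)
            assert len(variables) >= 1
        except ValueError:
            pass    # dropping every variable is an accepted outcome


class TestCrossValidate:
    def test_partition_properties(self, small_stack):
        rng = np.random.default_rng(14)
        g = small_stack.grid
        xy = sample_background(g.with_values(np.ones(g.shape, int)), 100,
                               seed=3)
        folds = cross_validate(xy, small_stack, k=10, seed=5,
                               n_background=300,
                               variables=["forage", "cover"])
        sizes = [f.test_presence_xy.shape[0] for f in folds]
        assert sizes == [10] * 10
        stacked = np.vstack([f.test_presence_xy for f in folds])
        assert stacked.shape == xy.shape
        # disjoint cover: every presence appears exactly once across folds
        assert {tuple(p) for p in stacked} == {tuple(p) for p in xy}

    def test_same_seed_same_partition(self, small_stack):
        g = small_stack.grid
        xy = sample_background(g.with_values(np.ones(g.shape, int)), 50,
                               seed=6)
        a = cross_validate(xy, small_stack, k=5, seed=7, n_background=200,
                           variables=["forage"])
        b = cross_validate(xy, small_stack, k=5, seed=7, n_background=200,
                           variables=["forage"])
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_presence_xy,
                                          fb.test_presence_xy)
            np.testing.assert_array_equal(fa.background_xy, fb.background_xy)

    def test_k_below_two_raises(self, small_stack):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((10, 2)), small_stack, k=1)


class TestKde:
    def grid(self):
        return Raster(np.zeros((100, 100)), x_origin=-5.0, y_origin=-5.0,
                      cell_size=0.1)

    def test_href_formula(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(64, 2))
        pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)   # exact unit variance
        kde = kde_polygon(pts, self.grid())
        assert kde.bandwidth == pytest.approx(64 ** (-1 / 6), abs=1e-12)
        assert kde.bandwidth == pytest.approx(0.5, abs=1e-3)

    def test_full_level_covers_every_cell(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(30, 2))
        kde = kde_polygon(pts, self.grid(), level=1.0)
        assert np.all(kde.mask.values[kde.density.values > 0] == 1)

    def test_isopleth_area_matches_analytic_circle(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(200, 2))
        kde = kde_polygon(pts, self.grid(), level=0.95)
        v = float(pts.var(axis=0, ddof=1).mean()) + kde.bandwidth**2
        analytic = np.pi * (-2.0 * v * np.log(0.05))   # 95% disk of N(0, v I)
        measured = kde.mask.values.sum() * 0.1 * 0.1
        assert abs(measured - analytic) / analytic < 0.15

    def test_identical_points_degenerate(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValueError):
            kde_polygon(pts, self.grid())


class TestBackground:
    def test_single_cell_region(self):
        mask = Raster(np.zeros((3, 3), dtype=int), cell_size=10.0)
        vals = mask.values.copy()
        vals[1, 1] = 1
        pts = sample_background(mask.with_values(vals), n=10, seed=0)
        assert np.all(pts == pts[0])
        assert tuple(pts[0]) == (15.0, 15.0)

    def test_seeded_determinism(self, small_stack):
        g = small_stack.grid
        region = g.with_values(np.ones(g.shape, int))
        a = sample_background(region, 100, seed=9)
        b = sample_background(region, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_two_cell_region_binomial_balance(self):
        vals = np.zeros((2, 1), dtype=int)
        vals[:, 0] = 1
        mask = Raster(vals, cell_size=10.0)
        pts = sample_background(mask, n=10000, seed=10)
        n_top = int((pts[:, 1] > 10).sum())
        assert abs(n_top - 5000) <= 150

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            sample_background(Raster(np.zeros((3, 3), dtype=int)), 10, 0)


def test_model_json_roundtrip(tmp_path):
    P, B = gibbs_sample(np.array([1.0, -0.5]), 1000, 300, seed=18)
    model = fit_maxent(P, B)
    model.to_json(tmp_path / "m.json")
    back = MaxentModel.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(back.predict(B), model.predict(B), atol=1e-12)


def test_clamping_outside_training_bounds():
    rng = np.random.default_rng(19)
    X = rng.uniform(0, 1, size=(500, 1))
    fs = FeatureSet.from_training(X, ["v"])
    inside = fs.transform(np.array([[1.0]]))
    outside = fs.transform(np.array([[5.0]]))
    np.testing.assert_array_equal(inside, outside)
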