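"""Mahalanobis suitability: D^2 algebra, chi-square mapping, PCA ranking."""

import numpy as np
import pytest
from scipy.special import gammaincc
from scipy.stats import chi2

from habmosaic.covariates import CovariateStack
from habmosaic.mahalanobis import (
    MahalanobisModel,
    fit_mahalanobis,
    iterative_removal,
    limiting_contribution,
    pca_contribution,
    predict_mahalanobis,
)
from habmosaic.raster import Raster


class TestFit:
    def test_orthogonal_columns_give_identity_sigma(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10000, 2))
        model = fit_mahalanobis(X)
        np.testing.assert_allclose(model.sigma, np.eye(2), atol=0.05)

    def test_duplicated_column_raises_naming_culprits(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            fit_mahalanobis(np.column_stack([x, x]), names=["a", "b"])

    def test_univariate_reduces_to_squared_zscore(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3.0, 2.0, size=500)[:, None]
        model = fit_mahalanobis(x)
        q = np.array([[5.0]])
        z2 = ((5.0 - x.mean()) / x.std(ddof=1)) ** 2
        assert model.d2(q)[0] == pytest.approx(z2, rel=1e-12)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError):
            fit_mahalanobis(np.eye(3))


class TestPredict:
    def fitted(self, seed=3, p=3, n=500):
        rng = np.random.default_rng(seed)
        return fit_mahalanobis(rng.normal(size=(n, p))), rng

    def test_suitability_is_one_at_centroid(self):
        model, _ = self.fitted()
        assert model.suitability(model.mu[None, :])[0] == pytest.approx(1.0)

    def test_chi_square_median_maps_to_half(self):
        model, _ = self.fitted()
        # place a point at exactly the chi-square median distance along
        # the first covariance eigenvector
        med = chi2.ppf(0.5, df=model.df)
        vals, vecs = np.linalg.eigh(model.sigma)
        x = model.mu + np.sqrt(med * vals[0]) * vecs[:, 0]
        assert model.d2(x[None, :])[0] == pytest.approx(med, rel=1e-9)
        assert model.suitability(x[None, :])[0] == pytest.approx(0.5, rel=1e-9)

    def test_d2_matches_explicit_inverse(self):
        model, rng = self.fitted(seed=4)
        X = rng.normal(size=(50, 3))
        inv = np.linalg.inv(model.sigma)
        brute = np.array([(x - model.mu) @ inv @ (x - model.mu) for x in X])
        np.testing.assert_allclose(model.d2(X), brute, atol=1e-9)

    def test_suitability_strictly_decreasing_in_d2(self):
        model, rng = self.fitted(seed=5)
        X = rng.normal(size=(100, 3))
        d2 = model.d2(X)
        s = model.suitability(X)
        order = np.argsort(d2)
        assert np.all(np.diff(s[order]) < 0)

    def test_affine_invariance_of_d2(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 3))
        Q = rng.normal(size=(20, 3))
        base = fit_mahalanobis(X).d2(Q)
        scale = np.array([10.0, 0.2, 1.0])
        shift = np.array([5.0, -2.0, 0.0])
        rescaled = fit_mahalanobis(X * scale + shift).d2(Q * scale + shift)
        np.testing.assert_allclose(rescaled, base, atol=1e-9)

    def test_against_reference_chi_square_tail(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            df = int(rng.integers(1, 12))
            d2 = float(rng.uniform(0, 40))
            ours = chi2.sf(d2, df=df)
            reference = gammaincc(df / 2.0, d2 / 2.0)   # closed-form tail
            assert ours == pytest.approx(reference, rel=1e-10, abs=1e-300)

    def test_predict_on_stack(self):
        rng = np.random.default_rng(8)
        model = fit_mahalanobis(rng.normal(size=(300, 2)), names=["a", "b"])
        stack = CovariateStack(rasters={
            "a": Raster(rng.normal(size=(6, 6)), cell_size=120.0),
            "b": Raster(rng.normal(size=(6, 6)), cell_size=120.0)})
        out = predict_mahalanobis(model, stack)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        with pytest.raises(KeyError):
            predict_mahalanobis(model, stack.subset(["a"]))


class TestPcaContribution:
    def test_identical_columns_contribute_equally(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        noise = rng.normal(size=300)
        contrib = pca_contribution(
            np.column_stack([x, x, noise]), ["a", "b", "n"])
        assert contrib["a"] == pytest.approx(contrib["b"], rel=1e-9)

    def test_sums_to_retained_variance_share(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(500, 5))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        lam = np.linalg.eigvalsh(np.cov(Z, rowvar=False))[::-1]
        share = lam / lam.sum()
        n_keep = int(np.searchsorted(np.cumsum(share), 0.80) + 1)
        contrib = pca_contribution(X)
        assert sum(contrib.values()) == pytest.approx(share[:n_keep].sum(),
                                                      abs=1e-9)

    def test_matches_eigendecomposition_oracle_and_ranks_hub_first(self):
        # 'a' carries the dominant shared-variance axis (correlated with both
        # b and c, which are only weakly related to each other)
        rng = np.random.default_rng(11)
        f = rng.normal(size=2000)
        X = np.column_stack([f,
                             f + rng.normal(size=2000),
                             f + rng.normal(size=2000),
                             rng.normal(size=2000)])
        contrib = pca_contribution(X, ["a", "b", "c", "d"])
        # oracle: direct eigendecomposition of the correlation matrix
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        lam, vecs = np.linalg.eigh(np.corrcoef(Z, rowvar=False))
        lam, vecs = lam[::-1], vecs[:, ::-1]
        share = lam / lam.sum()
        n_keep = int(np.searchsorted(np.cumsum(share), 0.80) + 1)
        oracle = (vecs[:, :n_keep] ** 2 * share[:n_keep]).sum(axis=1)
        np.testing.assert_allclose(list(contrib.values()), oracle, atol=1e-9)
        # the hub variable outranks its partners, which lose their residual
        # contrasts to the dropped low-variance components
        assert contrib["a"] > contrib["b"] and contrib["a"] > contrib["c"]

    def test_constant_column_raises(self):
        with pytest.raises(ValueError):
            pca_contribution(np.column_stack([np.ones(10),
                                              np.arange(10.0)]))


class TestIterativeRemoval:
    def selection_sample(self, seed=12, n=3000):
        # virtual selection: keep draws with high a + b - c, add pure noise
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n * 10, 5))
        score = X[:, 0] + X[:, 1] - X[:, 2]
        keep = np.argsort(score)[-n:]
        return X[keep], ["a", "b", "c", "noise1", "noise2"]

    def test_noise_dropped_informative_kept(self):
        X, names = self.selection_sample()
        kept, model = iterative_removal(X, names)
        assert {"a", "b", "c"} <= set(kept)
        assert not ({"noise1", "noise2"} & set(kept))
        assert model.df == len(kept)

    def test_limiting_contribution_orders_noise_last(self):
        X, names = self.selection_sample(seed=13)
        contrib = limiting_contribution(X, names)
        ranked = sorted(contrib, key=contrib.get)
        assert set(ranked[:2]) == {"noise1", "noise2"}

    def test_stops_at_min_variables(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(200, 3))
        kept, _ = iterative_removal(X, ["a", "b", "c"], contribution_floor=1.0,
                                    min_variables=2)
        assert len(kept) == 2


def test_model_json_roundtrip(tmp_path):
    rng = np.random.default_rng(15)
    model = fit_mahalanobis(rng.normal(size=(100, 3)), names=["x", "y", "z"])
    model.to_json(tmp_path / "m.json")
    back = MahalanobisModel.from_json(tmp_path / "m.json")
    Q = rng.normal(size=(10, 3))
    np.testing.assert_allclose(back.suitability(Q), model.suitability(Q),
                               atol=1e-12)
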