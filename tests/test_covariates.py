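"""Covariate operators versus brute-force oracles on small grids."""

import numpy as np
import pytest

from habmosaic.covariates import (
    CovariateStack,
    contiguity,
    correlation_screen,
    euclidean_distance,
    focal_density,
    label_patches,
    shape_index,
    tri,
)
from habmosaic.raster import Raster


def binary_raster(values, cell_size=120.0):
    return Raster(np.asarray(values, dtype=int), cell_size=cell_size)


class TestEuclideanDistance:
    def test_rook_and_diagonal_neighbors(self):
        m = np.zeros((5, 5), dtype=int)
        m[2, 2] = 1
        d = euclidean_distance(binary_raster(m))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(120.0)
        assert d.values[1, 1] == pytest.approx(120.0 * np.sqrt(2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        m = (rng.random((20, 20)) < 0.1).astype(int)
        m[7, 3] = 1
        r = binary_raster(m)
        d = euclidean_distance(r)
        true_rc = np.argwhere(m == 1)
        for i in range(20):
            for j in range(20):
                brute = np.min(np.hypot(true_rc[:, 0] - i, true_rc[:, 1] - j))
                assert abs(d.values[i, j] - brute * 120.0) <= 1e-9

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            euclidean_distance(binary_raster(np.zeros((3, 3))))


class TestFocalDensity:
    def test_saturated_and_empty(self):
        ones = binary_raster(np.ones((8, 8)))
        np.testing.assert_allclose(focal_density(ones, 300.0).values, 1.0)
        zeros = binary_raster(np.zeros((8, 8)))
        np.testing.assert_allclose(focal_density(zeros, 300.0).values, 0.0)

    def test_matches_neighborhood_count_oracle(self):
        rng = np.random.default_rng(1)
        m = (rng.random((15, 15)) < 0.4).astype(int)
        r = binary_raster(m, cell_size=100.0)
        out = focal_density(r, 250.0)     # radius 2.5 cells
        for i in range(15):
            for j in range(15):
                hits = tot = 0
                for a in range(15):
                    for b in range(15):
                        if (a - i) ** 2 + (b - j) ** 2 <= 2.5**2:
                            tot += 1
                            hits += m[a, b]
                assert out.values[i, j] == pytest.approx(hits / tot)

    def test_radius_below_cell_raises(self):
        with pytest.raises(ValueError):
            focal_density(binary_raster(np.ones((4, 4))), 50.0)


class TestTri:
    def test_constant_elevation_is_zero(self):
        r = Raster(np.full((6, 6), 42.0), cell_size=120.0)
        np.testing.assert_allclose(tri(r).values, 0.0)

    def test_unit_spike(self):
        z = np.zeros((3, 3))
        z[1, 1] = 1.0
        assert tri(Raster(z, cell_size=120.0)).values[1, 1] == pytest.approx(1.0)

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(10, 10))
        out = tri(Raster(z, cell_size=120.0))
        for i in range(10):
            for j in range(10):
                diffs = [
                    (z[a, b] - z[i, j]) ** 2
                    for a in range(max(0, i - 1), min(10, i + 2))
                    for b in range(max(0, j - 1), min(10, j + 2))
                    if (a, b) != (i, j)
                ]
                assert abs(out.values[i, j]
                           - np.sqrt(np.mean(diffs))) <= 1e-12


class TestShapeIndex:
    def test_square_patch_is_exactly_one(self):
        m = np.zeros((7, 7), dtype=int)
        m[2:5, 2:5] = 1
        per_patch, mean = shape_index(label_patches(binary_raster(m)))
        assert list(per_patch.values()) == [1.0]
        assert mean == 1.0

    def test_1x4_rectangle_hand_count(self):
        m = np.zeros((3, 6), dtype=int)
        m[1, 1:5] = 1        # P = 10 edges, A = 4 cells
        per_patch, _ = shape_index(label_patches(binary_raster(m)))
        assert list(per_patch.values()) == [pytest.approx(1.25)]

    def test_isoperimetric_lower_bound(self):
        rng = np.random.default_rng(3)
        m = (rng.random((20, 20)) < 0.45).astype(int)
        per_patch, mean = shape_index(label_patches(binary_raster(m)))
        assert all(v >= 1.0 - 1e-12 for v in per_patch.values())
        assert mean >= 1.0 - 1e-12

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            shape_index(label_patches(binary_raster(np.zeros((4, 4)))))


class TestContiguity:
    def test_full_interior_scores_one(self):
        r = binary_raster(np.ones((21, 21)))
        out = contiguity(r, window_area_km2=0.2)
        assert out.values[10, 10] == pytest.approx(1.0)

    def test_isolated_cell_scores_zero(self):
        m = np.zeros((11, 11), dtype=int)
        m[5, 5] = 1
        out = contiguity(binary_raster(m))
        assert out.values[5, 5] == 0.0

    def test_matches_template_oracle(self):
        rng = np.random.default_rng(4)
        m = (rng.random((12, 12)) < 0.5).astype(int)
        r = binary_raster(m, cell_size=100.0)
        area = 0.125   # km^2 -> radius sqrt(0.125e6/pi) ~ 199.5 m ~ 2 cells
        out = contiguity(r, window_area_km2=area)
        radius_cells = np.sqrt(area * 1e6 / np.pi) / 100.0
        w = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)
        score = np.zeros_like(m, dtype=float)
        for i in range(12):
            for j in range(12):
                if not m[i, j]:
                    continue
                t = 1.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if (di, dj) == (0, 0):
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < 12 and 0 <= b < 12 and m[a, b]:
                            t += w[di + 1, dj + 1]
                score[i, j] = (t - 1.0) / 12.0
        for i in range(12):
            for j in range(12):
                num = den = 0.0
                for a in range(12):
                    for b in range(12):
                        if (a - i) ** 2 + (b - j) ** 2 <= radius_cells**2 and m[a, b]:
                            num += score[a, b]
                            den += 1.0
                expected = num / den if den else 0.0
                assert abs(out.values[i, j] - expected) <= 1e-12

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError):
            contiguity(binary_raster(np.ones((4, 4)), cell_size=1000.0),
                       window_area_km2=0.5)


class TestCorrelationScreen:
    def make_stack(self, arrays):
        return CovariateStack(rasters={
            name: Raster(a, cell_size=120.0) for name, a in arrays.items()})

    def test_self_correlation_and_negation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 10))
        stack = self.make_stack({"x": x, "neg": -x})
        flagged = correlation_screen(stack)
        assert stack.correlation.loc["x", "x"] == pytest.approx(1.0)
        assert [(a, b) for a, b, _ in flagged] == [("x", "neg")]
        assert flagged[0][2] == pytest.approx(-1.0)

    def test_independent_noise_not_flagged(self):
        rng = np.random.default_rng(6)
        stack = self.make_stack({"a": rng.normal(size=(100, 100)),
                                 "b": rng.normal(size=(100, 100))})
        flagged = correlation_screen(stack)
        assert flagged == []
        assert abs(stack.correlation.loc["a", "b"]) < 0.05

    def test_degenerate_variable_excluded(self):
        rng = np.random.default_rng(7)
        stack = self.make_stack({"flat": np.ones((5, 5)),
                                 "x": rng.normal(size=(5, 5)),
                                 "y": rng.normal(size=(5, 5))})
        flagged = correlation_screen(stack)
        assert stack.degenerate == ["flat"]
        assert all("flat" not in pair[:2] for pair in flagged)

    def test_needs_two_variables(self):
        stack = self.make_stack({"only": np.zeros((3, 3))})
        with pytest.raises(ValueError):
            correlation_screen(stack)


def test_outputs_inherit_grid_and_bounds(small_stack):
    grid = small_stack.grid
    for name, r in small_stack.rasters.items():
        assert r.same_grid(grid)
    dens = small_stack.rasters["wetland_density"].values
    assert dens.min() >= 0.0 and dens.max() <= 1.0
    assert small_stack.rasters["dist_natural"].values.min() >= 0.0
    assert small_stack.rasters["tri"].values.min() >= 0.0
    cont = small_stack.rasters["natural_contiguity"].values
    assert cont.min() >= 0.0 and cont.max() <= 1.0
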