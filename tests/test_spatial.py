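"""IDW, ordinary kriging (with dense-solve oracle), and raster classes."""

import numpy as np
import pytest

from aquarisk.spatial import (
    Variogram,
    classify5,
    empirical_variogram,
    fit_variogram,
    idw,
    krige_grid,
    ordinary_krige,
)


@pytest.fixture()
def field5(rng):
    pts = rng.uniform(0, 10, (5, 2))
    vals = 2.0 + 0.5 * pts[:, 0] - 0.2 * pts[:, 1]
    return pts, vals


class TestVariogram:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            Variogram("spherical", nugget=1.0, sill=0.5, range_=1.0)
        with pytest.raises(ValueError):
            Variogram("spline", 0.0, 1.0, 1.0)

    def test_zero_at_origin_and_sill_at_range(self):
        v = Variogram("spherical", nugget=0.1, sill=1.0, range_=5.0)
        assert v(np.array([0.0]))[0] == 0.0
        assert v(np.array([5.0]))[0] == pytest.approx(1.0)
        assert v(np.array([50.0]))[0] == pytest.approx(1.0)

    def test_fit_recovers_empirical_scale(self, rng):
        pts = rng.uniform(0, 20, (60, 2))
        vals = np.sin(pts[:, 0] / 3) + 0.1 * rng.normal(size=60)
        v = fit_variogram(pts, vals)
        h, gamma = empirical_variogram(pts, vals)
        assert v.sill == pytest.approx(gamma.max(), rel=1.0)  # same order


class TestIdw:
    def test_exact_at_data_point(self, field5):
        pts, vals = field5
        assert idw(pts, vals, pts[2])[0] == pytest.approx(vals[2])

    def test_constant_field(self, field5, rng):
        pts, _ = field5
        q = rng.uniform(0, 10, (7, 2))
        np.testing.assert_allclose(idw(pts, np.full(5, 3.3), q), 3.3)

    def test_equidistant_symmetry(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert idw(pts, np.array([0.0, 2.0]), [[1.0, 0.0]])[0] == pytest.approx(1.0)

    def test_bounded_by_data(self, field5, rng):
        pts, vals = field5
        q = rng.uniform(-5, 15, (50, 2))
        pred = idw(pts, vals, q)
        assert (pred >= vals.min() - 1e-12).all() and (pred <= vals.max() + 1e-12).all()


class TestOrdinaryKrige:
    VG = Variogram("spherical", nugget=0.0, sill=2.0, range_=8.0)

    def test_exact_at_data_with_zero_nugget(self, field5):
        pts, vals = field5
        pred, var = ordinary_krige(pts, vals, self.VG, pts)
        np.testing.assert_allclose(pred, vals, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_weights_sum_to_one_via_constant_shift(self, field5, rng):
        # adding a constant to the data must shift predictions by the same
        # constant iff the weights sum to one
        pts, vals = field5
        q = rng.uniform(0, 10, (9, 2))
        p1, _ = ordinary_krige(pts, vals, self.VG, q)
        p2, _ = ordinary_krige(pts, vals + 11.5, self.VG, q)
        np.testing.assert_allclose(p2 - p1, 11.5, atol=1e-8)

    def test_matches_dense_solver_oracle(self, field5, rng):
        from scipy.spatial.distance import cdist

        pts, vals = field5
        q = rng.uniform(0, 10, (4, 2))
        pred, var = ordinary_krige(pts, vals, self.VG, q)
        n = len(pts)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = self.VG(cdist(pts, pts))
        A[:n, n] = A[n, :n] = 1.0
        for i, point in enumerate(q):
            b = np.append(self.VG(cdist([point], pts)[0]), 1.0)
            sol = np.linalg.solve(A, b)
            assert pred[i] == pytest.approx(float(sol[:n] @ vals), abs=1e-10)
            assert var[i] == pytest.approx(
                max(float(sol[:n] @ b[:n] + sol[n]), 0.0), abs=1e-10
            )

    def test_translation_and_rotation_invariance(self, field5, rng):
        pts, vals = field5
        q = rng.uniform(2, 8, (3, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([100.0, -40.0])
        p1, _ = ordinary_krige(pts, vals, self.VG, q)
        p2, _ = ordinary_krige(pts @ R.T + shift, vals, self.VG, q @ R.T + shift)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ordinary_krige(np.zeros((2, 2)), np.zeros(2), self.VG, [[0, 0]])

    def test_grid_shapes(self, rng):
        pts = rng.uniform(0, 10, (20, 2))
        vals = pts[:, 0] + rng.normal(0, 0.1, 20)
        gx, gy, grid = krige_grid(pts, vals, resolution=12)
        assert gx.shape == gy.shape == grid.shape == (12, 12)


class TestClassify5:
    def test_published_nickel_breaks(self):
        res = classify5(np.array([0.02, 2.19]))
        np.testing.assert_allclose(res.breaks, [0.454, 0.888, 1.322, 1.756], atol=1e-9)

    def test_published_manganese_breaks(self):
        res = classify5(np.array([0.01, 0.91]))
        np.testing.assert_allclose(res.breaks, [0.19, 0.37, 0.55, 0.73], atol=1e-9)

    def test_constant_grid_single_class(self):
        res = classify5(np.full((3, 3), 1.0))
        assert res.constant and (res.classes == 0).all()

    def test_every_finite_cell_classified(self, rng):
        grid = rng.uniform(0, 1, (10, 10))
        grid[0, 0] = np.nan
        res = classify5(grid)
        finite = np.isfinite(grid)
        assert (res.classes[finite] >= 0).all() and res.classes[~finite][0] == -1
        assert res.classes[finite].max() == 4 and res.classes[finite].min() == 0

    def test_breaks_strictly_increasing(self, rng):
        res = classify5(rng.uniform(-3, 9, 100))
        assert (np.diff(res.breaks) > 0).all()
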