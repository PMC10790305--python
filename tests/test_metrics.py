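"""Correspondences, distance statistics, ICC, fibre/LAT/CV/PS agreement."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lamp.mesh import LabelledSurfaceMesh
from lamp.metrics import (
    correspond,
    cv_compare,
    distance_stats,
    fibre_agreement,
    icc_absolute_agreement,
    lat_compare,
    ps_compare,
    ssim_uniform,
)


from conftest import make_icosphere, make_strip, strip_uac


def _point_mesh(points):
    points = np.asarray(points, dtype=float)
    tris = np.zeros((1, 3), dtype=int) if len(points) >= 3 else None
    if len(points) < 3:
        points = np.vstack([points, points[-1] + 1e-9, points[-1] + 2e-9])
        tris = np.array([[0, 1, 2]])
    return LabelledSurfaceMesh(vertices=points, triangles=np.array([[0, 1, 2]]))


class TestCorrespond:
    def test_identity_all_zero(self):
        mesh = make_icosphere(5.0, 2)
        corr = correspond(mesh, mesh)
        assert corr.dist_ab.max() == 0.0
        assert corr.within_ab.all()

    def test_two_points_outside_cutoff(self):
        a = _point_mesh([[0.0, 0, 0]])
        b = _point_mesh([[3.0, 0, 0]])
        corr = correspond(a, b, cutoff=1.0)
        assert corr.dist_ab[0] == pytest.approx(3.0)
        assert not corr.within_ab[0]

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(0)
        A = rng.random((100, 3)) * 10
        B = rng.random((100, 3)) * 10
        tris = np.array([[0, 1, 2]])
        corr = correspond(
            LabelledSurfaceMesh(A, tris), LabelledSurfaceMesh(B, tris)
        )
        D = cdist(A, B)
        np.testing.assert_array_equal(corr.idx_ab, D.argmin(axis=1))
        np.testing.assert_allclose(corr.dist_ab, D.min(axis=1))


class TestDistanceStats:
    def test_identity_zeros(self):
        mesh = make_icosphere(5.0, 2)
        s = distance_stats(mesh, mesh)["all"]
        assert s["hausdorff"] == s["mean"] == s["median"] == 0.0

    def test_concentric_spheres_offset(self):
        a = make_icosphere(20.0, 4)
        b = make_icosphere(23.0, 4)
        s = distance_stats(a, b)["all"]
        for key in ("hausdorff", "mean", "median"):
            assert abs(s[key] - 3.0) < 0.15

    def test_hausdorff_at_least_mean_and_nonnegative(self):
        rng = np.random.default_rng(1)
        a = make_icosphere(10.0, 2)
        b = make_icosphere(10.0, 2)
        b.vertices += rng.normal(0, 0.5, b.vertices.shape)
        s = distance_stats(a, b)["all"]
        assert s["hausdorff"] >= s["mean"] >= 0.0


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        res = icc_absolute_agreement(x)
        assert res.icc == pytest.approx(1.0)

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            res = icc_absolute_agreement(X)
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": X.ravel(),
                }
            )
            icc = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
            ref = icc.loc[icc["Type"].isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0]
            assert abs(res.icc - ref) < 1e-10

    def test_toy_table_against_hand_anova(self):
        # 4 subjects × 2 raters; MS terms computed by hand from the ANOVA
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 9.0]])
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((X - X.mean(axis=1, keepdims=True) - X.mean(axis=0) + grand) ** 2).sum() / (
            (n - 1) * (k - 1)
        )
        expect = (msr - mse) / (msr + (msc - mse) / n)
        assert icc_absolute_agreement(X).icc == pytest.approx(expect, abs=1e-12)

    def test_degenerate_table_flagged(self):
        res = icc_absolute_agreement(np.full((4, 2), 3.0))
        assert res.icc == 1.0 and res.degenerate

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestFibreAgreement:
    def _corr(self, n):
        mesh = make_icosphere(5.0, 2)
        return correspond(mesh, mesh), mesh

    def test_identity_and_antiparallel_are_perfect(self):
        corr, mesh = self._corr(0)
        rng = np.random.default_rng(0)
        f = rng.normal(size=(mesh.n_triangles, 3))
        f /= np.linalg.norm(f, axis=1)[:, None]
        assert fibre_agreement(corr, f, f)["fraction"] == 1.0
        assert fibre_agreement(corr, f, -f)["fraction"] == 1.0

    def test_thirty_degree_rotation_scores_zero(self):
        corr, mesh = self._corr(0)
        n = mesh.normals()
        rng = np.random.default_rng(1)
        f = np.cross(n, rng.normal(size=3))
        f /= np.linalg.norm(f, axis=1)[:, None]
        theta = np.radians(30.0)
        # rotate each fibre about its element normal by 30°: Rodrigues
        g = (
            f * np.cos(theta)
            + np.cross(n, f) * np.sin(theta)
            + n * (np.einsum("ij,ij->i", n, f))[:, None] * (1 - np.cos(theta))
        )
        out = fibre_agreement(corr, f, g)
        assert out["fraction"] == 0.0  # cos 30° < cos 22.5°

    def test_threshold_is_cos_22_5(self):
        corr, mesh = self._corr(0)
        f = np.tile([1.0, 0.0, 0.0], (mesh.n_triangles, 1))
        out = fibre_agreement(corr, f, f)
        assert out["threshold"] == pytest.approx(np.cos(np.pi / 8))

    def test_global_sign_flip_invariance(self):
        corr, mesh = self._corr(0)
        rng = np.random.default_rng(2)
        fa = rng.normal(size=(mesh.n_triangles, 3))
        fb = rng.normal(size=(mesh.n_triangles, 3))
        for f in (fa, fb):
            f /= np.linalg.norm(f, axis=1)[:, None]
        base = fibre_agreement(corr, fa, fb)["fraction"]
        assert fibre_agreement(corr, -fa, fb)["fraction"] == base
        assert fibre_agreement(corr, fa, -fb)["fraction"] == base


class TestLATCompare:
    def _setup(self):
        mesh = make_strip(21, 21, 1.0, 1.0)
        uac = strip_uac(mesh, 1.0, 1.0)
        lat = mesh.vertices[:, 0] * 100.0
        return lat, uac

    def test_identity(self):
        lat, uac = self._setup()
        out = lat_compare(lat, lat, uac, uac)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["abs_tat_diff_ms"] == 0.0

    def test_shift_preserves_correlation(self):
        lat, uac = self._setup()
        out = lat_compare(lat, lat + 5.0, uac, uac)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["abs_tat_diff_ms"] == pytest.approx(5.0)

    def test_too_few_common_cells_rejected(self):
        lat, uac = self._setup()
        with pytest.raises(ValueError):
            lat_compare(lat, np.full_like(lat, np.inf), uac, uac)


class TestCVCompare:
    def test_identity_and_shift(self):
        rng = np.random.default_rng(0)
        cv = rng.random(500) + 0.2
        assert cv_compare(cv, cv)["mean_diff"] == 0.0
        out = cv_compare(cv + 0.05, cv)
        assert out["mean_diff"] == pytest.approx(0.05)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            cv_compare(np.full(10, np.nan), np.ones(10))


class TestPSCompare:
    def test_identity_nonconstant(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(1.0, (101, 101)).astype(float)
        out = ps_compare(m, m)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["ssim"] == pytest.approx(1.0)

    def test_constant_maps_closed_form(self):
        mu_a, mu_b = 2.0, 3.0
        A = np.full((50, 50), mu_a)
        B = np.full((50, 50), mu_b)
        L = max(mu_a, mu_b)
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        expect = (2 * mu_a * mu_b + c1) * c2 / ((mu_a**2 + mu_b**2 + c1) * c2)
        assert ssim_uniform(A, B) == pytest.approx(expect, abs=1e-12)

    def test_zero_maps_defined_as_identical(self):
        out = ps_compare(np.zeros((20, 20)), np.zeros((20, 20)))
        assert np.isnan(out["pearson_r"])
        assert out["ssim"] == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.poisson(2.0, (60, 60)).astype(float)
        B = rng.poisson(2.0, (60, 60)).astype(float)
        assert ssim_uniform(A, B) == pytest.approx(ssim_uniform(B, A), abs=1e-12)

    def test_matches_reference_ssim(self):
        skimage_metrics = pytest.importorskip("skimage.metrics")
        rng = np.random.default_rng(2)
        A = rng.poisson(3.0, (80, 80)).astype(float)
        B = (A + rng.normal(0, 1.0, A.shape)).clip(0)
        L = max(A.max(), B.max())
        ref = skimage_metrics.structural_similarity(
            A, B, win_size=7, gaussian_weights=False, data_range=L
        )
        assert ssim_uniform(A, B) == pytest.approx(ref, abs=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps_compare(np.zeros((10, 10)), np.zeros((11, 11)))
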