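"""Data-attachment terms: currents, landmarks, appearance model, image energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdas.attachment import (
    AppearanceModel,
    GaussianMixture1D,
    LandmarkSet,
    currents_energy,
    currents_gradient,
    fit_mixture_em,
    histogram_equalize,
    image_energy,
    image_gradient,
    landmark_energy,
    landmark_gradient,
    sigma2_from_voxels,
)
from gdas.image import ScalarImage3D
from gdas.mesh import TriSurface, face_geometry
from gdas.shooting import KernelSpec
from gdas.synthetic import make_template

from .conftest import icosphere


def perturbed_icosphere(rng, scale=0.05):
    s = icosphere(0, 1.0)  # 12 vertices, 20 faces
    return TriSurface(s.vertices + scale * rng.normal(size=s.vertices.shape), s.faces)


class TestCurrents:
    def test_identical_meshes_zero(self, rng):
        s = perturbed_icosphere(rng)
        ks = KernelSpec(0.7)
        self_term = abs(
            currents_energy(s, TriSurface(s.vertices * 3, s.faces), ks)
        )
        assert abs(currents_energy(s, s, ks)) <= 1e-12 * self_term

    def test_symmetry(self, rng):
        a, b = perturbed_icosphere(rng), perturbed_icosphere(rng, 0.1)
        ks = KernelSpec(0.8)
        assert currents_energy(a, b, ks) == pytest.approx(
            currents_energy(b, a, ks), rel=1e-12
        )

    def test_distant_triangles_decouple(self):
        t1 = TriSurface([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        t2 = TriSurface(np.array(t1.vertices) + [50.0 * 0.5, 0, 0], t1.faces)
        ks = KernelSpec(0.5)
        n1 = face_geometry(t1).normals[0]
        n2 = face_geometry(t2).normals[0]
        expected = float(n1 @ n1 + n2 @ n2)
        assert currents_energy(t1, t2, ks) == pytest.approx(expected, abs=1e-10)

    def test_against_naive_double_loop(self, rng):
        a, b = perturbed_icosphere(rng), perturbed_icosphere(rng, 0.08)
        ks = KernelSpec(0.9)

        def naive(s1, s2):
            g1, g2 = face_geometry(s1), face_geometry(s2)
            def pair(ga, gb):
                tot = 0.0
                for i in range(len(ga.normals)):
                    for j in range(len(gb.normals)):
                        d2 = np.sum((ga.centers[i] - gb.centers[j]) ** 2)
                        tot += np.exp(-d2 / (2 * ks.tau**2)) * (
                            ga.normals[i] @ gb.normals[j]
                        )
                return tot
            return pair(g1, g1) - 2 * pair(g1, g2) + pair(g2, g2)

        assert currents_energy(a, b, ks) == pytest.approx(naive(a, b), rel=1e-12)

    def test_retriangulated_patch_nearly_identical_current(self):
        v = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        sA = TriSurface(v, [[0, 1, 2], [0, 2, 3]])
        sB = TriSurface(v, [[0, 1, 3], [1, 2, 3]])
        ks = KernelSpec(20.0)
        g = face_geometry(sA)
        self_term = currents_energy(sA, TriSurface(v + 100.0, sA.faces), ks)
        assert currents_energy(sA, sB, ks) <= 1e-6 * self_term

    def test_gradient_matches_finite_differences(self, rng):
        d, t = perturbed_icosphere(rng), perturbed_icosphere(rng, 0.1)
        ks = KernelSpec(0.8)
        g = currents_gradient(d, t, ks)
        h = 1e-5
        gfd = np.zeros_like(g)
        for i in range(d.n_vertices):
            for c in range(3):
                vp, vm = d.vertices.copy(), d.vertices.copy()
                vp[i, c] += h
                vm[i, c] -= h
                gfd[i, c] = (
                    currents_energy(TriSurface(vp, d.faces), t, ks)
                    - currents_energy(TriSurface(vm, d.faces), t, ks)
                ) / (2 * h)
        assert np.abs(g - gfd).max() <= 1e-5 * np.abs(gfd).max()

    def test_gradient_zero_at_perfect_match(self, rng):
        s = perturbed_icosphere(rng)
        assert np.abs(currents_gradient(s, s, KernelSpec(0.8))).max() <= 1e-10

    def test_translation_equivariance(self, rng):
        d, t = perturbed_icosphere(rng), perturbed_icosphere(rng, 0.1)
        ks = KernelSpec(0.8)
        shift = np.array([3.0, -1.0, 2.0])
        g0 = currents_gradient(d, t, ks)
        g1 = currents_gradient(
            TriSurface(d.vertices + shift, d.faces),
            TriSurface(t.vertices + shift, t.faces),
            ks,
        )
        assert np.abs(g0 - g1).max() <= 1e-10 * max(np.abs(g0).max(), 1.0)


class TestLandmarks:
    def test_perfect_match_zero(self, rng):
        p = rng.normal(size=(5, 3))
        assert landmark_energy(LandmarkSet(p), LandmarkSet(p.copy())) == 0.0

    def test_single_offset(self):
        X = LandmarkSet([[0.0, 0, 0]])
        Y = LandmarkSet([[1.0, 2.0, 2.0]])
        assert landmark_energy(X, Y) == pytest.approx(9.0)

    def test_matches_naive_loop(self, rng):
        X, Y = rng.normal(size=(38, 3)), rng.normal(size=(38, 3))
        naive = sum(float((x - y) @ (x - y)) for x, y in zip(X, Y))
        assert landmark_energy(LandmarkSet(X), LandmarkSet(Y)) == pytest.approx(naive)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            landmark_energy(LandmarkSet(rng.normal(size=(3, 3))),
                            LandmarkSet(rng.normal(size=(4, 3))))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_quadratic_scaling(self, scale):
        X = np.array([[0.0, 0, 0], [1, 1, 0]])
        Y = X + scale * np.array([[1.0, 0, 0], [0, 1.0, 0]])
        e = landmark_energy(LandmarkSet(X), LandmarkSet(Y))
        assert e == pytest.approx(2.0 * scale**2, rel=1e-12)

    def test_gradient_structure_and_fd(self, rng):
        surf = make_template((5.0, 3.0, 2.0), 1)
        idx = np.array([0, 7, 20])
        tlm = LandmarkSet(surf.vertices[idx], idx)
        targets = LandmarkSet(surf.vertices[idx] + rng.normal(size=(3, 3)))
        g = landmark_gradient(surf, tlm, targets)
        off = np.setdiff1d(np.arange(surf.n_vertices), idx)
        assert np.all(g[off] == 0.0)
        assert np.allclose(g[idx], 2 * (surf.vertices[idx] - targets.points))
        h = 1e-6
        for j, vi in enumerate(idx):
            for c in range(3):
                vp, vm = surf.vertices.copy(), surf.vertices.copy()
                vp[vi, c] += h
                vm[vi, c] -= h
                fd = (
                    landmark_energy(LandmarkSet(vp[idx]), targets)
                    - landmark_energy(LandmarkSet(vm[idx]), targets)
                ) / (2 * h)
                assert g[vi, c] == pytest.approx(fd, abs=1e-8 * max(1, abs(fd)))


class TestSigma2:
    @pytest.mark.parametrize(
        "dims,expected",
        [((1, 1, 1), 0.25), ((2, 2, 2), 1.0), ((0.93, 0.93, 2.0), 0.47748333333333334)],
    )
    def test_voxel_rule(self, dims, expected):
        assert sigma2_from_voxels(*dims) == pytest.approx(expected, rel=1e-12)


class TestMixtureEM:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(3.0, 2.0, size=500)
        m, trace = fit_mixture_em(x, 1)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-10)
        assert m.variances[0] == pytest.approx(x.var(), rel=1e-10)  # biased MLE
        assert m.weights[0] == 1.0

    def test_loglik_monotone_every_iteration(self, rng):
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(4, 0.5, 600)])
        _, trace = fit_mixture_em(x, 3)
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))

    def test_two_component_recovery_within_mc_error(self, rng):
        w, mu, sd = (0.4, 0.6), (0.0, 10.0), (1.0, 2.0)
        n = 20000
        comp = rng.choice(2, size=n, p=w)
        x = rng.normal(np.array(mu)[comp], np.array(sd)[comp])
        m, _ = fit_mixture_em(x, 2, seed=0)
        for q in range(2):
            nq = n * w[q]
            assert abs(m.weights[q] - w[q]) <= 3 * np.sqrt(w[q] * (1 - w[q]) / n)
            assert abs(m.means[q] - mu[q]) <= 3 * sd[q] / np.sqrt(nq)
            assert abs(m.variances[q] - sd[q] ** 2) <= 3 * sd[q] ** 2 * np.sqrt(2 / nq)

    def test_against_sklearn_reference(self, rng):
        """Independent EM route: sklearn's GaussianMixture reaches the same
        log-likelihood and parameters on a well-separated problem."""
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(0, 1, 4000), rng.normal(8, 1.5, 6000)])
        mine, _ = fit_mixture_em(x, 2, seed=0)
        ref = GaussianMixture(2, tol=1e-7, max_iter=500, random_state=0).fit(
            x[:, None]
        )
        order = np.argsort(ref.means_.ravel())
        assert np.allclose(mine.means, ref.means_.ravel()[order], atol=0.05)
        assert np.allclose(mine.weights, ref.weights_[order], atol=0.01)
        assert np.allclose(
            mine.variances, ref.covariances_.ravel()[order], rtol=0.05
        )

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mixture_em(rng.normal(size=25), 3)


def _grid_image(shape=(16, 16, 16), spacing=1.0):
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    return aff


class TestHistogramEqualization:
    def test_self_reference_is_identity_on_roi(self, rng):
        data = rng.normal(100, 20, size=(12, 12, 12))
        img = ScalarImage3D(data, _grid_image())
        roi = np.zeros(data.shape, bool)
        roi[3:9, 3:9, 3:9] = True
        out = histogram_equalize(img, data[roi], roi)
        q = np.linspace(0.05, 0.95, 19)
        assert np.abs(
            np.quantile(out.data[roi], q) - np.quantile(data[roi], q)
        ).max() <= 1.0

    def test_inverts_affine_shift(self, rng):
        ref = rng.normal(100, 15, size=5000)
        shifted = 2.0 * ref + 30.0
        data = shifted[: 4096].reshape(16, 16, 16)
        img = ScalarImage3D(data, _grid_image())
        roi = np.ones(data.shape, bool)
        out = histogram_equalize(img, ref, roi)
        q = np.linspace(0.05, 0.95, 19)
        assert np.abs(
            np.quantile(out.data, q) - np.quantile(ref[:4096], q)
        ).max() <= 0.05 * 15

    def test_output_cdf_matches_reference(self, rng):
        data = rng.gamma(4.0, 20.0, size=(14, 14, 14))
        ref = rng.normal(50, 10, size=20000)
        img = ScalarImage3D(data, _grid_image())
        roi = np.ones(data.shape, bool)
        out = histogram_equalize(img, ref, roi)
        xs = np.linspace(20, 80, 200)
        cdf_out = np.searchsorted(np.sort(out.data.ravel()), xs) / out.data.size
        cdf_ref = np.searchsorted(np.sort(ref), xs) / len(ref)
        assert np.abs(cdf_out - cdf_ref).max() <= 2.0 / 256


def _flat_appearance():
    g = GaussianMixture1D([1.0], [50.0], [100.0])
    return AppearanceModel(g, GaussianMixture1D([1.0], [50.0], [100.0]))


class TestImageEnergy:
    def test_identical_mixtures_surface_independent(self, rng):
        surf = make_template((6.0, 4.0, 3.0), 1)
        data = rng.normal(50, 10, size=(24, 24, 24))
        aff = np.eye(4)
        aff[:3, 3] = -12.0
        img = ScalarImage3D(data, aff)
        app = _flat_appearance()
        e1 = image_energy(surf, img, app)
        e2 = image_energy(TriSurface(surf.vertices * 0.8, surf.faces), img, app)
        assert abs(e1 - e2) <= 1e-9 * abs(e1)

    def test_against_naive_per_voxel_loop(self, rng):
        from gdas.mesh import point_inside

        surf = icosphere(0, 3.0)  # 8-ish faces worth of simplicity: 20 faces
        data = rng.normal(60, 5, size=(10, 10, 10))
        aff = np.eye(4)
        aff[:3, 3] = -4.5
        img = ScalarImage3D(data, aff)
        app = AppearanceModel(
            GaussianMixture1D([1.0], [65.0], [25.0]),
            GaussianMixture1D([1.0], [55.0], [25.0]),
        )
        centers = img.voxel_centers_world()
        inside = point_inside(surf, centers)
        lp_ext = app.outside.log_pdf(data.ravel())
        lp_int = app.inside.log_pdf(data.ravel())
        naive = (lp_ext[inside].sum() + lp_int[~inside].sum()) * img.voxel_volume
        assert image_energy(surf, img, app) == pytest.approx(naive, rel=1e-12)

    def test_true_boundary_beats_dilated(self, rng):
        surf = make_template((8.0, 5.0, 4.0), 2)
        app = AppearanceModel(
            GaussianMixture1D([1.0], [100.0], [64.0]),
            GaussianMixture1D([1.0], [30.0], [64.0]),
        )
        from gdas.synthetic import render_t1
        from gdas.voxelize import voxelize

        seg = voxelize(surf, 1.0, padding=4.0)
        img = render_t1(seg, app, seed=2)
        e_true = image_energy(surf, img, app)
        e_dilated = image_energy(TriSurface(surf.vertices * 1.3, surf.faces), img, app)
        assert e_true < e_dilated

    def test_surface_outside_image_rejected(self, rng):
        surf = make_template((8.0, 5.0, 4.0), 1)
        img = ScalarImage3D(np.zeros((5, 5, 5)), _grid_image())
        with pytest.raises(ValueError):
            image_energy(surf, img, _flat_appearance())


class TestImageGradient:
    @staticmethod
    def _smooth_case(subdiv=2, sp=0.4):
        surf = make_template((10.0, 7.0, 6.0), subdiv)
        lo = surf.vertices.min(0) - 4
        hi = surf.vertices.max(0) + 4
        shape = np.ceil((hi - lo) / sp).astype(int) + 1
        aff = np.eye(4)
        aff[:3, :3] *= sp
        aff[:3, 3] = lo
        ii = np.indices(shape).reshape(3, -1).T * sp + lo
        r = np.linalg.norm(ii / np.array([10.0, 7.0, 6.0]), axis=1).reshape(shape)
        img = ScalarImage3D(100.0 - 40.0 * r, aff)
        app = AppearanceModel(
            GaussianMixture1D([1.0], [90.0], [200.0]),
            GaussianMixture1D([1.0], [50.0], [200.0]),
        )
        return surf, img, app

    def test_zero_for_identical_mixtures(self):
        surf, img, _ = self._smooth_case(1)
        g = image_gradient(surf, img, _flat_appearance())
        assert np.abs(g).max() == 0.0

    def test_directional_derivative_matches_voxel_sum(self):
        """Face-center quadrature vs central differences of the voxelized
        energy along a smooth outward perturbation (5% tolerance: the two
        discretizations differ)."""
        surf, img, app = self._smooth_case()
        g = image_gradient(surf, img, app)
        v = surf.vertices / np.linalg.norm(surf.vertices, axis=1, keepdims=True)
        h = 0.2
        ep = image_energy(TriSurface(surf.vertices + h * v, surf.faces), img, app)
        em = image_energy(TriSurface(surf.vertices - h * v, surf.faces), img, app)
        fd = (ep - em) / (2 * h)
        assert float(np.sum(g * v)) == pytest.approx(fd, rel=0.05)

    def test_descent_property(self, rng):
        """A short step along the negative gradient decreases the energy
        from randomized starting shapes."""
        surf, img, app = self._smooth_case(1)
        for _ in range(20):
            start = TriSurface(
                surf.vertices * rng.uniform(0.85, 1.15)
                + 0.3 * rng.normal(size=3),
                surf.faces,
            )
            g = image_gradient(start, img, app)
            step = 0.1 / max(np.linalg.norm(g, axis=1).max(), 1e-12)
            e0 = image_energy(start, img, app)
            e1 = image_energy(
                TriSurface(start.vertices - step * g, start.faces), img, app
            )
            assert e1 <= e0

    def test_refinement_consistency(self):
        """The quadrature's directional derivative converges as the mesh is
        refined (coarse-to-fine differences shrink)."""
        vals = []
        for subdiv in (1, 2, 3):
            surf, img, app = self._smooth_case(subdiv, sp=0.5)
            g = image_gradient(surf, img, app)
            v = surf.vertices / np.linalg.norm(surf.vertices, axis=1, keepdims=True)
            vals.append(float(np.sum(g * v)))
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])
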