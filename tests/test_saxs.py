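import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from saxser.model_io import ConformerModel, ScatteringCurve
from saxser.saxs import (
    SaxsError,
    align_and_nsd,
    chi2,
    compute_profile,
    ensemble_profile,
    guinier_fit,
    kratky_transform,
    optimal_scale,
    pddf_model,
    rg_from_coords,
)
from conftest import gaussian_curve, random_cloud


class TestComputeProfile:
    def test_single_point_flat(self):
        m = ConformerModel(id="one", points=[[1.0, 2.0, 3.0]])
        c = compute_profile(m, np.linspace(0.01, 0.5, 20))
        np.testing.assert_allclose(c.I, 1.0)

    def test_two_points_limits(self, two_point_model):
        c = compute_profile(two_point_model, np.array([1e-9, np.pi / 10.0]))
        assert c.I[0] == pytest.approx(4.0, rel=1e-9)  # I(0) = (Σf)²
        assert c.I[1] == pytest.approx(2.0, rel=1e-9)  # sinc(π) = 0

    def test_forward_intensity_dominates(self):
        m = random_cloud(40, seed=3)
        c = compute_profile(m, np.linspace(1e-6, 0.5, 50))
        total_w = m.weights.sum()
        assert c.I[0] == pytest.approx(total_w**2, rel=1e-6)
        assert np.all(c.I <= c.I[0] + 1e-9)


class TestEnsembleProfile:
    def test_identical_and_weighted_means(self, coarse_q):
        a = ScatteringCurve(q=coarse_q, I=np.zeros_like(coarse_q))
        b = ScatteringCurve(q=coarse_q, I=np.full_like(coarse_q, 4.0))
        same = ensemble_profile([b, b])
        np.testing.assert_allclose(same.I, b.I)
        np.testing.assert_allclose(ensemble_profile([a, b]).I, 2.0)
        np.testing.assert_allclose(ensemble_profile([a, b], [0.25, 0.75]).I, 3.0)

    def test_grid_mismatch(self, coarse_q):
        a = ScatteringCurve(q=coarse_q, I=np.ones_like(coarse_q))
        b = ScatteringCurve(q=coarse_q + 0.001, I=np.ones_like(coarse_q))
        with pytest.raises(SaxsError, match="grid"):
            ensemble_profile([a, b])


class TestScaleAndChi2:
    def test_exact_multiple(self):
        q = np.array([0.1, 0.2, 0.3])
        calc = ScatteringCurve(q=q, I=[1.0, 2.0, 3.0])
        exp = ScatteringCurve(q=q, I=[3.0, 6.0, 9.0], sigma=[0.7, 1.1, 2.0])
        assert optimal_scale(calc, exp) == pytest.approx(3.0)
        assert chi2(calc, exp).chi2 == pytest.approx(0.0, abs=1e-24)

    def test_worked_example(self):
        q = np.array([0.1, 0.2])
        calc = ScatteringCurve(q=q, I=[1.0, 2.0])
        exp = ScatteringCurve(q=q, I=[2.0, 2.0], sigma=[1.0, 1.0])
        fit = chi2(calc, exp)
        assert fit.mu == pytest.approx(1.2)
        assert fit.chi2 == pytest.approx(0.8)
        np.testing.assert_allclose(fit.residuals, [-0.8, 0.4])
        np.testing.assert_allclose(fit.residuals_exp_minus_calc, [0.8, -0.4])
        # chi2 = mean(resid²)·K/(K−1)
        assert fit.chi2 == pytest.approx(np.mean(fit.residuals**2) * fit.K / (fit.K - 1))

    def test_zero_calc_degenerate(self):
        q = np.array([0.1, 0.2])
        calc = ScatteringCurve(q=q, I=[0.0, 0.0])
        exp = ScatteringCurve(q=q, I=[1.0, 1.0], sigma=[1.0, 1.0])
        with pytest.raises(SaxsError, match="zero"):
            optimal_scale(calc, exp)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_mu_matches_grid_search_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        K = 30
        q = np.sort(rng.uniform(0.01, 0.4, K))
        calc = ScatteringCurve(q=q, I=rng.uniform(0.5, 5.0, K))
        exp = ScatteringCurve(
            q=q, I=rng.uniform(0.5, 5.0, K), sigma=rng.uniform(0.05, 0.5, K)
        )
        mu = optimal_scale(calc, exp)
        grid = np.linspace(max(mu * 0.5, 1e-6), mu * 1.5, 20001)
        losses = np.array(
            [np.sum(((g * calc.I - exp.I) / exp.sigma) ** 2) for g in grid[::100]]
        )
        coarse_best = grid[::100][int(np.argmin(losses))]
        assert mu == pytest.approx(coarse_best, rel=1e-2)
        # dense search via the expanded quadratic: same loss, vectorized
        inv_var = 1.0 / exp.sigma**2
        a = np.sum(calc.I**2 * inv_var)
        b = np.sum(calc.I * exp.I * inv_var)
        c = np.sum(exp.I**2 * inv_var)
        dense = a * grid**2 - 2 * b * grid + c
        assert mu == pytest.approx(grid[int(np.argmin(dense))], rel=1e-4)
        # brute-force minimum χ² is never below the analytic one
        assert chi2(calc, exp).chi2 <= dense.min() / (K - 1) + 1e-9
        # free-μ χ² is invariant to positive rescaling of calc
        c = float(rng.uniform(0.1, 10.0))
        scaled = ScatteringCurve(q=q, I=c * calc.I)
        assert chi2(scaled, exp).chi2 == pytest.approx(chi2(calc, exp).chi2, rel=1e-9)


class TestGuinier:
    def test_exact_gaussian(self):
        fit = guinier_fit(gaussian_curve(rg=20.0))
        assert fit.rg == pytest.approx(20.0, rel=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_scaling_leaves_rg(self):
        base = gaussian_curve(rg=20.0)
        scaled = ScatteringCurve(q=base.q, I=5.0 * base.I)
        fit = guinier_fit(scaled)
        assert fit.rg == pytest.approx(20.0, rel=1e-6)
        assert fit.i0 == pytest.approx(500.0, rel=1e-6)

    def test_two_point_model_low_q(self, two_point_model):
        rg_true = rg_from_coords(two_point_model)  # 5 Å
        q = np.linspace(0.005, 1.0 / rg_true, 120)
        curve = compute_profile(two_point_model, q)
        fit = guinier_fit(curve, qrg_max=1.0)
        assert fit.rg == pytest.approx(rg_true, rel=0.02)

    def test_rising_curve_flags_non_globular(self):
        q = np.linspace(0.01, 0.1, 30)
        fit = guinier_fit(ScatteringCurve(q=q, I=1.0 + 10 * q**2))
        assert fit.non_globular


class TestRgFromCoords:
    def test_symmetric_pair(self):
        m = ConformerModel(id="p", points=[[5.0, 0, 0], [-5.0, 0, 0]])
        assert rg_from_coords(m) == pytest.approx(5.0)

    def test_centroid_and_pair_forms_agree(self):
        for seed in range(5):
            m = random_cloud(25, seed=seed)
            w = np.abs(np.random.default_rng(seed).normal(size=25)) + 0.1
            m = ConformerModel(id="w", points=m.points, weights=w)
            W = w.sum()
            diff = m.points[:, None, :] - m.points[None, :, :]
            d2 = np.sum(diff**2, axis=-1)
            pair_form = np.sqrt(np.sum(np.outer(w, w) * d2) / (2 * W**2))
            assert rg_from_coords(m) == pytest.approx(pair_form, abs=1e-9)

    def test_uniform_ball(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(5000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 30.0 * rng.uniform(0, 1, 5000)[:, None] ** (1 / 3)
        rg = rg_from_coords(ConformerModel(id="ball", points=pts))
        assert rg == pytest.approx(np.sqrt(3 / 5) * 30.0, rel=0.01)

    def test_zero_weights_degenerate(self):
        m = ConformerModel(id="z", points=[[0, 0, 0], [1, 0, 0]], weights=[0.0, 0.0])
        with pytest.raises(SaxsError):
            rg_from_coords(m)


class TestPddf:
    def test_two_point_mass_at_distance(self, two_point_model):
        dist = pddf_model([two_point_model], n_bins=20)
        assert dist.dmax == pytest.approx(10.0)
        peak_bin = np.argmax(dist.p)
        assert dist.r[peak_bin] == pytest.approx(10.0, abs=dist.r[2] - dist.r[1])

    def test_unit_integral_and_rg_identity(self):
        for seed in (0, 1, 2):
            m = random_cloud(30, seed=seed)
            dist = pddf_model([m], n_bins=400)
            assert np.trapezoid(dist.p, dist.r) == pytest.approx(1.0, abs=1e-9)
            n = len(m)
            rg2_from_pddf = ((n - 1) / n) * 0.5 * dist.moment(2)
            assert np.sqrt(rg2_from_pddf) == pytest.approx(
                rg_from_coords(m), rel=0.01
            )

    def test_single_point_models_error(self):
        m = ConformerModel(id="one", points=[[0, 0, 0]])
        with pytest.raises(SaxsError, match="pairs"):
            pddf_model([m])


class TestKratky:
    def test_constant_curve(self, coarse_q):
        c = ScatteringCurve(q=coarse_q, I=np.full_like(coarse_q, 7.0))
        k = kratky_transform(c)
        np.testing.assert_allclose(k.I, 7.0 * coarse_q**2)

    def test_globular_curve_has_interior_maximum(self):
        q = np.linspace(0.005, 0.4, 200)
        k = kratky_transform(ScatteringCurve(q=q, I=100 * np.exp(-(q**2) * 400 / 3)))
        peak = np.argmax(k.I)
        assert 0 < peak < len(q) - 1

    def test_coil_plateau(self):
        rg, i0 = 30.0, 50.0
        q = np.linspace(8.0 / rg, 12.0 / rg, 100)  # qRg in [8, 12]
        x = q**2 * rg**2
        I = i0 * 2 * (np.exp(-x) + x - 1) / x**2
        k = kratky_transform(ScatteringCurve(q=q, I=I))
        plateau = 2 * i0 / rg**2
        assert np.all(np.abs(k.I - plateau) / plateau < 0.02)

    def test_sigma_propagation(self, coarse_q):
        c = ScatteringCurve(
            q=coarse_q, I=np.ones_like(coarse_q), sigma=np.full_like(coarse_q, 0.5)
        )
        k = kratky_transform(c)
        np.testing.assert_allclose(k.sigma, 0.5 * coarse_q**2)


def _nsd_direct(pa, pb):
    from scipy.spatial import cKDTree

    def nn2(p):
        d, _ = cKDTree(p).query(p, k=2)
        return np.mean(d[:, 1]) ** 2

    da2, db2 = nn2(pa), nn2(pb)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return np.sqrt(0.5 * (np.mean(d_ab**2) / db2 + np.mean(d_ba**2) / da2))


class TestNsd:
    def test_identity_is_zero(self):
        m = random_cloud(15, seed=5)
        value, _ = align_and_nsd(m, m)
        assert value == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        m = random_cloud(20, seed=6)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ConformerModel(id="mv", points=m.points @ R.T + np.array([50.0, 0, 0]))
        value, transform = align_and_nsd(m, moved)
        assert value == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(transform.apply(moved.points), m.points, atol=1e-4)

    def test_symmetry(self):
        a = random_cloud(12, seed=7)
        b = random_cloud(14, seed=8)
        v_ab, _ = align_and_nsd(a, b)
        v_ba, _ = align_and_nsd(b, a)
        assert v_ab == pytest.approx(v_ba, abs=1e-6)
        assert v_ab > 0

    def test_matches_rotation_grid_oracle(self):
        a = ConformerModel(
            id="a", points=np.array([[0, 0, 0], [10, 0, 0], [0, 8, 0], [0, 0, 6.0]])
        )
        b = ConformerModel(
            id="b", points=np.array([[1, 1, 0], [9, 0, 2], [0, 7, 1], [1, 0, 6.0]])
        )
        value, _ = align_and_nsd(a, b)
        # oracle: dense SO(3) grid (both enantiomers), centroid-superposed,
        # then Nelder-Mead polish of the best grid point
        from scipy.optimize import minimize

        pa = a.points - a.points.mean(axis=0)
        best = np.inf
        grid = np.linspace(0, 2 * np.pi, 25, endpoint=False)
        half = np.linspace(0, np.pi, 13)
        for mirror in (1.0, -1.0):
            pb0 = b.points * np.array([1.0, 1.0, mirror])
            pb0 = pb0 - pb0.mean(axis=0)
            for ai in grid:
                for bi in half:
                    for ci in grid:
                        R = Rotation.from_euler("zyz", [ai, bi, ci]).as_matrix()
                        v = _nsd_direct(pa, pb0 @ R.T)
                        if v < best:
                            best, args = v, (pb0, R)
        pb0, R = args

        def obj(x):
            Rl = Rotation.from_rotvec(x[:3]).as_matrix()
            return _nsd_direct(pa, pb0 @ (Rl @ R).T + x[3:])

        res = minimize(obj, np.zeros(6), method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10})
        oracle = min(best, res.fun)
        assert value == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_models_rejected(self):
        line = ConformerModel(id="line", points=[[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        other = random_cloud(5, seed=9)
        with pytest.raises(SaxsError, match="degenerate|2 points"):
            align_and_nsd(line, other)
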