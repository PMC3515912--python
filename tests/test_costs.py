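import numpy as np
import pytest

import lungreg as lr
from lungreg.costs import (
    CostContext,
    CostWeights,
    cost_elastic,
    cost_mi,
    cost_ncc,
    cost_ssd,
    cost_sstvd,
    cost_ssvmd,
    domain_union,
    histogram_match,
    total_cost_and_gradient,
)

from conftest import bounded_random_transform


def vol_of(values, spacing=(1, 1, 1)):
    return lr.ImageVolume(np.asarray(values, dtype=float), spacing, (0, 0, 0))


def full_mask(vol):
    return lr.BinaryMask(np.ones(vol.shape), vol.spacing, vol.origin)


def identity_for(vol, spacing=8.0):
    return lr.BSplineTransform.for_volume(vol, (spacing,) * 3)


def single_voxel_mask(vol, idx=(3, 3, 3)):
    m = np.zeros(vol.shape)
    m[idx] = 1.0
    return lr.BinaryMask(m, vol.spacing, vol.origin)


def linear_scaling_transform(vol, s):
    """u(x) = s*x via linear-precision coefficients; J = (1+s)^3 exactly."""
    T = identity_for(vol)
    for a in range(3):
        pos = T.control_positions(a)
        shape = [1, 1, 1]
        shape[a] = -1
        T.coefficients[..., a] = s * pos.reshape(shape)
    return T


class TestDomainUnion:
    def test_identity_identical_masks(self, rng):
        vol = vol_of(np.zeros((8, 8, 8)))
        vals = (rng.random((8, 8, 8)) < 0.5).astype(float)
        vals[4, 4, 4] = 1.0
        m = lr.BinaryMask(vals, vol.spacing, vol.origin)
        omega = domain_union(m, m, identity_for(vol))
        assert np.array_equal(omega.values, m.values)

    def test_disjoint_masks_or(self):
        vol = vol_of(np.zeros((8, 8, 8)))
        a = np.zeros((8, 8, 8)); a[:4] = 1
        b = np.zeros((8, 8, 8)); b[4:] = 1
        ma = lr.BinaryMask(a, vol.spacing, vol.origin)
        mb = lr.BinaryMask(b, vol.spacing, vol.origin)
        omega = domain_union(ma, mb, identity_for(vol))
        assert np.all(omega.values == 1.0)

    def test_shifted_mask_against_brute_force(self, rng):
        vol = vol_of(np.zeros((16, 16, 16)))
        T = bounded_random_transform(vol, 8.0, seed=5)
        vals = np.zeros((16, 16, 16))
        vals[5:11, 5:11, 5:11] = 1.0
        tmask = lr.BinaryMask(vals, vol.spacing, vol.origin)
        omega = domain_union(tmask, tmask, T)
        # brute force: voxel in omega iff in target mask or h(x) rounds into it
        expect = np.zeros((16, 16, 16), dtype=bool)
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    x = np.array([[i, j, k]], dtype=float)
                    hx = np.rint(T(x)[0]).astype(int)
                    inside = np.all((hx >= 0) & (hx < 16))
                    expect[i, j, k] = bool(vals[i, j, k]) or (
                        inside and bool(vals[hx[0], hx[1], hx[2]])
                    )
        assert np.array_equal(omega.values.astype(bool), expect)


class TestHistogramMatch:
    def test_match_to_self_is_identity(self, rng):
        src = vol_of(rng.normal(-800, 100, (12, 12, 12)))
        out = histogram_match(src, src)
        assert np.abs(out.values - src.values).max() < 1e-9

    def test_pure_shift_recovers_reference_quantiles(self, rng):
        ref = vol_of(rng.normal(-800, 100, (16, 16, 16)))
        src = vol_of(ref.values + 100.0)
        out = histogram_match(src, ref, match_points=15)
        qs = np.linspace(0.05, 0.95, 9)
        assert np.abs(np.quantile(out.values, qs) - np.quantile(ref.values, qs)).max() < 2.0

    def test_mapping_monotone(self, rng):
        src = vol_of(rng.normal(0, 50, (10, 10, 10)))
        ref = vol_of(rng.gamma(2.0, 30.0, (10, 10, 10)))
        out = histogram_match(src, ref)
        order = np.argsort(src.values.ravel())
        mapped = out.values.ravel()[order]
        assert np.all(np.diff(mapped) >= -1e-12)

    def test_constant_source_warns(self):
        src = vol_of(np.full((8, 8, 8), 5.0))
        ref = vol_of(np.arange(512, dtype=float).reshape(8, 8, 8))
        with pytest.warns(UserWarning, match="constant"):
            out = histogram_match(src, ref)
        assert np.all(out.values == 5.0)


class TestSSD:
    def test_identical_images_zero(self, rng):
        vol = vol_of(rng.normal(-800, 50, (12, 12, 12)))
        assert cost_ssd(vol, vol, identity_for(vol), full_mask(vol)) == pytest.approx(0.0, abs=1e-12)

    def test_two_voxel_hand_sum(self):
        i2 = vol_of(np.full((8, 8, 8), 0.0))
        i1 = vol_of(np.full((8, 8, 8), 0.0))
        i2.values[3, 3, 3] = -500.0
        i2.values[3, 3, 4] = -600.0
        i1.values[3, 3, 3] = -400.0
        i1.values[3, 3, 4] = -600.0
        m = np.zeros((8, 8, 8))
        m[3, 3, 3] = m[3, 3, 4] = 1.0
        omega = lr.BinaryMask(m, i2.spacing, i2.origin)
        # identity: samples land exactly on voxel centres
        assert cost_ssd(i1, i2, identity_for(i1), omega) == pytest.approx(10000.0)

    def test_nonnegative(self, phantom32):
        T = bounded_random_transform(phantom32.target, 8.0, seed=2)
        omega = domain_union(phantom32.target_mask, phantom32.template_mask, T)
        assert cost_ssd(phantom32.template, phantom32.target, T, omega) >= 0.0


class TestNCC:
    def test_proportional_images_give_minus_one(self, rng):
        i2 = vol_of(rng.uniform(1, 100, (10, 10, 10)))
        i1 = vol_of(2.0 * i2.values)
        got = cost_ncc(i1, i2, identity_for(i1), full_mask(i1))
        assert got == pytest.approx(-1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((10, 10, 10)); a[:5] = 7.0
        b = np.zeros((10, 10, 10)); b[5:] = 3.0
        i1, i2 = vol_of(a), vol_of(b)
        got = cost_ncc(i1, i2, identity_for(i1), full_mask(i1))
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_cauchy_schwarz(self, phantom32):
        T = bounded_random_transform(phantom32.target, 8.0, seed=3)
        omega = domain_union(phantom32.target_mask, phantom32.template_mask, T)
        got = cost_ncc(phantom32.template, phantom32.target, T, omega)
        assert -1.0 <= got <= 1.0


class TestSSTVD:
    def test_identity_zero(self, rng):
        vol = vol_of(rng.uniform(-900, -700, (12, 12, 12)))
        w = CostWeights(chi=0, gamma_reg=0)
        assert cost_sstvd(vol, vol, identity_for(vol), full_mask(vol), w) == pytest.approx(0.0, abs=1e-12)

    def test_mass_conserving_voxel_is_zero(self):
        # v2 = 1 mm^3, I2 = -500, I1(h(x)) = -750, J = 2:
        # [500/1055 - 2*250/1055]^2 = 0
        s = 2.0 ** (1.0 / 3.0) - 1.0  # (1+s)^3 = 2 exactly
        i2 = vol_of(np.full((8, 8, 8), -500.0))
        i1 = vol_of(np.full((8, 8, 8), -750.0))
        T = linear_scaling_transform(i1, s)
        omega = single_voxel_mask(i2)
        got = cost_sstvd(i1, i2, T, omega)
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_identity_jacobian_voxel_value(self):
        # same voxel with J = 1: [(500 - 250)/1055]^2
        i2 = vol_of(np.full((8, 8, 8), -500.0))
        i1 = vol_of(np.full((8, 8, 8), -750.0))
        omega = single_voxel_mask(i2)
        got = cost_sstvd(i1, i2, identity_for(i1), omega)
        assert got == pytest.approx((250.0 / 1055.0) ** 2, rel=1e-12)
        assert got == pytest.approx(0.05615, abs=1e-4)


class TestSSVMD:
    def test_identical_fields_zero(self, rng):
        f = vol_of(rng.uniform(0, 1, (10, 10, 10)))
        assert cost_ssvmd(f, f, identity_for(f), full_mask(f)) == pytest.approx(0.0, abs=1e-12)

    def test_vessel_to_tissue_mismatch_maximal(self):
        f2 = vol_of(np.zeros((8, 8, 8)))
        f1 = vol_of(np.zeros((8, 8, 8)))
        f2.values[3, 3, 3] = 1.0  # vessel in target, tissue in template
        omega = single_voxel_mask(f2)
        got = cost_ssvmd(f1, f2, identity_for(f1), omega)
        assert got == pytest.approx(1.0)

    def test_three_voxel_hand_sum(self):
        f2 = vol_of(np.full((8, 8, 8), 0.5))
        f1 = vol_of(np.full((8, 8, 8), 0.5))
        f2.values[3, 3, 3] = 1.0
        f2.values[3, 3, 4] = 0.5
        f2.values[3, 3, 5] = 0.0
        m = np.zeros((8, 8, 8)); m[3, 3, 3:6] = 1.0
        omega = lr.BinaryMask(m, f2.spacing, f2.origin)
        got = cost_ssvmd(f1, f2, identity_for(f1), omega)
        assert got == pytest.approx(0.5)

    def test_out_of_range_fields_rejected(self):
        bad = vol_of(np.full((8, 8, 8), 1.5))
        ok = vol_of(np.full((8, 8, 8), 0.5))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            cost_ssvmd(bad, ok, identity_for(ok), full_mask(ok))


class TestMI:
    def test_hard_window_identity_equals_entropy(self, rng):
        vals = rng.normal(-800, 80, (16, 16, 16))
        vol = vol_of(vals)
        got = cost_mi(vol, vol, identity_for(vol), full_mask(vol), window="hard")
        counts, _ = np.histogram(vals, bins=50)
        p = counts / counts.sum()
        H = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert got == pytest.approx(-H, rel=1e-12)

    def test_spline_window_matches_brute_force(self, rng):
        # independent re-evaluation of the Parzen estimator definition
        from lungreg.bspline import bspline_basis
        vals1 = rng.normal(-800, 80, (10, 10, 10))
        vals2 = vals1 + rng.normal(0, 20, (10, 10, 10))
        i1, i2 = vol_of(vals1), vol_of(vals2)
        got = cost_mi(i1, i2, identity_for(i1), full_mask(i1), window="spline")
        nb = 50
        m = vals1.ravel()  # identity: exact voxel-centre samples
        f = vals2.ravel()
        j = np.clip(((f - f.min()) / (f.max() - f.min()) * nb).astype(int), 0, nb - 1)
        kappa = 2.0 + (m - vals1.min()) * (nb - 4) / (vals1.max() - vals1.min())
        P = np.zeros((nb, nb))
        for kv, jv in zip(kappa, j):
            for i in range(int(np.floor(kv)) - 1, int(np.floor(kv)) + 3):
                if 0 <= i < nb:
                    P[i, jv] += bspline_basis(kv - i)
        P /= P.sum()
        p1, p2 = P.sum(1), P.sum(0)
        pos = P > 0
        expected = -np.sum(P[pos] * np.log(P[pos] / np.outer(p1, p2)[pos]))
        assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_noise_near_zero(self, seed):
        gen = np.random.default_rng(seed)
        i1 = vol_of(gen.uniform(0, 100, (64, 64, 64)))
        i2 = vol_of(gen.uniform(0, 100, (64, 64, 64)))
        got = cost_mi(i1, i2, identity_for(i1, 16.0), full_mask(i1))
        assert abs(got) < 0.02

    def test_information_inequality(self, phantom32):
        T = bounded_random_transform(phantom32.target, 8.0, seed=9)
        omega = domain_union(phantom32.target_mask, phantom32.template_mask, T)
        got = cost_mi(phantom32.template, phantom32.target, T, omega)
        h = []
        for vol in (phantom32.template, phantom32.target):
            counts, _ = np.histogram(vol.values[omega.bool_values], bins=50)
            p = counts / counts.sum()
            h.append(-np.sum(p[p > 0] * np.log(p[p > 0])))
        assert -min(h) - 0.05 <= got <= 0.0

    def test_constant_image_returns_zero(self):
        const = vol_of(np.full((8, 8, 8), -700.0))
        other = vol_of(np.arange(512, dtype=float).reshape(8, 8, 8))
        got = cost_mi(const, other, identity_for(const), full_mask(const))
        assert got == 0.0


class TestElastic:
    def test_zero_displacement_zero_cost(self):
        vol = vol_of(np.zeros((12, 12, 12)))
        w = CostWeights()
        assert cost_elastic(identity_for(vol), full_mask(vol), w) == 0.0

    def test_constant_displacement_gamma_term_only(self):
        # u = c: derivatives vanish, cost = gamma_el^2 ||c||^2 * volume(Omega)
        vol = vol_of(np.zeros((12, 12, 12)))
        T = identity_for(vol)
        c = np.array([0.5, -0.25, 1.0])
        T.coefficients[:] = c
        w = CostWeights(alpha_el=1.0, beta_el=1.0, gamma_el=0.3)
        omega = full_mask(vol)
        got = cost_elastic(T, omega, w)
        expected = 0.3**2 * np.dot(c, c) * 12**3  # unit voxels
        assert got == pytest.approx(expected, rel=1e-9)

    def test_operator_matches_finite_differences(self, rng):
        # central differences of u at random interior points (small step;
        # voxel-sized steps would straddle knot planes where the spline's
        # third derivative jumps)
        vol = vol_of(np.zeros((16, 16, 16)))
        T = bounded_random_transform(vol, 8.0, seed=13)
        w = CostWeights(alpha_el=1.0, beta_el=1.0, gamma_el=0.01)
        pts = rng.uniform(3, 13, (100, 3))
        h = 0.05
        u = T.displacement(pts)
        eye = np.eye(3)

        def d2(a, b):
            if a == b:
                return (
                    T.displacement(pts + h * eye[a]) - 2 * u
                    + T.displacement(pts - h * eye[a])
                ) / h**2
            return (
                T.displacement(pts + h * (eye[a] + eye[b]))
                - T.displacement(pts + h * (eye[a] - eye[b]))
                - T.displacement(pts - h * (eye[a] - eye[b]))
                + T.displacement(pts - h * (eye[a] + eye[b]))
            ) / (4 * h**2)

        lap_fd = sum(d2(b, b) for b in range(3))
        graddiv_fd = np.stack(
            [sum(d2(a, b)[:, b] for b in range(3)) for a in range(3)], axis=-1
        )
        lu_fd = -w.alpha_el * lap_fd - w.beta_el * graddiv_fd + w.gamma_el * u

        # analytic L u at the same points, via a tiny grid anchored at each p
        from lungreg.bspline import LatticeBasis
        lu_an = np.empty_like(lu_fd)
        for i, p in enumerate(pts):
            g = lr.ImageVolume(np.zeros((4, 4, 4)), (0.5, 0.5, 0.5), p)
            basis = LatticeBasis(T, g)
            second = {}
            for a in range(3):
                for b in range(a, 3):
                    derivs = [0, 0, 0]
                    derivs[a] += 1
                    derivs[b] += 1
                    second[(a, b)] = basis.field(T.coefficients, tuple(derivs))
            lap = second[(0, 0)] + second[(1, 1)] + second[(2, 2)]
            gd = np.stack(
                [sum(second[(min(a, b), max(a, b))][..., b] for b in range(3))
                 for a in range(3)], axis=-1,
            )
            uu = basis.field(T.coefficients)
            lu = -w.alpha_el * lap - w.beta_el * gd + w.gamma_el * uu
            lu_an[i] = lu[0, 0, 0]  # grid origin sits exactly at p
        assert np.abs(lu_an - lu_fd).max() / np.abs(lu_fd).max() < 1e-2


class TestTotalCost:
    def test_breakdown_linearity_and_invariant(self, phantom32):
        T = bounded_random_transform(phantom32.target, 8.0, seed=21)
        F1 = lr.multiscale_vesselness(phantom32.template)
        F2 = lr.multiscale_vesselness(phantom32.target)
        for chi in (0.5, 1.0):
            w = CostWeights(chi=chi, gamma_reg=0.2)
            bd, grad = total_cost_and_gradient(
                phantom32.template, phantom32.target, F1, F2,
                phantom32.target_mask, phantom32.template_mask, T, w, "sstvd",
            )
            assert bd.total == pytest.approx(
                bd.intensity_term + chi * bd.ssvmd_term + 0.2 * bd.reg_term, rel=1e-9
            )
            assert grad.shape == T.coefficients.shape
        # doubling chi doubles the SSVMD contribution to the total
        w1 = CostWeights(chi=1.0, gamma_reg=0.0)
        w2 = CostWeights(chi=2.0, gamma_reg=0.0)
        omega = domain_union(phantom32.target_mask, phantom32.template_mask, T)
        bd1, _ = total_cost_and_gradient(
            phantom32.template, phantom32.target, F1, F2,
            phantom32.target_mask, phantom32.template_mask, T, w1, "ssd", omega=omega,
        )
        bd2, _ = total_cost_and_gradient(
            phantom32.template, phantom32.target, F1, F2,
            phantom32.target_mask, phantom32.template_mask, T, w2, "ssd", omega=omega,
        )
        assert (bd2.total - bd2.intensity_term) == pytest.approx(
            2.0 * (bd1.total - bd1.intensity_term), rel=1e-9
        )

    def test_identical_images_identity_is_stationary(self, rng):
        vals = rng.normal(-800, 60, (16, 16, 16))
        vol = vol_of(vals)
        f = vol_of(np.clip(rng.uniform(0, 1, (16, 16, 16)), 0, 1))
        mask = full_mask(vol)
        T = identity_for(vol)
        w = CostWeights(chi=1.0, gamma_reg=0.1)
        bd, grad = total_cost_and_gradient(vol, vol, f, f, mask, mask, T, w, "ssd")
        assert bd.total == pytest.approx(0.0, abs=1e-9)
        assert np.abs(grad).max() < 1e-8

    def test_unknown_metric_rejected(self, phantom32):
        T = identity_for(phantom32.target)
        with pytest.raises(ValueError, match="unknown metric"):
            total_cost_and_gradient(
                phantom32.template, phantom32.target, None, None,
                phantom32.target_mask, phantom32.template_mask, T,
                CostWeights(chi=0, gamma_reg=0), "ssdd",
            )

    def test_empty_omega_rejected(self, phantom32):
        T = identity_for(phantom32.target)
        empty = np.zeros(phantom32.target.shape)
        empty[0, 0, 0] = 1.0  # mask invariant needs one voxel; clear after
        omega = lr.BinaryMask(empty, phantom32.target.spacing, phantom32.target.origin)
        omega.values[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="empty"):
            CostContext(
                phantom32.template, phantom32.target, omega, T,
                CostWeights(chi=0, gamma_reg=0), "ssd",
            )
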