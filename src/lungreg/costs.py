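"""Similarity and regularization cost terms and their coefficient gradients.

The total registration objective is

    C_total(h) = C_intensity + chi * C_SSVMD + gamma_reg * C_REG

where C_intensity is one of SSD, (negative) MI, (negative) NCC or SSTVD,
C_SSVMD compares Frangi vesselness fields, and C_REG penalizes
``||L u||^2`` with the linear-elastic operator
``L u = -alpha_el lap(u) - beta_el grad(div u) + gamma_el u``.

All sums run over the voxels of Omega, the union of the target lung region
and the warped template lung region, and the squared-difference costs are
scaled by the voxel volume (mm^3) so values are comparable across pyramid
levels.  Gradients with respect to the B-spline coefficients are analytic:
fields of per-voxel adjoint quantities are scattered back onto the control
lattice through the same separable basis matrices used for evaluation
(including the dependence of the Jacobian determinant on the coefficients in
SSTVD).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .bspline import BSplineTransform, LatticeBasis, bspline_basis
from .sampling import SplineImage
from .volumes import BinaryMask, ImageVolume

__all__ = [
    "CostWeights",
    "CostBreakdown",
    "CostContext",
    "domain_union",
    "histogram_match",
    "cost_ssd",
    "cost_mi",
    "cost_ncc",
    "cost_sstvd",
    "cost_ssvmd",
    "cost_elastic",
    "total_cost_and_gradient",
]

METRICS = ("ssd", "mi", "ncc", "sstvd")


@dataclass
class CostWeights:
    """Weights and physical constants of the total cost.

    chi scales the vesselness term, gamma_reg the elastic term;
    alpha_el/beta_el/gamma_el are the elastic operator coefficients.  hu_air
    and tissue_denominator define the air/tissue mixture model used by SSTVD
    (tissue fraction = (HU - hu_air) / tissue_denominator).
    """

    chi: float = 1.0
    gamma_reg: float = 0.1
    alpha_el: float = 1.0
    beta_el: float = 1.0
    gamma_el: float = 0.01
    hu_air: float = -1000.0
    tissue_denominator: float = 1055.0

    def __post_init__(self):
        if self.chi < 0 or self.gamma_reg < 0:
            raise ValueError("chi and gamma_reg must be >= 0")
        if min(self.alpha_el, self.beta_el, self.gamma_el) < 0:
            raise ValueError("elastic coefficients must be >= 0")
        if self.gamma_reg > 0 and self.alpha_el + self.beta_el + self.gamma_el == 0:
            raise ValueError("elastic coefficients must not all be zero")


@dataclass
class CostBreakdown:
    intensity_term: float
    ssvmd_term: float
    reg_term: float
    total: float
    metric: str


def _require_same_lattice(a: ImageVolume, b: ImageVolume) -> None:
    if not a.same_grid(b):
        raise ValueError("volumes/masks must share shape, spacing and origin")


def _grid_points(vol: ImageVolume) -> np.ndarray:
    """(N, 3) world coordinates of all voxel centres."""
    axes = [vol.axis_coords(a) for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([c.ravel() for c in g], axis=1)


def domain_union(
    target_mask: BinaryMask, template_mask: BinaryMask, T: BSplineTransform
) -> BinaryMask:
    """Omega: target lung voxels plus voxels whose h(x) falls in the template lung."""
    _require_same_lattice(target_mask, template_mask)
    basis = LatticeBasis(T, target_mask)
    u = basis.field(T.coefficients).reshape(-1, 3)
    pts = _grid_points(target_mask) + u
    idx = np.rint((pts - template_mask.origin) / template_mask.spacing).astype(int)
    n = np.array(template_mask.shape)
    ok = np.all((idx >= 0) & (idx < n), axis=1)
    warped = np.zeros(len(pts), dtype=bool)
    warped[ok] = template_mask.values[idx[ok, 0], idx[ok, 1], idx[ok, 2]] > 0
    union = target_mask.bool_values | warped.reshape(target_mask.shape)
    return BinaryMask(union.astype(float), target_mask.spacing, target_mask.origin)


def histogram_match(
    src: ImageVolume, ref: ImageVolume, levels: int = 1024, match_points: int = 7
) -> ImageVolume:
    """Monotone quantile mapping of src intensities onto ref's distribution.

    Quantiles at ``match_points`` evenly spaced probabilities (including the
    extremes) are matched exactly; intermediate intensities are linearly
    interpolated between matched quantiles.  ``levels`` caps the quantile
    resolution and is validated per the levels >= match_points >= 2 contract.
    """
    if match_points < 2 or levels < match_points:
        raise ValueError("need levels >= match_points >= 2")
    if np.ptp(src.values) == 0:
        warnings.warn("histogram_match: constant source image returned unchanged")
        return ImageVolume(src.values.copy(), src.spacing, src.origin)
    qs = np.linspace(0.0, 1.0, match_points)
    src_q = np.quantile(src.values, qs)
    ref_q = np.quantile(ref.values, qs)
    # np.interp requires strictly usable xp; collapse duplicate source quantiles
    keep = np.concatenate([[True], np.diff(src_q) > 0])
    mapped = np.interp(src.values, src_q[keep], ref_q[keep])
    return ImageVolume(mapped, src.spacing, src.origin)


# ---------------------------------------------------------------------------
# evaluation context
# ---------------------------------------------------------------------------

class CostContext:
    """Per-level bundle of images, masks, interpolators and basis matrices.

    Built once per resolution level; ``evaluate`` maps a coefficient array to
    the cost breakdown and (optionally) its gradient.  The grid geometry is
    the target image lattice.
    """

    def __init__(
        self,
        template: ImageVolume,
        target: ImageVolume,
        omega: BinaryMask,
        transform: BSplineTransform,
        weights: CostWeights,
        metric: str,
        vesselness_template: ImageVolume | None = None,
        vesselness_target: ImageVolume | None = None,
        interp_order: int = 3,
        mi_bins: int = 50,
    ):
        metric = metric.lower()
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
        _require_same_lattice(target, omega)
        self.metric = metric
        self.w = weights
        self.target = target
        self.omega = omega.bool_values.ravel()
        if not self.omega.any():
            raise ValueError("Omega is empty")
        self.grid = target
        self.basis = LatticeBasis(transform, target)
        self.lattice_shape = transform.lattice_shape
        self.pts = _grid_points(target)[self.omega]
        self.v2 = target.voxel_volume
        self.i2 = target.values.ravel()[self.omega]
        self.interp = SplineImage(template, order=interp_order, background=weights.hu_air)
        self.mi_bins = mi_bins
        if weights.chi > 0:
            if vesselness_template is None or vesselness_target is None:
                raise ValueError("chi > 0 requires vesselness fields for both images")
            _validate_vesselness(vesselness_template.values)
            _validate_vesselness(vesselness_target.values)
            self.f2 = vesselness_target.values.ravel()[self.omega]
            self.f_interp = SplineImage(vesselness_template, order=interp_order, background=0.0)
        else:
            self.f2 = None
            self.f_interp = None
        # fixed per-level intensity ranges for MI
        if metric == "mi":
            self._mi_fixed_range = (float(self.i2.min()), float(self.i2.max()))
            tvals = template.values
            self._mi_moving_range = (float(tvals.min()), float(tvals.max()))

    # -- helpers -------------------------------------------------------------

    def _warp(self, coefficients: np.ndarray):
        u = self.basis.field(coefficients).reshape(-1, 3)[self.omega]
        return self.pts + u

    def _jacobian_data(self, coefficients: np.ndarray):
        D = self.basis.displacement_gradient(coefficients).reshape(-1, 3, 3)[self.omega]
        F = D + np.eye(3)
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        return J, Finv

    # -- metric terms ---------------------------------------------------------

    def _intensity(self, m, gm, coefficients, need_grad):
        """Return (value, dC/dm, jac_adjoint) for the active metric.

        jac_adjoint is None except for SSTVD, where it is the per-voxel
        dC/dJ * J * Finv (3x3) matrix used in the Jacobian chain rule.
        """
        w = self.w
        if self.metric == "ssd":
            diff = self.i2 - m
            value = self.v2 * float(np.dot(diff, diff))
            dm = -2.0 * self.v2 * diff if need_grad else None
            return value, dm, None
        if self.metric == "ncc":
            b = float(np.dot(self.i2, self.i2))
            c = float(np.dot(m, m))
            if b == 0.0 or c == 0.0:
                raise ValueError("NCC undefined: an image is identically zero on Omega")
            a = float(np.dot(self.i2, m))
            value = -a / np.sqrt(b * c)
            dm = None
            if need_grad:
                dm = -self.i2 / np.sqrt(b * c) + a * m / (np.sqrt(b) * c**1.5)
            return value, dm, None
        if self.metric == "sstvd":
            J, Finv = self._jacobian_data(coefficients)
            k = self.v2 / w.tissue_denominator
            i2c = np.maximum(self.i2, w.hu_air)
            mc = np.maximum(m, w.hu_air)
            r = k * (i2c - w.hu_air) - k * J * (mc - w.hu_air)
            value = float(np.dot(r, r))
            if not need_grad:
                return value, None, None
            dm = -2.0 * r * k * J
            dm[m < w.hu_air] = 0.0
            dj = -2.0 * r * k * (mc - w.hu_air)
            jac_adjoint = (dj * J)[:, None, None] * Finv
            return value, dm, jac_adjoint
        # mi
        return self._mi(m, need_grad)

    def _mi(self, m, need_grad):
        nb = self.mi_bins
        lo2, hi2 = self._mi_fixed_range
        lo1, hi1 = self._mi_moving_range
        n = m.shape[0]
        if hi2 <= lo2 or hi1 <= lo1:
            return 0.0, (np.zeros_like(m) if need_grad else None), None
        j = np.clip(((self.i2 - lo2) / (hi2 - lo2) * nb).astype(int), 0, nb - 1)
        scale = (nb - 4) / (hi1 - lo1)
        kappa = 2.0 + (m - lo1) * scale
        clamped = (kappa < 2.0) | (kappa > nb - 2.0)
        kappa = np.clip(kappa, 2.0, float(nb - 2))
        base = np.floor(kappa).astype(int)
        offs = np.arange(-1, 3)
        taps = np.clip(base[:, None] + offs[None, :], 0, nb - 1)  # (n, 4)
        wm = bspline_basis(kappa[:, None] - (base[:, None] + offs[None, :]))
        P = np.zeros((nb, nb))
        np.add.at(P, (taps.ravel(), np.repeat(j, 4)), wm.ravel())
        P /= n
        p1 = P.sum(axis=1)
        p2 = P.sum(axis=0)
        pos = P > 0
        denom = np.outer(p1, p2)
        value = -float(np.sum(P[pos] * np.log(P[pos] / denom[pos])))
        if not need_grad:
            return value, None, None
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.where(pos, np.log(np.where(pos, P, 1.0) / p1[:, None]), 0.0)
        dwm = bspline_basis(kappa[:, None] - (base[:, None] + offs[None, :]), deriv=1)
        dm = -(scale / n) * np.sum(dwm * L[taps, j[:, None]], axis=1)
        dm[clamped] = 0.0
        return value, dm, None

    def _ssvmd(self, pts, need_grad):
        if need_grad:
            vf, gf = self.f_interp.sample(pts, gradient=True)
        else:
            vf, gf = self.f_interp.sample(pts), None
        diff = self.f2 - vf
        value = self.v2 * float(np.dot(diff, diff))
        dvf = -2.0 * self.v2 * diff if need_grad else None
        return value, dvf, gf

    def _elastic(self, coefficients, need_grad):
        w = self.w
        basis = self.basis
        u = basis.field(coefficients)
        second = {}
        for a in range(3):
            for b in range(a, 3):
                derivs = [0, 0, 0]
                derivs[a] += 1
                derivs[b] += 1
                second[(a, b)] = basis.field(coefficients, tuple(derivs))
        lap = second[(0, 0)] + second[(1, 1)] + second[(2, 2)]
        graddiv = np.empty_like(u)
        for a in range(3):
            graddiv[..., a] = sum(
                second[(min(a, b), max(a, b))][..., b] for b in range(3)
            )
        Lu = -w.alpha_el * lap - w.beta_el * graddiv + w.gamma_el * u
        mask = self.omega.reshape(self.grid.shape)
        value = self.v2 * float(np.sum(Lu[mask] ** 2))
        if not need_grad:
            return value, None
        W = np.where(mask[..., None], 2.0 * self.v2 * Lu, 0.0)
        grad = np.zeros(self.lattice_shape + (3,))
        for d in range(3):
            acc = w.gamma_el * basis.scatter(W[..., d])
            for b in range(3):
                derivs = [0, 0, 0]
                derivs[b] = 2
                acc -= w.alpha_el * basis.scatter(W[..., d], tuple(derivs))
            for a in range(3):
                derivs = [0, 0, 0]
                derivs[a] += 1
                derivs[d] += 1
                acc -= w.beta_el * basis.scatter(W[..., a], tuple(derivs))
            grad[..., d] = acc
        return value, grad

    # -- full objective --------------------------------------------------------

    def _scatter_adjoint(self, adj: np.ndarray, derivs=(0, 0, 0)) -> np.ndarray:
        """Scatter an (n_omega, 3) adjoint field back onto the lattice."""
        field = np.zeros((int(np.prod(self.grid.shape)), 3))
        field[self.omega] = adj
        field = field.reshape(self.grid.shape + (3,))
        out = np.empty(self.lattice_shape + (3,))
        for d in range(3):
            out[..., d] = self.basis.scatter(field[..., d], derivs)
        return out

    def evaluate(self, coefficients: np.ndarray, need_grad: bool = True,
                 parts: bool = False):
        """Cost breakdown (and gradient over coefficients) at one iterate.

        With ``parts=True`` additionally returns the unweighted per-term
        gradients (intensity, ssvmd, reg).
        """
        w = self.w
        coefficients = coefficients.reshape(self.lattice_shape + (3,))
        pts = self._warp(coefficients)
        if need_grad:
            m, gm = self.interp.sample(pts, gradient=True)
        else:
            m, gm = self.interp.sample(pts), None
        c_int, dm, jac_adjoint = self._intensity(m, gm, coefficients, need_grad)

        c_ves, dvf, gf = (0.0, None, None)
        if w.chi > 0:
            c_ves, dvf, gf = self._ssvmd(pts, need_grad)

        c_reg, g_reg = (0.0, None)
        if w.gamma_reg > 0:
            c_reg, g_reg = self._elastic(coefficients, need_grad)

        total = c_int + w.chi * c_ves + w.gamma_reg * c_reg
        breakdown = CostBreakdown(c_int, c_ves, c_reg, total, self.metric)
        if not need_grad:
            return breakdown, None

        # position-dependence of the sampled template values
        g_int = self._scatter_adjoint(dm[:, None] * gm)
        # SSTVD: dependence of the Jacobian determinant on the coefficients
        if jac_adjoint is not None:
            for b in range(3):
                derivs = [0, 0, 0]
                derivs[b] = 1
                g_int += self._scatter_adjoint(jac_adjoint[:, b, :], tuple(derivs))
        g_ves = None
        if w.chi > 0:
            g_ves = self._scatter_adjoint(dvf[:, None] * gf)

        grad = g_int.copy()
        if g_ves is not None:
            grad += w.chi * g_ves
        if g_reg is not None:
            grad += w.gamma_reg * g_reg
        if parts:
            return breakdown, grad, (g_int, g_ves, g_reg)
        return breakdown, grad


def _validate_vesselness(values: np.ndarray, tol: float = 1e-6) -> None:
    if values.min() < -tol or values.max() > 1.0 + tol:
        raise ValueError("vesselness fields must lie in [0, 1]")


# ---------------------------------------------------------------------------
# public single-term cost functions
# ---------------------------------------------------------------------------

def _single_metric_context(I1, I2, T, omega, weights=None, metric="ssd", **kw):
    w = weights or CostWeights(chi=0.0, gamma_reg=0.0)
    return CostContext(I1, I2, omega, T, w, metric, **kw)


def cost_ssd(I1, I2, T, omega, interp_order: int = 3) -> float:
    """Sum of squared intensity differences over Omega (HU^2 * mm^3).

    The template is expected to be histogram-matched to the target first.
    """
    w = CostWeights(chi=0.0, gamma_reg=0.0)
    ctx = CostContext(I1, I2, omega, T, w, "ssd", interp_order=interp_order)
    return ctx.evaluate(T.coefficients, need_grad=False)[0].intensity_term


def cost_ncc(I1, I2, T, omega, interp_order: int = 3) -> float:
    """Negative normalized cross correlation over Omega, in [-1, 1]."""
    w = CostWeights(chi=0.0, gamma_reg=0.0)
    ctx = CostContext(I1, I2, omega, T, w, "ncc", interp_order=interp_order)
    return ctx.evaluate(T.coefficients, need_grad=False)[0].intensity_term


def cost_sstvd(I1, I2, T, omega, weights: CostWeights | None = None,
               interp_order: int = 3) -> float:
    """Sum of squared tissue volume differences (mm^6 of tissue volume)."""
    w = weights or CostWeights(chi=0.0, gamma_reg=0.0)
    w = CostWeights(0.0, 0.0, w.alpha_el, w.beta_el, w.gamma_el,
                    w.hu_air, w.tissue_denominator)
    ctx = CostContext(I1, I2, omega, T, w, "sstvd", interp_order=interp_order)
    return ctx.evaluate(T.coefficients, need_grad=False)[0].intensity_term


def cost_mi(I1, I2, T, omega, bins: int = 50, window: str = "spline",
            interp_order: int = 3) -> float:
    """Negative mutual information of (I1 o h, I2) over Omega.

    ``window="spline"`` (default) uses differentiable cubic-spline Parzen bin
    contributions for the warped template axis -- the estimator used during
    optimization.  ``window="hard"`` bins both axes discretely, for which
    MI(X, X) = H(X) holds exactly.
    """
    if window == "spline":
        w = CostWeights(chi=0.0, gamma_reg=0.0)
        ctx = CostContext(I1, I2, omega, T, w, "mi", interp_order=interp_order,
                          mi_bins=bins)
        return ctx.evaluate(T.coefficients, need_grad=False)[0].intensity_term
    if window != "hard":
        raise ValueError("window must be 'spline' or 'hard'")
    _require_same_lattice(I2, omega)
    sel = omega.bool_values.ravel()
    if not sel.any():
        raise ValueError("Omega is empty")
    basis = LatticeBasis(T, I2)
    pts = _grid_points(I2)[sel] + basis.field(T.coefficients).reshape(-1, 3)[sel]
    m = SplineImage(I1, order=interp_order, background=-1000.0).sample(pts)
    i2 = I2.values.ravel()[sel]
    if np.ptp(m) == 0 or np.ptp(i2) == 0:
        return 0.0
    P, _, _ = np.histogram2d(m, i2, bins=bins)
    P /= P.sum()
    p1 = P.sum(axis=1)
    p2 = P.sum(axis=0)
    pos = P > 0
    return -float(np.sum(P[pos] * np.log(P[pos] / np.outer(p1, p2)[pos])))


def cost_ssvmd(F1, F2, T, omega, interp_order: int = 3) -> float:
    """Sum of squared vesselness differences over Omega (mm^3)."""
    _validate_vesselness(F1.values)
    _validate_vesselness(F2.values)
    _require_same_lattice(F2, omega)
    sel = omega.bool_values.ravel()
    if not sel.any():
        raise ValueError("Omega is empty")
    basis = LatticeBasis(T, F2)
    pts = _grid_points(F2)[sel] + basis.field(T.coefficients).reshape(-1, 3)[sel]
    vf = SplineImage(F1, order=interp_order, background=0.0).sample(pts)
    diff = F2.values.ravel()[sel] - vf
    return F2.voxel_volume * float(np.dot(diff, diff))


def cost_elastic(T, omega, weights: CostWeights) -> float:
    """Integrated squared elastic operator response over Omega (mm^3-scaled)."""
    basis = LatticeBasis(T, omega)
    mask = omega.bool_values
    u = basis.field(T.coefficients)
    second = {}
    for a in range(3):
        for b in range(a, 3):
            derivs = [0, 0, 0]
            derivs[a] += 1
            derivs[b] += 1
            second[(a, b)] = basis.field(T.coefficients, tuple(derivs))
    lap = second[(0, 0)] + second[(1, 1)] + second[(2, 2)]
    graddiv = np.empty_like(u)
    for a in range(3):
        graddiv[..., a] = sum(second[(min(a, b), max(a, b))][..., b] for b in range(3))
    Lu = -weights.alpha_el * lap - weights.beta_el * graddiv + weights.gamma_el * u
    return omega.voxel_volume * float(np.sum(Lu[mask] ** 2))


def total_cost_and_gradient(
    I1: ImageVolume,
    I2: ImageVolume,
    F1: ImageVolume | None,
    F2: ImageVolume | None,
    target_mask: BinaryMask,
    template_mask: BinaryMask,
    T: BSplineTransform,
    weights: CostWeights,
    metric: str,
    omega: BinaryMask | None = None,
    interp_order: int = 3,
    mi_bins: int = 50,
):
    """Full objective of one iterate: breakdown plus coefficient gradient.

    Omega defaults to the union of the target mask and the template mask
    warped through T.
    """
    if omega is None:
        omega = domain_union(target_mask, template_mask, T)
    ctx = CostContext(
        I1, I2, omega, T, weights, metric,
        vesselness_template=F1, vesselness_target=F2,
        interp_order=interp_order, mi_bins=mi_bins,
    )
    return ctx.evaluate(T.coefficients, need_grad=True)
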