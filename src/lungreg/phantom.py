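"""Synthetic template/target lung pairs with known ground-truth deformation.

The target ("FRC-like") volume is built analytically: an ellipsoidal lung of
air/tissue-mixture parenchyma inside a soft-tissue body background, a
recursively branching tree of bright tubes whose radii shrink geometrically
(the finest generation sits 1-2 voxels wide, deliberately near the intensity
contrast floor), and a planar fissure represented as a zero-thickness point
sheet.  A random ground-truth cubic B-spline transform within the local
injectivity bound maps target to template coordinates; the template volume
is painted by evaluating the same analytic geometry at the numerically
inverted transform positions (no resampling, hence no interpolation blur),
with parenchyma intensity scaled so regional tissue content is conserved
(template tissue fraction = target fraction / Jacobian) -- the model SSTVD
assumes.  Landmark pairs are exact correspondences p_k = truth(q_k).

Gaussian white noise is added independently per volume; all randomness is
split deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .bspline import BSplineTransform, INJECTIVITY_K
from .volumes import BinaryMask, ImageVolume, LandmarkPairs, PointSet

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "GenerationError",
    "make_ground_truth_transform",
    "generate_phantom_pair",
    "invert_transform_on_grid",
]

HU_AIR = -1000.0
HU_TISSUE = 0.0


class GenerationError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    """Geometry, intensity model and deformation parameters of a phantom."""

    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)  # mm
    lung_semiaxes: tuple = (22.0, 24.0, 26.0)  # mm
    vessel_generations: int = 4
    root_radius: float = 2.5  # mm
    radius_decay: float = 0.6
    vessel_hu: float = 50.0
    tissue_fraction_target: float = 0.15  # FRC-like parenchyma (~ -850 HU)
    tissue_fraction_template: float = 0.15  # used only when conserve_tissue=False
    conserve_tissue: bool = True
    noise_sd: float = 5.0  # HU
    psf_sigma: float = 0.7  # mm, scanner point-spread blur applied per volume
    truth_grid_spacing: float = 16.0  # mm
    amplitude_fraction: float = 0.5  # of the injectivity bound delta/K
    background_hu: float = 50.0  # chest-wall-like body background
    root_length: float = 14.0  # mm
    branch_length_decay: float = 0.72
    branch_angle_deg: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.amplitude_fraction <= 1.0):
            raise ValueError("amplitude fraction must lie in [0, 1]")
        for f in (self.tissue_fraction_target, self.tissue_fraction_template):
            if not (0.0 < f < 1.0):
                raise ValueError("tissue fractions must lie in (0, 1)")
        if self.vessel_generations < 1:
            raise ValueError("vessel generations must be >= 1")

    @property
    def center(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def target_geometry(self) -> ImageVolume:
        return ImageVolume(np.zeros(self.shape), self.spacing, (0.0, 0.0, 0.0))


@dataclass
class PhantomPair:
    template: ImageVolume
    target: ImageVolume
    template_mask: BinaryMask
    target_mask: BinaryMask
    landmarks: LandmarkPairs
    vessel_points_template: PointSet
    vessel_points_target: PointSet
    fissure_points_template: PointSet
    fissure_points_target: PointSet
    truth: BSplineTransform


def make_ground_truth_transform(spec: PhantomSpec, seed: int) -> BSplineTransform:
    """Random smooth transform with coefficients within amplitude * delta/K.

    Coefficients are drawn iid and then correlated across the control lattice
    (one-control-point Gaussian smoothing) before rescaling to the amplitude:
    respiratory deformation is spatially smooth, and an uncorrelated draw
    would put most of its energy at the lattice Nyquist frequency, unlike any
    physiological motion.
    """
    delta = float(spec.truth_grid_spacing)
    if delta < 4.0:
        raise ValueError("truth grid spacing must be >= 4 mm")
    if delta < 2.0 * float(np.max(spec.spacing)):
        raise ValueError("truth grid spacing below two voxels")
    geom = spec.target_geometry()
    lo, hi = geom.domain()
    T = BSplineTransform.from_domain(lo, hi, np.full(3, delta))
    bound = spec.amplitude_fraction * T.grid_spacing / INJECTIVITY_K
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-1.0, 1.0, size=T.coefficients.shape)
    smooth = ndimage.gaussian_filter(raw, sigma=(1.0, 1.0, 1.0, 0.0), mode="nearest")
    peak = np.abs(smooth).max(axis=(0, 1, 2))
    scale = np.where(peak > 0, bound / np.where(peak > 0, peak, 1.0), 0.0)
    T.coefficients = smooth * scale
    return T


def invert_transform_on_grid(T: BSplineTransform, pts: np.ndarray,
                             tol: float = 1e-9, max_iter: int = 80) -> np.ndarray:
    """Solve h(q) = y for q at each row of pts by fixed-point iteration.

    Converges for displacement fields whose gradient norm is below one, which
    holds comfortably within the injectivity bound.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    q = pts.copy()
    active = np.arange(pts.shape[0])
    for _ in range(max_iter):
        update = pts[active] - T.displacement(q[active], strict=False) - q[active]
        q[active] += update
        still = np.max(np.abs(update), axis=1) >= tol
        active = active[still]
        if active.size == 0:
            break
    return q


# ---------------------------------------------------------------------------
# vessel tree
# ---------------------------------------------------------------------------

def _ellipsoid_radius2(pts: np.ndarray, center: np.ndarray, semiaxes: np.ndarray):
    rel = (np.atleast_2d(pts) - center) / semiaxes
    return np.sum(rel * rel, axis=1)


def _orthonormal_frame(d: np.ndarray):
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return d, e1, e2


def _grow_tree(spec: PhantomSpec, rng, scale: float):
    """Return (segments, branch_points); raise if a branch cannot fit."""
    center = spec.center
    semi = np.asarray(spec.lung_semiaxes, dtype=float)
    margin = 0.88
    segments = []  # (p0, p1, radius, generation)
    branch_points = []

    def grow(p0, direction, length, generation):
        radius = spec.root_radius * spec.radius_decay ** generation
        length_try = length
        for _ in range(5):
            p1 = p0 + direction * length_try
            if _ellipsoid_radius2(p1, center, semi)[0] <= margin**2:
                break
            length_try *= 0.7
        else:
            raise GenerationError("vessel branch escaped the lung ellipsoid")
        segments.append((p0.copy(), p1.copy(), radius, generation))
        if generation + 1 < spec.vessel_generations:
            branch_points.append(p1.copy())
            d, e1, e2 = _orthonormal_frame(direction)
            theta = np.deg2rad(spec.branch_angle_deg + rng.uniform(-5.0, 5.0))
            az = rng.uniform(0.0, 2.0 * np.pi)
            for phi in (az, az + np.pi):
                child = (
                    np.cos(theta) * d
                    + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                )
                grow(p1, child / np.linalg.norm(child),
                     length_try * spec.branch_length_decay, generation + 1)

    root_start = center + np.array([0.0, 0.0, -0.62 * semi[2]])
    tilt = np.array([0.12, 0.05, 1.0])
    grow(root_start, tilt / np.linalg.norm(tilt), scale * spec.root_length, 0)
    return segments, branch_points


def _tree_with_retries(spec: PhantomSpec, rng):
    scale = 1.0
    for _ in range(6):
        try:
            return _grow_tree(spec, rng, scale)
        except GenerationError:
            scale *= 0.8
    raise GenerationError("vessel tree generation failed after retries")


def _sample_segments(segments, step: float):
    """Dense centreline samples (points, radii) every ``step`` mm."""
    pts, radii = [], []
    for p0, p1, radius, _gen in segments:
        n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts.append(p0 + t * (p1 - p0))
        radii.append(np.full(n, radius))
    return np.vstack(pts), np.concatenate(radii)


def _vessel_margin(pts: np.ndarray, trees_and_radii) -> np.ndarray:
    """Signed tube margin (mm): radius minus distance to the nearest
    centreline, maximized over generations (positive inside a vessel)."""
    margin = np.full(pts.shape[0], -np.inf)
    for tree, radius in trees_and_radii:
        dist, _ = tree.query(pts, k=1)
        np.maximum(margin, radius - dist, out=margin)
    return margin


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def generate_phantom_pair(spec: PhantomSpec, seed: int | None = None) -> PhantomPair:
    """Deterministically generate a template/target pair with ground truth."""
    if seed is None:
        seed = spec.seed
    master = np.random.default_rng(seed)
    seed_truth, seed_tree, seed_noise1, seed_noise2 = (
        int(s) for s in master.integers(0, 2**31 - 1, size=4)
    )
    truth = make_ground_truth_transform(spec, seed_truth)
    geom = spec.target_geometry()
    center = spec.center
    semi = np.asarray(spec.lung_semiaxes, dtype=float)

    segments, branch_points = _tree_with_retries(spec, np.random.default_rng(seed_tree))
    step = 0.25 * float(np.min(spec.spacing))
    samples, radii = _sample_segments(segments, step)

    axes = [geom.axis_coords(a) for a in range(3)]
    grid = np.stack([c.ravel() for c in np.meshgrid(*axes, indexing="ij")], axis=1)

    f2 = spec.tissue_fraction_target

    generations = sorted({seg[3] for seg in segments})
    trees_and_radii = []
    for g in generations:
        gs, gr = _sample_segments([s for s in segments if s[3] == g], step)
        trees_and_radii.append((cKDTree(gs), float(gr[0])))

    # partial-volume edge profile emulating the scanner's finite resolution:
    # intensities blend linearly over ~one voxel around each analytic surface
    edge = float(np.min(spec.spacing))

    def paint(points, fractions):
        """Analytic intensity at world points given per-point tissue fraction."""
        d_lung = (1.0 - np.sqrt(_ellipsoid_radius2(points, center, semi))) * np.min(semi)
        frac_lung = np.clip(0.5 + d_lung / edge, 0.0, 1.0)
        parenchyma = HU_AIR + fractions * (HU_TISSUE - HU_AIR)
        hu = spec.background_hu * (1.0 - frac_lung) + parenchyma * frac_lung
        frac_vessel = np.clip(
            0.5 + _vessel_margin(points, trees_and_radii) / edge, 0.0, 1.0
        ) * frac_lung
        hu = hu * (1.0 - frac_vessel) + spec.vessel_hu * frac_vessel
        return hu, frac_lung >= 0.5

    # target: evaluate geometry at the voxel centres directly
    target_hu, target_lung = paint(grid, np.full(len(grid), f2))

    # template: evaluate the same geometry at the inverse-mapped positions,
    # scaling parenchyma intensity for tissue conservation
    q = invert_transform_on_grid(truth, grid)
    if spec.conserve_tissue:
        # J at scattered q via the analytic point-wise Jacobian
        jac_q = _jacobian_at_points(truth, q)
        f1 = np.clip(f2 / jac_q, 0.02, 0.95)
    else:
        f1 = np.full(len(q), spec.tissue_fraction_template)
    template_hu, template_lung = paint(q, f1)

    shape = spec.shape
    if spec.psf_sigma > 0:
        sig_vox = spec.psf_sigma / np.asarray(spec.spacing)
        template_hu = ndimage.gaussian_filter(
            template_hu.reshape(shape), sig_vox, mode="nearest"
        ).ravel()
        target_hu = ndimage.gaussian_filter(
            target_hu.reshape(shape), sig_vox, mode="nearest"
        ).ravel()

    rng1 = np.random.default_rng(seed_noise1)
    rng2 = np.random.default_rng(seed_noise2)
    if spec.noise_sd > 0:
        template_hu = template_hu + rng1.normal(0.0, spec.noise_sd, template_hu.shape)
        target_hu = target_hu + rng2.normal(0.0, spec.noise_sd, target_hu.shape)
    template = ImageVolume(template_hu.reshape(shape), spec.spacing, (0, 0, 0))
    target = ImageVolume(target_hu.reshape(shape), spec.spacing, (0, 0, 0))
    template_mask = BinaryMask(
        template_lung.reshape(shape).astype(float), spec.spacing, (0, 0, 0)
    )
    target_mask = BinaryMask(
        target_lung.reshape(shape).astype(float), spec.spacing, (0, 0, 0)
    )

    inner = 0.92  # point sets stay strictly inside the lung
    # landmarks: vessel-tree branch points plus segment midpoints
    lm = list(branch_points) + [0.5 * (s[0] + s[1]) for s in segments]
    lm = np.array(lm)
    lm = lm[_ellipsoid_radius2(lm, center, semi) <= inner**2]
    lm = np.unique(np.round(lm, 9), axis=0)
    if len(lm) == 0:
        raise GenerationError("no landmarks inside the lung")
    q_k = lm
    p_k = truth(q_k)
    landmarks = LandmarkPairs(p_k, q_k)

    keep = _ellipsoid_radius2(samples, center, semi) <= inner**2
    v2_pts = samples[keep][:: max(1, int(round(1.0 / step)))]
    vessel_target = PointSet(v2_pts, label="vessel")
    vessel_template = PointSet(truth(v2_pts), label="vessel")

    fissure_target = PointSet(_fissure_points(center, semi, inner), label="fissure")
    fissure_template = PointSet(truth(fissure_target.points), label="fissure")

    return PhantomPair(
        template=template,
        target=target,
        template_mask=template_mask,
        target_mask=target_mask,
        landmarks=landmarks,
        vessel_points_template=vessel_template,
        vessel_points_target=vessel_target,
        fissure_points_template=fissure_template,
        fissure_points_target=fissure_target,
        truth=truth,
    )


def _jacobian_at_points(T: BSplineTransform, pts: np.ndarray) -> np.ndarray:
    """det(I + du/dx) at scattered points via analytic spline derivatives."""
    pts = np.atleast_2d(pts)
    D = np.empty((pts.shape[0], 3, 3))
    eps_free = _scattered_displacement_gradient(T, pts)
    D[:] = eps_free
    F = D + np.eye(3)
    return np.linalg.det(F)


def _scattered_displacement_gradient(T: BSplineTransform, pts: np.ndarray) -> np.ndarray:
    """du_a/dx_b (N, 3, 3) at scattered points, zero-extended off-lattice."""
    from .bspline import bspline_basis

    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    t = (pts - T.grid_origin) / T.grid_spacing
    base = np.floor(t).astype(int)
    f = t - base
    w = np.empty((pts.shape[0], 4, 3))
    dw = np.empty((pts.shape[0], 4, 3))
    for k, off in enumerate((-1, 0, 1, 2)):
        w[:, k, :] = bspline_basis(f - off)
        dw[:, k, :] = bspline_basis(f - off, deriv=1) / T.grid_spacing
    n = np.array(T.lattice_shape)
    out = np.zeros((pts.shape[0], 3, 3))
    for a in range(4):
        ia = base[:, 0] + (a - 1)
        va = (ia >= 0) & (ia < n[0])
        for b in range(4):
            ib = base[:, 1] + (b - 1)
            vb = va & (ib >= 0) & (ib < n[1])
            for c in range(4):
                ic = base[:, 2] + (c - 1)
                v = vb & (ic >= 0) & (ic < n[2])
                if not v.any():
                    continue
                coeff = T.coefficients[
                    np.clip(ia[v], 0, n[0] - 1),
                    np.clip(ib[v], 0, n[1] - 1),
                    np.clip(ic[v], 0, n[2] - 1),
                ]
                wx, wy, wz = w[v, a, 0], w[v, b, 1], w[v, c, 2]
                dx, dy, dz = dw[v, a, 0], dw[v, b, 1], dw[v, c, 2]
                out[v, :, 0] += (dx * wy * wz)[:, None] * coeff
                out[v, :, 1] += (wx * dy * wz)[:, None] * coeff
                out[v, :, 2] += (wx * wy * dz)[:, None] * coeff
    return out


def _fissure_points(center, semi, inner, step: float = 1.5) -> np.ndarray:
    """Zero-thickness oblique plane through the lung, as a point sheet."""
    normal = np.array([0.25, 0.10, 0.96])
    d, e1, e2 = _orthonormal_frame(normal)
    extent = float(np.max(semi))
    t = np.arange(-extent, extent + step, step)
    t1, t2 = np.meshgrid(t, t, indexing="ij")
    pts = center + t1.ravel()[:, None] * e1 + t2.ravel()[:, None] * e2
    keep = _ellipsoid_radius2(pts, center, semi) <= inner**2
    return pts[keep]
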