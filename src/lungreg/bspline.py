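"""Cubic B-spline free-form deformation (FFD).

The transform is ``h(x) = x + sum_i phi_i * B((x - x_i)/delta)`` over a
regular lattice of control points ``x_i = grid_origin + i * grid_spacing``
with 3-vector coefficients ``phi_i`` in mm and the separable uniform cubic
B-spline kernel.  Local injectivity is guaranteed by bounding every
coefficient component by ``grid_spacing / K`` with K = 2.479772335
(Choi-Lee bound); the registration driver applies this as a symmetric box
constraint during optimization.

All spatial quantities are world millimetres.  Derivatives (and hence the
Jacobian determinant) are analytic B-spline derivatives, not finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import ImageVolume, PointSet

__all__ = [
    "INJECTIVITY_K",
    "bspline_basis",
    "BSplineTransform",
    "LatticeBasis",
    "MultiresSchedule",
    "ScheduleLevel",
    "injectivity_bounds",
    "transform_points",
    "jacobian_determinant",
    "check_positive_jacobian",
    "dense_min_jacobian",
    "refine_to_spacing",
    "read_transform",
    "write_transform",
]

#: Local-injectivity constant: |phi| <= delta / K per component keeps det > 0.
INJECTIVITY_K = 2.479772335


def bspline_basis(t, deriv: int = 0):
    """Uniform cubic B-spline kernel (or its first/second derivative).

    ``B(t) = (4 - 6 t^2 + 3|t|^3)/6`` for ``|t| < 1``,
    ``(2 - |t|)^3 / 6`` for ``1 <= |t| < 2`` and 0 beyond.
    """
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    out = np.zeros_like(t)
    if deriv == 0:
        out[inner] = (4.0 - 6.0 * a[inner] ** 2 + 3.0 * a[inner] ** 3) / 6.0
        out[outer] = (2.0 - a[outer]) ** 3 / 6.0
    elif deriv == 1:
        s = np.sign(t)
        out[inner] = (-12.0 * t[inner] + 9.0 * a[inner] * t[inner]) / 6.0
        out[outer] = -s[outer] * (2.0 - a[outer]) ** 2 / 2.0
    elif deriv == 2:
        out[inner] = -2.0 + 3.0 * a[inner]
        out[outer] = 2.0 - a[outer]
    else:
        raise ValueError("deriv must be 0, 1 or 2")
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BSplineTransform:
    """Control-point lattice of 3-vector displacement coefficients (mm)."""

    grid_spacing: np.ndarray
    grid_origin: np.ndarray
    coefficients: np.ndarray  # (nx, ny, nz, 3)

    def __post_init__(self):
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if not np.all(self.grid_spacing > 0):
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_domain(cls, domain_lo, domain_hi, grid_spacing) -> "BSplineTransform":
        """Identity transform whose lattice supports ``[domain_lo, domain_hi]``.

        Control points start two grid steps before the domain corner so every
        domain point has full cubic support.
        """
        lo = np.asarray(domain_lo, dtype=float).reshape(3)
        hi = np.asarray(domain_hi, dtype=float).reshape(3)
        delta = np.asarray(grid_spacing, dtype=float).reshape(3)
        if np.any(hi < lo):
            raise ValueError("domain_hi must be >= domain_lo")
        origin = lo - 2.0 * delta
        n = np.ceil((hi - lo) / delta - 1e-9).astype(int) + 6
        coeffs = np.zeros((n[0], n[1], n[2], 3))
        return cls(delta, origin, coeffs)

    @classmethod
    def for_volume(cls, vol: ImageVolume, grid_spacing) -> "BSplineTransform":
        lo, hi = vol.domain()
        return cls.from_domain(lo, hi, grid_spacing)

    @property
    def lattice_shape(self) -> tuple:
        return self.coefficients.shape[:3]

    def copy(self) -> "BSplineTransform":
        return BSplineTransform(
            self.grid_spacing.copy(), self.grid_origin.copy(), self.coefficients.copy()
        )

    def support_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World region where the full cubic support is available."""
        n = np.array(self.lattice_shape)
        lo = self.grid_origin + self.grid_spacing
        hi = self.grid_origin + (n - 3) * self.grid_spacing
        return lo, hi

    def control_positions(self, axis: int) -> np.ndarray:
        n = self.lattice_shape[axis]
        return self.grid_origin[axis] + self.grid_spacing[axis] * np.arange(n)

    # -- scattered-point evaluation -----------------------------------------

    def _check_support(self, pts: np.ndarray) -> None:
        lo, hi = self.support_bounds()
        tol = 1e-9
        if np.any(pts < lo - tol) or np.any(pts > hi + tol):
            raise ValueError("point(s) outside the supported transform domain")

    def displacement(self, pts: np.ndarray, strict: bool = True) -> np.ndarray:
        """Displacement u(x) at scattered world points (N x 3).

        With ``strict=False`` control points outside the lattice are treated
        as zero coefficients instead of raising, which extends the field
        smoothly by zero beyond the lattice.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if strict:
            self._check_support(pts)
        t = (pts - self.grid_origin) / self.grid_spacing  # (N, 3)
        base = np.floor(t).astype(int)
        f = t - base
        # per-axis weights for control offsets -1, 0, 1, 2
        w = np.empty((pts.shape[0], 4, 3))
        for k, off in enumerate((-1, 0, 1, 2)):
            w[:, k, :] = bspline_basis(f - off)
        n = np.array(self.lattice_shape)
        disp = np.zeros_like(pts)
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
                    ww = w[v, a, 0] * w[v, b, 1] * w[v, c, 2]
                    disp[v] += ww[:, None] * self.coefficients[
                        np.clip(ia[v], 0, n[0] - 1),
                        np.clip(ib[v], 0, n[1] - 1),
                        np.clip(ic[v], 0, n[2] - 1),
                    ]
        return disp

    def __call__(self, pts: np.ndarray, strict: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts + self.displacement(pts, strict=strict)

    # -- I/O -----------------------------------------------------------------

    def write(self, path) -> None:
        write_transform(self, path)


def injectivity_bounds(T: BSplineTransform) -> np.ndarray:
    """Per-axis symmetric coefficient bound (mm): grid_spacing / K."""
    return T.grid_spacing / INJECTIVITY_K


def transform_points(T: BSplineTransform, pts) -> PointSet:
    """Apply h to a PointSet (or N x 3 array), returning a PointSet."""
    if isinstance(pts, PointSet):
        arr, label = pts.points, pts.label
    else:
        arr, label = np.atleast_2d(np.asarray(pts, dtype=float)), ""
    return PointSet(T(arr), label=label)


class LatticeBasis:
    """Separable B-spline basis matrices tying a transform lattice to a grid.

    For a regular evaluation grid the tensor-product structure lets both the
    forward map (coefficients -> fields on the grid) and its adjoint (grid
    fields -> coefficient gradients) be computed as three small matrix
    contractions per component.  Basis matrices are cached per (axis,
    derivative order).
    """

    def __init__(self, transform: BSplineTransform, grid: ImageVolume):
        self.grid_spacing = transform.grid_spacing
        self.grid_origin = transform.grid_origin
        self.lattice_shape = transform.lattice_shape
        self.axis_coords = [grid.axis_coords(a) for a in range(3)]
        lo, hi = transform.support_bounds()
        for a in range(3):
            c = self.axis_coords[a]
            if c[0] < lo[a] - 1e-9 or c[-1] > hi[a] + 1e-9:
                raise ValueError("evaluation grid extends beyond the transform support")
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def matrix(self, axis: int, deriv: int = 0) -> np.ndarray:
        key = (axis, deriv)
        if key not in self._cache:
            coords = self.axis_coords[axis]
            delta = self.grid_spacing[axis]
            t = (coords[:, None] - self.grid_origin[axis]) / delta - np.arange(
                self.lattice_shape[axis]
            )[None, :]
            self._cache[key] = bspline_basis(t, deriv) / delta**deriv
        return self._cache[key]

    def _apply(self, c3: np.ndarray, derivs=(0, 0, 0)) -> np.ndarray:
        bx = self.matrix(0, derivs[0])
        by = self.matrix(1, derivs[1])
        bz = self.matrix(2, derivs[2])
        return np.einsum("xi,yj,zk,ijk->xyz", bx, by, bz, c3, optimize=True)

    def field(self, coefficients: np.ndarray, derivs=(0, 0, 0)) -> np.ndarray:
        """Vector field (Nx, Ny, Nz, 3) from (nx, ny, nz, 3) coefficients."""
        return np.stack(
            [self._apply(coefficients[..., d], derivs) for d in range(3)], axis=-1
        )

    def scatter(self, field: np.ndarray, derivs=(0, 0, 0)) -> np.ndarray:
        """Adjoint of ``_apply``: accumulate a grid field onto the lattice."""
        bx = self.matrix(0, derivs[0])
        by = self.matrix(1, derivs[1])
        bz = self.matrix(2, derivs[2])
        return np.einsum("xi,yj,zk,xyz->ijk", bx, by, bz, field, optimize=True)

    def displacement_gradient(self, coefficients: np.ndarray) -> np.ndarray:
        """du_a/dx_b on the grid, shape (Nx, Ny, Nz, 3, 3)."""
        cols = []
        for b in range(3):
            derivs = [0, 0, 0]
            derivs[b] = 1
            cols.append(self.field(coefficients, tuple(derivs)))
        return np.stack(cols, axis=-1)  # [..., a, b]

    def jacobian(self, coefficients: np.ndarray) -> np.ndarray:
        D = self.displacement_gradient(coefficients)
        F = D + np.eye(3)
        return np.linalg.det(F)


def jacobian_determinant(T: BSplineTransform, like: ImageVolume) -> ImageVolume:
    """Jacobian determinant of h on the voxel lattice of ``like`` (unitless)."""
    basis = LatticeBasis(T, like)
    return ImageVolume(basis.jacobian(T.coefficients), like.spacing, like.origin)


def check_positive_jacobian(T: BSplineTransform, like: ImageVolume):
    """Minimum lattice Jacobian and the voxel index where it occurs."""
    jac = jacobian_determinant(T, like).values
    idx = np.unravel_index(np.argmin(jac), jac.shape)
    return float(jac[idx]), tuple(int(i) for i in idx)


def dense_min_jacobian(T: BSplineTransform, n_per_axis: int = 48, margin: float = 0.0):
    """Minimum Jacobian over a dense regular sampling of the supported domain."""
    lo, hi = T.support_bounds()
    lo = lo + margin
    hi = hi - margin
    shape = (n_per_axis,) * 3
    spacing = (hi - lo) / (n_per_axis - 1)
    grid = ImageVolume(np.zeros(shape), spacing, lo)
    jac = LatticeBasis(T, grid).jacobian(T.coefficients)
    return float(jac.min())


# ---------------------------------------------------------------------------
# grid refinement
# ---------------------------------------------------------------------------

def _dyadic_matrix(n: int) -> np.ndarray:
    """Knot-insertion matrix mapping n coarse to 2n-1 fine cubic coefficients.

    Two-scale relation masks [1, 4, 6, 4, 1]/8; coarse coefficients outside
    the lattice are treated as zero (affects the field only beyond the
    2-control-point margin).
    """
    m = 2 * n - 1
    S = np.zeros((m, n))
    for i in range(n):
        for k, w in zip(range(-2, 3), (0.125, 0.5, 0.75, 0.5, 0.125)):
            j = 2 * i + k
            if 0 <= j < m:
                S[j, i] = w
    return S


def refine_to_spacing(
    T: BSplineTransform, new_spacing, domain: ImageVolume
) -> BSplineTransform:
    """Re-express the transform on a finer control grid.

    Halving the spacing uses exact dyadic subdivision (nested spline spaces),
    after which the lattice is cropped back to a two-control-point margin
    around the voxel-centre domain of ``domain`` -- the removed points lie
    beyond the kernel support of any domain point, so the displacement field
    over the domain is unchanged.  Other ratios use a separable least-squares
    fit of the displacement sampled on the domain lattice.
    """
    new = np.asarray(new_spacing, dtype=float).reshape(3)
    old = T.grid_spacing
    if np.any(new > old + 1e-9):
        raise ValueError("new spacing must be <= current spacing on every axis")
    if np.any(new < 2.0 * domain.spacing - 1e-9):
        raise ValueError("grid spacing below two voxels of the domain lattice")
    dlo, dhi = domain.domain()
    if np.allclose(new, old):
        return T.copy()
    if np.allclose(old / new, 2.0):
        mats = [_dyadic_matrix(T.lattice_shape[a]) for a in range(3)]
        fine = np.stack(
            [
                np.einsum(
                    "ai,bj,ck,ijk->abc",
                    mats[0],
                    mats[1],
                    mats[2],
                    T.coefficients[..., d],
                    optimize=True,
                )
                for d in range(3)
            ],
            axis=-1,
        )
        origin = T.grid_origin.copy()
        keep = []
        for a in range(3):
            pos = origin[a] + new[a] * np.arange(fine.shape[a])
            # a 3-step margin guarantees full cubic support of the domain;
            # removed points lie > 2 steps outside, beyond any kernel reach
            lo_keep = dlo[a] - 3.0 * new[a] - 1e-9
            hi_keep = dhi[a] + 3.0 * new[a] + 1e-9
            idx = np.nonzero((pos >= lo_keep) & (pos <= hi_keep))[0]
            keep.append((idx[0], idx[-1] + 1))
            origin[a] = pos[idx[0]]
        fine = fine[keep[0][0]:keep[0][1], keep[1][0]:keep[1][1], keep[2][0]:keep[2][1]]
        out = BSplineTransform(new, origin, np.ascontiguousarray(fine))
    else:
        out = BSplineTransform.from_domain(dlo, dhi, new)
        basis = LatticeBasis(out, domain)
        pinvs = [np.linalg.pinv(basis.matrix(a), rcond=1e-10) for a in range(3)]
        coarse_basis = LatticeBasis(T, domain)
        u = coarse_basis.field(T.coefficients)
        out.coefficients = np.stack(
            [
                np.einsum(
                    "ix,jy,kz,xyz->ijk",
                    pinvs[0],
                    pinvs[1],
                    pinvs[2],
                    u[..., d],
                    optimize=True,
                )
                for d in range(3)
            ],
            axis=-1,
        )
    # the refined lattice must still support the whole domain
    slo, shi = out.support_bounds()
    assert np.all(slo <= dlo + 1e-9) and np.all(shi >= dhi - 1e-9)
    return out


# ---------------------------------------------------------------------------
# multiresolution schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleLevel:
    image_factor: float  # 1/8, 1/4, 1/2 or 1
    grid_spacing: float  # mm, isotropic
    max_iterations: int


@dataclass
class MultiresSchedule:
    levels: list

    def __post_init__(self):
        if not self.levels:
            raise ValueError("schedule must contain at least one level")
        factors = [lv.image_factor for lv in self.levels]
        spacings = [lv.grid_spacing for lv in self.levels]
        if any(b < a for a, b in zip(factors, factors[1:])):
            raise ValueError("image factors must be non-decreasing")
        if any(b > a for a, b in zip(spacings, spacings[1:])):
            raise ValueError("grid spacings must be non-increasing")
        if any(lv.max_iterations < 1 for lv in self.levels):
            raise ValueError("iteration caps must be >= 1")

    def __iter__(self):
        return iter(self.levels)

    def __len__(self):
        return len(self.levels)


# ---------------------------------------------------------------------------
# transform file I/O (plain text, exact round-trip)
# ---------------------------------------------------------------------------

def write_transform(T: BSplineTransform, path) -> None:
    path = Path(path)
    n = T.lattice_shape
    with open(path, "w") as fh:
        fh.write("# lungreg cubic B-spline transform v1\n")
        fh.write("grid_spacing: " + " ".join(f"{v:.17g}" for v in T.grid_spacing) + "\n")
        fh.write("grid_origin: " + " ".join(f"{v:.17g}" for v in T.grid_origin) + "\n")
        fh.write(f"lattice: {n[0]} {n[1]} {n[2]}\n")
        flat = T.coefficients.reshape(-1, 3)
        for row in flat:
            fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_transform(path) -> BSplineTransform:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"not a lungreg transform file: {path}")
    header = {}
    body_start = 1
    for ln in lines[1:]:
        if ":" in ln:
            key, val = ln.split(":", 1)
            header[key.strip()] = val.strip()
            body_start += 1
        else:
            break
    try:
        spacing = np.array([float(v) for v in header["grid_spacing"].split()])
        origin = np.array([float(v) for v in header["grid_origin"].split()])
        n = tuple(int(v) for v in header["lattice"].split())
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed transform header in {path}") from exc
    rows = lines[body_start:]
    if len(rows) != n[0] * n[1] * n[2]:
        raise ValueError(f"transform file {path} has wrong coefficient count")
    coeffs = np.array([[float(v) for v in r.split()] for r in rows])
    return BSplineTransform(spacing, origin, coeffs.reshape(n + (3,)))
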