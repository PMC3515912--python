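"""Multiscale Hessian eigenanalysis and the Frangi vesselness measure.

Bright tubular structures (vessels) in CT have one near-zero Hessian
eigenvalue along the tube and two similar negative eigenvalues across it.
With eigenvalues ordered by magnitude |l1| <= |l2| <= |l3| the vesselness
response is

    F = (1 - exp(-Ra^2 / 2 alpha^2)) * exp(-Rb^2 / 2 beta^2)
        * (1 - exp(-S^2 / 2 rho^2))        if l2 < 0 and l3 < 0, else 0

with Ra = |l2|/|l3| (plate vs tube), Rb = |l1|/sqrt(|l2 l3|) (blob
deviation) and S = sqrt(l1^2 + l2^2 + l3^2) (structure vs noise).  The
multiscale measure takes the maximum response over a list of Gaussian scales
(mm) and is min-max rescaled to [0, 1].

Because S carries the image's intensity units, HU volumes are linearly
pre-scaled to [0, 1] over a body window (default [-1000, 400] HU) before
Hessian filtering so that the conventional rho = 5 is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume

__all__ = [
    "VesselnessParams",
    "EigenField",
    "hessian_eigenvalues",
    "frangi_response",
    "multiscale_vesselness",
]

DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class VesselnessParams:
    """Frangi sensitivity parameters and the multiscale sigma list (mm)."""

    alpha_v: float = 0.5
    beta_v: float = 0.5
    rho: float = 5.0
    sigmas: tuple = (2.0, 3.0)

    def __post_init__(self):
        if self.alpha_v <= 0 or self.beta_v <= 0 or self.rho <= 0:
            raise ValueError("alpha_v, beta_v and rho must be positive")
        s = tuple(float(v) for v in self.sigmas)
        if not s or any(v <= 0 for v in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("sigmas must be nonempty, positive, strictly increasing")
        self.sigmas = s


@dataclass
class EigenField:
    """Hessian eigenvalue fields ordered by magnitude |l1| <= |l2| <= |l3|."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray

    def __post_init__(self):
        a1, a2, a3 = (np.abs(getattr(self, f"lambda{i}")) for i in (1, 2, 3))
        if np.any(a1 > a2 + 1e-12) or np.any(a2 > a3 + 1e-12):
            raise ValueError("eigenvalues must be ordered by ascending magnitude")


def hessian_eigenvalues(vol: ImageVolume, sigma: float) -> EigenField:
    """Eigenvalues of the Gaussian-derivative Hessian at scale ``sigma`` (mm).

    Derivatives are taken with respect to world millimetres; the Gaussian
    standard deviation is converted to voxel units per axis.
    """
    if sigma < 0.5 * float(np.max(vol.spacing)):
        raise ValueError(
            f"sigma {sigma} mm below half the largest voxel spacing "
            f"{np.max(vol.spacing)} mm"
        )
    sig_vox = sigma / vol.spacing
    H = np.empty(vol.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            # truncate=8: the default 4-sigma support leaves derivative
            # kernels with a ~1e-4 nonzero sum, so constants would not map to
            # exactly zero curvature
            d = ndimage.gaussian_filter(
                vol.values, sigma=sig_vox, order=tuple(order), mode="nearest",
                truncate=8.0,
            ) / (vol.spacing[a] * vol.spacing[b])
            H[..., a, b] = d
            H[..., b, a] = d
    eig = np.linalg.eigvalsh(H)  # ascending by value
    order = np.argsort(np.abs(eig), axis=-1)
    eig = np.take_along_axis(eig, order, axis=-1)
    return EigenField(eig[..., 0], eig[..., 1], eig[..., 2])


def frangi_response(eigs: EigenField, params: VesselnessParams) -> np.ndarray:
    """Pointwise vesselness response in [0, 1) from ordered eigenvalues."""
    l1, l2, l3 = eigs.lambda1, eigs.lambda2, eigs.lambda3
    bright_tube = (l2 < 0) & (l3 < 0)
    eps = np.finfo(float).tiny
    a2, a3 = np.abs(l2), np.abs(l3)
    ra = a2 / np.maximum(a3, eps)
    rb = np.abs(l1) / np.maximum(np.sqrt(a2 * a3), eps)
    s2 = l1**2 + l2**2 + l3**2
    F = (
        (1.0 - np.exp(-(ra**2) / (2.0 * params.alpha_v**2)))
        * np.exp(-(rb**2) / (2.0 * params.beta_v**2))
        * (1.0 - np.exp(-s2 / (2.0 * params.rho**2)))
    )
    return np.where(bright_tube, F, 0.0)


def multiscale_vesselness(
    vol: ImageVolume,
    params: VesselnessParams | None = None,
    hu_window: tuple | None = DEFAULT_HU_WINDOW,
) -> ImageVolume:
    """Maximum Frangi response over scales, min-max rescaled to [0, 1].

    ``hu_window`` linearly maps that intensity range to [0, 1] before
    filtering (pass None for inputs that are already unitless).  A constant
    input maps to an all-zero field.
    """
    params = params or VesselnessParams()
    values = vol.values
    if hu_window is not None:
        lo, hi = hu_window
        values = (values - lo) / (hi - lo)
    work = ImageVolume(values, vol.spacing, vol.origin)
    best = np.zeros(vol.shape)
    floor = 0.5 * float(np.max(vol.spacing))
    for sigma in params.sigmas:
        eigs = hessian_eigenvalues(work, max(sigma, floor))
        np.maximum(best, frangi_response(eigs, params), out=best)
    peak = best.max()
    if peak > 0:
        best = (best - best.min()) / (peak - best.min())
    return ImageVolume(best, vol.spacing, vol.origin)
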