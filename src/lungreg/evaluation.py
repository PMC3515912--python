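"""Registration accuracy assessment.

Landmark error is the Euclidean distance ||p_k - h(q_k)|| between a template
landmark and its transformed target counterpart.  Vessel/fissure positioning
errors are directed closest-point distances from a source point set to the
transformed counterpart set (the direction is explicit and never silently
symmetrized).  Jacobian statistics summarize local volume change: min J and
1/max J over a lung mask, with the full map returned for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bspline import BSplineTransform, jacobian_determinant
from .volumes import BinaryMask, ImageVolume, LandmarkPairs, PointSet

__all__ = [
    "DistanceSummary",
    "landmark_error",
    "point_set_distance",
    "jacobian_stats",
]


@dataclass
class DistanceSummary:
    """Per-point distances (mm) with pooled summary statistics."""

    distances: np.ndarray
    mean: float
    std: float  # population standard deviation over points
    max: float

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceSummary":
        d = np.asarray(d, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("need a nonempty 1-D distance array")
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        return cls(d, float(d.mean()), float(d.std(ddof=0)), float(d.max()))


def landmark_error(pairs: LandmarkPairs, T: BSplineTransform) -> DistanceSummary:
    """Distances ||p_k - h(q_k)|| over all landmark pairs."""
    warped = T(pairs.target_points)
    d = np.linalg.norm(pairs.template_points - warped, axis=1)
    return DistanceSummary.from_distances(d)


def point_set_distance(
    source: PointSet, deformed_from: PointSet, T: BSplineTransform
) -> DistanceSummary:
    """min_y ||x - h(y)|| for each x in source, y over deformed_from.

    Exact nearest neighbours (k-d tree, equal to brute force).  The measure
    is directional: swap the arguments to evaluate the other direction.
    """
    if len(source) == 0 or len(deformed_from) == 0:
        raise ValueError("point sets must be nonempty")
    warped = T(deformed_from.points)
    d, _ = cKDTree(warped).query(source.points, k=1)
    return DistanceSummary.from_distances(np.atleast_1d(d))


def jacobian_stats(T: BSplineTransform, mask: BinaryMask):
    """(min J, 1/max J, Jacobian map) over the masked voxels."""
    jac_map = jacobian_determinant(T, mask)
    vals = jac_map.values[mask.bool_values]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return float(vals.min()), float(1.0 / vals.max()), jac_map
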