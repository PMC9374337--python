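"""Spherocylinder geometry for confined-diffusion simulations.

A spherocylinder (a cylinder capped by two hemispheres) is the standard
idealization of a rod-shaped bacterium such as *E. coli*. The long axis is
aligned with x and the compartment is centered at the origin, so the
cylindrical section spans ``|x| <= total_length/2 - radius`` and each cap is
a hemisphere of the same radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for invalid compartment dimensions."""


@dataclass(frozen=True)
class Spherocylinder:
    """Reflective spherocylindrical compartment.

    Parameters
    ----------
    radius : float
        Compartment radius in micrometers. Must be positive.
    total_length : float
        End-to-end length in micrometers, including both hemispherical
        caps. Must satisfy ``total_length >= 2 * radius``.
    """

    radius: float
    total_length: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"radius must be > 0, got {self.radius}")
        if self.total_length < 2 * self.radius:
            raise GeometryError(
                f"total_length ({self.total_length}) must be >= 2*radius "
                f"({2 * self.radius})"
            )

    @property
    def half_cylinder_length(self) -> float:
        """Half-length of the cylindrical section (``h``), in μm."""
        return self.total_length / 2.0 - self.radius

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical section, in μm."""
        return self.total_length - 2.0 * self.radius

    def _axis_foot(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the axis segment for each row of ``points``."""
        h = self.half_cylinder_length
        foot = np.zeros_like(points)
        foot[:, 0] = np.clip(points[:, 0], -h, h)
        return foot

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of each 3-D point from the compartment axis segment."""
        points = np.atleast_2d(points)
        delta = points - self._axis_foot(points)
        return np.sqrt((delta**2).sum(axis=1))

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the compartment (boundary included)."""
        return self.radial_distance(points) <= self.radius + atol

    def reflect(self, points: np.ndarray, max_iter: int = 64) -> np.ndarray:
        """Fold exterior points back inside by iterated specular reflection.

        Each exterior point is mirrored across the tangent plane of the
        nearest boundary point; the operation repeats until every point is
        interior. For diffusive steps much smaller than the radius a single
        reflection almost always suffices.
        """
        pts = np.array(np.atleast_2d(points), dtype=float, copy=True)
        for _ in range(max_iter):
            foot = self._axis_foot(pts)
            delta = pts - foot
            dist = np.sqrt((delta**2).sum(axis=1))
            outside = dist > self.radius
            if not outside.any():
                return pts
            scale = (2.0 * self.radius - dist[outside]) / dist[outside]
            pts[outside] = foot[outside] + delta[outside] * scale[:, None]
        raise RuntimeError("reflection did not converge; step size too large "
                           "relative to the compartment radius")

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the compartment (rejection)."""
        out = np.empty((n, 3))
        filled = 0
        lo = [-self.total_length / 2.0, -self.radius, -self.radius]
        hi = [self.total_length / 2.0, self.radius, self.radius]
        while filled < n:
            cand = rng.uniform(lo, hi, size=(max(2 * (n - filled), 16), 3))
            keep = cand[self.contains(cand)]
            take = keep[: n - filled]
            out[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        return out

    def footprint_halfwidth(self, x: np.ndarray) -> np.ndarray:
        """Half-width of the planar (x, y) projection at axial position x.

        Zero outside the compartment; used to draw uniform points over the
        projected footprint when synthesizing spurious localizations.
        """
        h = self.half_cylinder_length
        ax = np.clip(np.abs(np.asarray(x, dtype=float)) - h, 0.0, None)
        inside = ax <= self.radius
        out = np.zeros_like(ax)
        out[inside] = np.sqrt(self.radius**2 - ax[inside] ** 2)
        return out

    def sample_footprint(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` planar points uniform over the projected footprint."""
        out = np.empty((n, 2))
        filled = 0
        half_l = self.total_length / 2.0
        while filled < n:
            cand_x = rng.uniform(-half_l, half_l, size=max(2 * (n - filled), 16))
            cand_y = rng.uniform(-self.radius, self.radius, size=cand_x.size)
            keep = np.abs(cand_y) <= self.footprint_halfwidth(cand_x)
            take = np.column_stack([cand_x[keep], cand_y[keep]])[: n - filled]
            out[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        return out
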