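"""Shared low-level geometry: axes, anatomical frames, rigid transforms.

All coordinates are world millimetres.  An :class:`AnatomicalFrame` stores its
axes as the *columns* of a 3x3 rotation-like matrix, so ``frame.axes[:, 0]``
is the frame's x-axis expressed in world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Axis3D",
    "AnatomicalFrame",
    "unit",
    "point_line_distance",
    "canonical_direction",
    "random_rotation",
]

_ORTHO_TOL = 1e-9


def unit(v: np.ndarray) -> np.ndarray:
    """Return v / |v|; raises ValueError on a zero vector."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot normalize zero or non-finite vector")
    return v / n


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Sign-normalize a unit vector: largest-|component| made positive.

    Ties are broken by the first nonzero component.  Two antiparallel
    directions map to the same representative, which makes undirected lines
    (e.g. the hinge axis) independent of the order of the defining points.
    """
    d = np.asarray(d, dtype=float)
    i = int(np.argmax(np.abs(d)))
    if d[i] == 0.0:
        raise ValueError("zero direction")
    return d if d[i] > 0 else -d


@dataclass(frozen=True)
class Axis3D:
    """A line in 3D: a point on the line and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            if n == 0.0:
                raise ValueError("axis direction must be nonzero")
            d = d / n
        object.__setattr__(self, "direction", d)

    def distance_to(self, p: np.ndarray) -> float:
        """Perpendicular distance from point p to this line, mm."""
        return point_line_distance(p, self.point, self.direction)


def point_line_distance(p, line_point, line_dir) -> float:
    p = np.asarray(p, dtype=float)
    r = p - np.asarray(line_point, dtype=float)
    d = unit(line_dir)
    return float(np.linalg.norm(r - np.dot(r, d) * d))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right- or left-handed frame with a world origin.

    axes[:, 0], axes[:, 1], axes[:, 2] are the x/y/z unit vectors.
    """

    origin: np.ndarray
    axes: np.ndarray
    handedness: str = field(default="right")

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of column vectors")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        det = float(np.linalg.det(axes))
        handed = "right" if det > 0 else "left"
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if handed != self.handedness:
            raise ValueError(
                f"declared handedness {self.handedness!r} does not match "
                f"det = {det:+.3f}"
            )
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def axis(self, i: int, through: np.ndarray | None = None) -> Axis3D:
        """The i-th frame axis as a line through `through` (default origin)."""
        p = self.origin if through is None else np.asarray(through, float)
        return Axis3D(point=p, direction=self.axes[:, i])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express world points in this frame (rows of points are points)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - self.origin) @ self.axes
        return local[0] if np.asarray(points).ndim == 1 else local

    def to_world(self, local: np.ndarray) -> np.ndarray:
        loc = np.atleast_2d(np.asarray(local, dtype=float))
        world = loc @ self.axes.T + self.origin
        return world[0] if np.asarray(local).ndim == 1 else world


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed proper rotation matrix (QR of Gaussian)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
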