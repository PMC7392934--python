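"""Landmark- and mesh-based morphometry of the middle-ear ossicles.

Implements the measurement layer: characteristic lengths between named
landmarks and the center of mass, articular-surface area/centroid, the
total-least-squares footplate plane and projected footplate area, equivalent
diameters, the stapes local frame (x along the footplate long axis, y along
the short axis, z toward the stapes head), the global intrinsic frame, the
hinge-like rotational axis of the malleus-incus complex, and the lever arms
L1 (axis to umbo) / L2 (axis to incudostapedial-joint centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import Axis3D, AnatomicalFrame, canonical_direction, unit
from .io import LandmarkSet, SurfaceMesh

__all__ = [
    "SurfacePatch",
    "LeverGeometry",
    "point_distance",
    "characteristic_lengths",
    "patch_area_centroid",
    "fit_plane",
    "projected_area",
    "equivalent_diameter",
    "stapes_frame",
    "hinge_axis",
    "lever_geometry",
    "global_frame",
]


@dataclass(frozen=True)
class SurfacePatch:
    """A subset of a triangulated surface (open or closed), in mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices",
                           np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces",
                           np.asarray(self.faces, dtype=np.int64))

    @classmethod
    def from_mesh(cls, mesh: SurfaceMesh, face_indices=None) -> "SurfacePatch":
        faces = (mesh.faces if face_indices is None
                 else mesh.faces[np.asarray(face_indices)])
        return cls(vertices=mesh.vertices, faces=faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    @property
    def centroid(self) -> np.ndarray:
        a, c = patch_area_centroid(self)
        return c

    def transformed(self, rotation, translation) -> "SurfacePatch":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return SurfacePatch(vertices=self.vertices @ r.T + t,
                            faces=self.faces)


@dataclass(frozen=True)
class LeverGeometry:
    """Hinge axis and the two rotational lever arms of the ossicular chain."""

    axis: Axis3D
    l1: float           # axis -> umbo tip, mm
    l2: float           # axis -> ISJ centroid, mm
    ratio: float        # L1/L2
    d_axis_com: float   # axis -> chain COM, mm


def point_distance(p, q) -> float:
    """Euclidean 3D distance, mm."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


#: (length name, from, to) where 'com' refers to the supplied COM.
_LENGTH_DEFS = {
    "malleus": [
        ("L_mal", "head_tip", "umbo_tip"),
        ("L_manu", "lateral_process_tip", "umbo_tip"),
        ("L_head", "com", "head_tip"),
        ("L_umbo", "com", "umbo_tip"),
    ],
    "incus": [
        ("L_SP", "com", "short_process_tip"),
        ("L_LP", "com", "isj_centroid"),
    ],
    "stapes": [],
}

_RATIO_DEFS = {
    "malleus": [("L_manu/L_mal", "L_manu", "L_mal"),
                ("L_head/L_umbo", "L_head", "L_umbo")],
    "incus": [("L_SP/L_LP", "L_SP", "L_LP")],
    "stapes": [],
}


def characteristic_lengths(landmarks: LandmarkSet, ossicle: str,
                           com=None) -> dict:
    """Characteristic lengths and their ratios for one ossicle.

    COM-anchored lengths (L_head, L_umbo, L_SP, L_LP) are computed only when
    `com` is supplied.  Missing required landmarks raise a ValueError naming
    the landmark.
    """
    if ossicle not in _LENGTH_DEFS:
        raise ValueError(f"unknown ossicle kind {ossicle!r}")
    out: dict[str, float] = {}
    for name, a, b in _LENGTH_DEFS[ossicle]:
        if "com" in (a, b) and com is None:
            continue
        pa = np.asarray(com, float) if a == "com" else landmarks[a]
        pb = np.asarray(com, float) if b == "com" else landmarks[b]
        out[name] = point_distance(pa, pb)
    for name, num, den in _RATIO_DEFS[ossicle]:
        if num in out and den in out and out[den] > 0:
            out[name] = out[num] / out[den]
    return out


def patch_area_centroid(patch: SurfacePatch) -> tuple[float, np.ndarray]:
    """Total area (mm^2) and area-weighted centroid of a surface patch."""
    areas = patch.face_areas()
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("patch has zero total area")
    centroids = patch.triangles().mean(axis=1)
    return total, (areas[:, None] * centroids).sum(axis=0) / total


def fit_plane(patch: SurfacePatch) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane of a patch, area-weighted.

    Minimizes the area-weighted sum of squared orthogonal vertex distances
    (each face corner weighted by a third of its face area).  Returns
    (point_on_plane, unit_normal); raises on (near-)collinear patches.
    """
    areas = patch.face_areas()
    if areas.sum() <= 0:
        raise ValueError("cannot fit a plane to a zero-area patch")
    pts = patch.triangles().reshape(-1, 3)
    w = np.repeat(areas / 3.0, 3)
    mean = (w[:, None] * pts).sum(axis=0) / w.sum()
    centered = pts - mean
    cov = (w[:, None] * centered).T @ centered / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    # two near-zero eigenvalues => points are (nearly) collinear
    if evals[1] <= 1e-12 * max(evals[2], 1e-300):
        raise ValueError("patch vertices are collinear; plane is undefined")
    return mean, canonical_direction(evecs[:, 0])


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(n, helper))
    v = np.cross(n, u)
    return u, v


def projected_area(patch: SurfacePatch, plane=None) -> float:
    """Area of the single-counted planar region covered by the projected
    triangles, mm^2.

    Each triangle is orthogonally projected onto the plane (default: the
    patch's own total-least-squares plane) and the exact planar union of the
    projected polygons is taken, so folded or overhanging regions are not
    double-counted.  Always <= the 3D patch area.
    """
    if plane is None:
        plane = fit_plane(patch)
    point, normal = plane
    u, v = _plane_basis(normal)
    tri = patch.triangles() - np.asarray(point, float)
    uv = np.stack([tri @ u, tri @ v], axis=-1)  # (m, 3, 2)
    polys = []
    for corners in uv:
        p = Polygon(corners)
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        return 0.0
    return float(unary_union(polys).area)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: sqrt(4A/pi), mm."""
    if not (area > 0):
        raise ValueError("area must be > 0")
    return float(np.sqrt(4.0 * area / np.pi))


def _projected_principal_direction(patch: SurfacePatch, origin, normal):
    """In-plane long axis of the projected outline via area-weighted 2D
    second moments of the projected surface (rotation invariant)."""
    u, v = _plane_basis(normal)
    pts = patch.triangles().reshape(-1, 3) - np.asarray(origin, float)
    w = np.repeat(patch.face_areas() / 3.0, 3)
    uv = np.stack([pts @ u, pts @ v], axis=-1)
    mean = (w[:, None] * uv).sum(axis=0) / w.sum()
    c = uv - mean
    cov = (w[:, None] * c).T @ c / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    long2d = evecs[:, 1]  # larger variance
    return canonical_direction(long2d[0] * u + long2d[1] * v)


def stapes_frame(footplate: SurfacePatch, head: SurfacePatch,
                 side: str = "right"):
    """Local anatomical frame of the stapes from its footplate and head.

    Origin: centroid of the footplate medial surface.  z: footplate plane
    normal signed toward the head (lateral).  x: long in-plane principal
    direction of the projected footplate outline (anterior-posterior).
    y = z x x, flipped for left ears so that right ears give a right-handed
    frame.  Returns ``(frame, measurements)`` where measurements holds the
    footplate long/short lengths a >= b (extents along x/y) and the total
    stapes height h (footplate centroid to head centroid).
    """
    fp_area, fp_centroid = patch_area_centroid(footplate)
    _, head_centroid = patch_area_centroid(head)
    _, normal = fit_plane(footplate)
    signed = float(np.dot(head_centroid - fp_centroid, normal))
    if abs(signed) < 1e-9:
        raise ValueError(
            "head centroid lies in the footplate plane; cannot orient z")
    z = normal if signed > 0 else -normal
    x = _projected_principal_direction(footplate, fp_centroid, z)
    x = unit(x - np.dot(x, z) * z)
    y = np.cross(z, x)
    handedness = "right"
    if side == "left":
        y = -y
        handedness = "left"
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    frame = AnatomicalFrame(origin=fp_centroid,
                            axes=np.column_stack([x, y, z]),
                            handedness=handedness)
    verts = footplate.vertices[np.unique(footplate.faces)] - fp_centroid
    a = float(np.ptp(verts @ x))
    b = float(np.ptp(verts @ y))
    if b > a:  # long axis is x by construction, but guard degenerate covs
        a, b = b, a
    h = point_distance(fp_centroid, head_centroid)
    measurements = {"a": a, "b": b, "a/b": a / b if b > 0 else np.inf,
                    "h": h, "A_FT": fp_area}
    return frame, measurements


def stapes_com_coordinates(frame: AnatomicalFrame, com) -> dict:
    """COM of the stapes in its local frame: in-plane x_c, y_c and the height
    h_c, the Euclidean distance from the footplate centroid to the COM."""
    local = frame.to_local(np.asarray(com, float))
    return {"x_c": float(local[0]), "y_c": float(local[1]),
            "h_c": point_distance(frame.origin, com)}


def hinge_axis(anterior_process, incus_short_process_tip) -> Axis3D:
    """The hinge-like rotational axis of the malleus-incus complex: the line
    through the malleus anterior process and the incus short-process tip
    (the two skull-attachment points)."""
    p = np.asarray(anterior_process, float)
    q = np.asarray(incus_short_process_tip, float)
    d = q - p
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("hinge landmarks coincide; axis is undefined")
    return Axis3D(point=p, direction=canonical_direction(unit(d)))


def lever_geometry(axis: Axis3D, umbo_tip, isj_centroid,
                   com=None) -> LeverGeometry:
    """Lever arms of the hinge-like rotation.

    L1 and L2 are the perpendicular distances from the rotational axis to the
    umbo tip and to the centroid of the incus articular surface; their ratio
    sets the umbo-to-lenticular motion magnitude ratio.  L2 = 0 (ISJ centroid
    on the axis) makes the ratio undefined and raises.
    """
    l1 = axis.distance_to(umbo_tip)
    l2 = axis.distance_to(isj_centroid)
    if l2 <= 0 or l1 <= 0:
        raise ValueError("lever arm of zero length; ratio undefined")
    d_com = axis.distance_to(com) if com is not None else float("nan")
    return LeverGeometry(axis=axis, l1=l1, l2=l2, ratio=l1 / l2,
                         d_axis_com=d_com)


def global_frame(chain_com, stapes: AnatomicalFrame) -> AnatomicalFrame:
    """The global intrinsic frame: stapes-frame axes, origin at the COM of
    the entire ossicular chain."""
    return AnatomicalFrame(origin=np.asarray(chain_com, float),
                           axes=stapes.axes.copy(),
                           handedness=stapes.handedness)
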