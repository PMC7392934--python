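"""Volume, mesh and landmark I/O plus grayscale window segmentation.

Conventions (fixed package-wide):

* Voxel arrays are indexed ``values[ix, iy, iz]``; the world position of the
  *center* of voxel (i, j, k) is ``origin + spacing * (i, j, k)`` in mm.
* Grayscale levels are dimensionless 0-1000 (micro-CT evaluation-software
  scale); no attenuation calibration is applied.
* Left-ear landmark sets are mirrored (x -> -x) to a right-ear convention at
  load time and the flip is recorded, so downstream frame logic can assume a
  single handedness.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from . import _nrrd

__all__ = [
    "VoxelVolume",
    "SurfaceMesh",
    "LandmarkSet",
    "load_volume",
    "save_volume",
    "segment_window",
    "load_mesh",
    "save_mesh",
    "load_landmarks",
    "save_landmarks",
]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid with isotropic spacing — the mass-distribution carrier.

    Parameters
    ----------
    values : (nx, ny, nz) array
        Grayscale level or a 0/1 occupancy mask.
    spacing : float
        Edge length of one voxel, mm (isotropic).
    origin : (3,) array
        World position of the center of voxel (0, 0, 0), mm.
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("values must be a 3D array with all extents >= 1")
        if not (self.spacing > 0):
            raise ValueError("spacing must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", float(self.spacing))
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return self.spacing ** 3

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def occupied_centers(self) -> np.ndarray:
        """World coordinates (n, 3) of the centers of all nonzero voxels."""
        idx = np.argwhere(self.values != 0)
        return self.origin + idx * self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing


def load_volume(path, spacing_mm: float | None = None) -> VoxelVolume:
    """Load a multi-page TIFF stack or NRRD volume.

    TIFF carries no trustworthy physical spacing, so `spacing_mm` is required
    for TIFF.  NRRD spacing comes from the header unless overridden; an
    anisotropic header is a hard error (the pipeline assumes isotropic voxels).
    Grayscale values are preserved unmodified.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    origin = np.zeros(3)
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        # tifffile returns (pages, rows, cols) = (z, y, x) -> (x, y, z)
        arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
        if spacing_mm is None:
            raise ValueError(
                f"{path}: TIFF stacks carry no physical spacing; "
                "pass spacing_mm")
        spacing = float(spacing_mm)
    elif suffix == ".nrrd":
        arr, header = _nrrd.read(path)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NRRD, got {arr.ndim}D")
        sp = _nrrd.spacings_from_header(header)
        if spacing_mm is not None:
            spacing = float(spacing_mm)
        elif sp is not None:
            if np.ptp(sp) > 1e-6 * sp.max():
                raise ValueError(
                    f"{path}: anisotropic spacing {tuple(sp)} not supported")
            spacing = float(sp[0])
        else:
            raise ValueError(
                f"{path}: NRRD header has no spacing; pass spacing_mm")
        o = _nrrd.origin_from_header(header)
        if o is not None:
            origin = o
    else:
        raise ValueError(f"{path}: unsupported volume format {suffix!r}")
    return VoxelVolume(values=arr, spacing=spacing, origin=origin)


def save_volume(vol: VoxelVolume, path) -> None:
    """Write a volume as TIFF stack (spacing not stored) or NRRD."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(
            vol.values.transpose(2, 1, 0)), photometric="minisblack")
    elif suffix == ".nrrd":
        _nrrd.write(path, vol.values, vol.spacing, origin=vol.origin)
    else:
        raise ValueError(f"{path}: unsupported volume format {suffix!r}")


def segment_window(vol: VoxelVolume, lo: float, hi: float) -> VoxelVolume:
    """Binary mask of voxels with grayscale level in [lo, hi].

    This is the simple window-threshold entry point (the micro-CT evaluation
    software's 250-1000 grayscale selection); hand-drawn contouring is not
    reproduced.  Spacing and origin are preserved.  An empty mask is valid but
    suspicious, so it warns rather than raises.
    """
    if lo > hi:
        raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
    mask = ((vol.values >= lo) & (vol.values <= hi)).astype(np.uint8)
    if not mask.any():
        warnings.warn(
            f"segment_window([{lo}, {hi}]) produced an empty mask",
            stacklevel=2)
    return VoxelVolume(values=mask, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# meshes

@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface in mm: (n, 3) vertices, (m, 3) face indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices),
                   faces=np.asarray(tm.faces))

    def mirrored_x(self) -> "SurfaceMesh":
        """Mirror about the x = 0 plane, re-winding faces to keep orientation."""
        v = self.vertices.copy()
        v[:, 0] = -v[:, 0]
        return SurfaceMesh(vertices=v, faces=self.faces[:, ::-1])

    def enclosed_volume(self) -> float:
        """Volume enclosed by a closed, consistently oriented surface, mm^3."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise ValueError("enclosed volume requires a watertight mesh")
        return float(abs(tm.volume))


def load_mesh(path) -> SurfaceMesh:
    """Load an ASCII or binary STL; welds duplicate vertices and drops
    degenerate faces."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: missing or empty mesh file")
    try:
        tm = trimesh.load(path, force="mesh")
    except Exception as exc:  # trimesh raises various types on bad input
        raise ValueError(f"{path}: unreadable mesh ({exc})") from exc
    if tm is None or len(getattr(tm, "faces", ())) == 0:
        raise ValueError(f"{path}: mesh contains no faces")
    tm.merge_vertices()
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    return SurfaceMesh.from_trimesh(tm)


def save_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.to_trimesh().export(Path(path))


# ---------------------------------------------------------------------------
# landmarks

#: Required landmark names per ossicle (documented contract for morphometry).
REQUIRED_LANDMARKS = {
    "malleus": ("head_tip", "umbo_tip", "lateral_process_tip"),
    "incus": ("short_process_tip", "isj_centroid"),
    "stapes": ("footplate_center", "head_center"),
}


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points in mm for one specimen/ossicle.

    `mirrored` records whether a left-ear set was reflected (x -> -x) into the
    right-ear convention at load time.
    """

    points: dict
    side: str
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        pts = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} is not a finite 3D point")
            pts[str(name)] = arr
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(
                f"required landmark {name!r} missing; have "
                f"{sorted(self.points)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return sorted(self.points)

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise ValueError(f"missing required landmarks: {missing}")

    def mirrored_x(self) -> "LandmarkSet":
        pts = {k: np.array([-v[0], v[1], v[2]]) for k, v in self.points.items()}
        return LandmarkSet(points=pts, side=self.side,
                           mirrored=not self.mirrored)

    def transformed(self, rotation: np.ndarray, translation) -> "LandmarkSet":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(self, points={k: r @ v + t
                                     for k, v in self.points.items()})


def load_landmarks(path, mirror_left: bool = True) -> LandmarkSet:
    """Load landmarks from JSON or CSV.

    JSON schema: ``{"side": "left"|"right", "landmarks": {name: [x, y, z]}}``.
    CSV schema: columns ``name, x, y, z, side``.
    Duplicate names and non-finite coordinates are errors; a missing side
    field is an error.  Left-ear sets are mirrored to the right-ear
    convention unless ``mirror_left=False``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        def _no_dupes(pairs):
            keys = [k for k, _ in pairs]
            if len(keys) != len(set(keys)):
                dupes = sorted({k for k in keys if keys.count(k) > 1})
                raise ValueError(f"{path}: duplicate landmark names {dupes}")
            return dict(pairs)

        data = json.loads(path.read_text(), object_pairs_hook=_no_dupes)
        if "side" not in data:
            raise ValueError(f"{path}: missing required field 'side'")
        raw = data.get("landmarks", {})
        points, side = dict(raw), data["side"]
    elif path.suffix.lower() == ".csv":
        points = {}
        sides = set()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "side" not in reader.fieldnames:
                raise ValueError(f"{path}: missing required field 'side'")
            for row in reader:
                name = row["name"]
                if name in points:
                    raise ValueError(f"{path}: duplicate landmark {name!r}")
                points[name] = [float(row[c]) for c in ("x", "y", "z")]
                sides.add(row["side"])
        if len(sides) != 1:
            raise ValueError(f"{path}: expected one side, got {sorted(sides)}")
        side = sides.pop()
    else:
        raise ValueError(f"{path}: unsupported landmark format")
    lm = LandmarkSet(points=points, side=side)
    if mirror_left and side == "left":
        lm = lm.mirrored_x()
    return lm


def save_landmarks(lm: LandmarkSet, path) -> None:
    path = Path(path)
    payload = {
        "side": lm.side,
        "mirrored": lm.mirrored,
        "landmarks": {k: [float(x) for x in v] for k, v in lm.points.items()},
    }
    path.write_text(json.dumps(payload, indent=1))
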