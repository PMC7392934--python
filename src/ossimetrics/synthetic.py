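"""Synthetic ossicle phantoms with closed-form mass properties.

Real micro-CT scans of ossicles are not redistributable, so every other
module is exercised against phantoms built from analytic solids (spheres,
ellipsoids, elliptic cylinders, boxes) whose volume, center of mass and
inertia tensor are known in closed form and composed exactly via the tensor
parallel-axis rule.  The generator emits the same artifact set a scan
pipeline would: a grayscale volume (bone/low-density/background levels on
the 0-1000 scale, chosen so a 250-1000 window reproduces the bone mask
exactly), a binary mask, surface meshes, named landmarks, and a ground-truth
record.

A voxel is occupied iff its *center* lies inside the analytic solid,
matching the point-mass discretization used by the inertia code, so the
voxel-vs-analytic comparison bias is second order in the spacing.

``toy_ossicle`` builds stylized malleus / incus / stapes / chain fixtures at
sheep- or human-like scale: compact head plus slender handle, body plus two
processes, plate plus crura and head, with total lengths of 2-8 mm and
masses of a few to ~20 mg at bone-like density.  Characteristic lengths,
footplate axes, the hinge axis and the lever arms are all recorded
analytically at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import Axis3D, random_rotation, unit
from .io import LandmarkSet, SurfaceMesh, VoxelVolume
from .mass_properties import (MassProperties, combine_bodies,
                              mass_properties_from_tensor)
from .morphometry import SurfacePatch

__all__ = [
    "Sphere", "Ellipsoid", "Cylinder", "Box",
    "PhantomSpec", "VoxelizedPhantom", "ToyFixture",
    "voxelize", "analytic_mass_properties", "toy_ossicle",
    "brute_force_inertia",
    "elliptical_disc_patch", "spherical_cap_patch", "hemisphere_patch",
]

GRAY_BONE = 600
GRAY_LOW = 100
GRAY_BACKGROUND = 0


# ---------------------------------------------------------------------------
# analytic primitives

@dataclass(frozen=True)
class _Primitive:
    center: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    density_tag: str = "bone"

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))

    def _local(self, points: np.ndarray) -> np.ndarray:
        return (points - self.center) @ self.rotation

    def bounds(self) -> np.ndarray:
        """World AABB (2, 3) via the rotated local extents."""
        ext = np.abs(self.rotation) @ self._half_extents()
        return np.stack([self.center - ext, self.center + ext])


@dataclass(frozen=True)
class Sphere(_Primitive):
    radius: float = 1.0

    def contains(self, points):
        d = np.asarray(points, float) - self.center
        return np.einsum("...i,...i->...", d, d) <= self.radius ** 2

    def volume(self):
        return 4.0 / 3.0 * np.pi * self.radius ** 3

    def inertia_body(self, mass):
        return np.eye(3) * (0.4 * mass * self.radius ** 2)

    def _half_extents(self):
        return np.full(3, self.radius)


@dataclass(frozen=True)
class Ellipsoid(_Primitive):
    semi_axes: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        super().__post_init__()
        object.__setattr__(self, "semi_axes",
                           np.asarray(self.semi_axes, float))

    def contains(self, points):
        x = self._local(np.asarray(points, float)) / self.semi_axes
        return np.einsum("...i,...i->...", x, x) <= 1.0

    def volume(self):
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    def inertia_body(self, mass):
        a, b, c = self.semi_axes
        return np.diag([b * b + c * c, a * a + c * c, a * a + b * b]) \
            * (mass / 5.0)

    def _half_extents(self):
        return self.semi_axes


@dataclass(frozen=True)
class Cylinder(_Primitive):
    """Solid (possibly elliptic) cylinder; local z is the long axis."""

    radii: tuple = (1.0, 1.0)      # semi-axes of the cross-section
    half_length: float = 1.0

    def contains(self, points):
        x = self._local(np.asarray(points, float))
        p, q = self.radii
        inside_xy = (x[..., 0] / p) ** 2 + (x[..., 1] / q) ** 2 <= 1.0
        return inside_xy & (np.abs(x[..., 2]) <= self.half_length)

    def volume(self):
        p, q = self.radii
        return np.pi * p * q * 2.0 * self.half_length

    def inertia_body(self, mass):
        p, q = self.radii
        length = 2.0 * self.half_length
        return np.diag([
            mass * (q * q / 4.0 + length * length / 12.0),
            mass * (p * p / 4.0 + length * length / 12.0),
            mass * (p * p + q * q) / 4.0,
        ])

    def _half_extents(self):
        p, q = self.radii
        return np.array([p, q, self.half_length])


@dataclass(frozen=True)
class Box(_Primitive):
    half_extents: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        super().__post_init__()
        object.__setattr__(self, "half_extents",
                           np.asarray(self.half_extents, float))

    def contains(self, points):
        x = np.abs(self._local(np.asarray(points, float)))
        return np.all(x <= self.half_extents, axis=-1)

    def volume(self):
        return float(8.0 * np.prod(self.half_extents))

    def inertia_body(self, mass):
        p, q, w = self.half_extents
        return np.diag([q * q + w * w, p * p + w * w, p * p + q * q]) \
            * (mass / 3.0)

    def _half_extents(self):
        return self.half_extents


def _cylinder_between(p0, p1, radius, **kw) -> Cylinder:
    """Circular cylinder whose axis runs from p0 to p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    z = unit(axis)
    helper = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0, 1.0, 0])
    x = unit(np.cross(helper, z))
    y = np.cross(z, x)
    return Cylinder(center=(p0 + p1) / 2, rotation=np.column_stack([x, y, z]),
                    radii=(radius, radius), half_length=length / 2, **kw)


def analytic_mass_properties(primitives, density: float,
                             holes=()) -> MassProperties:
    """Closed-form mass properties of a union of non-overlapping primitives.

    `holes` are primitives fully contained in the solid and carved out; they
    enter the composition with negative mass.
    """
    parts = []
    for p in primitives:
        m = density * p.volume()
        inertia = p.rotation @ p.inertia_body(m) @ p.rotation.T
        parts.append(mass_properties_from_tensor(p.volume(), m, p.center,
                                                 inertia))
    for h in holes:
        m = -density * h.volume()
        inertia = h.rotation @ h.inertia_body(m) @ h.rotation.T
        parts.append(mass_properties_from_tensor(-h.volume(), m, h.center,
                                                 inertia))
    return combine_bodies(parts)


# ---------------------------------------------------------------------------
# voxelization

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one voxel phantom.

    `v_L` asks the voxelizer to carve a low-density spherical inclusion
    occupying approximately that fraction of the bone volume (emulating
    marrow spaces / blood vessels, which occupy up to ~14% of real ossicles).
    """

    primitives: tuple
    spacing: float = 0.02                   # mm
    v_L: float = 0.0
    levels: tuple = (GRAY_BONE, GRAY_LOW, GRAY_BACKGROUND)
    landmarks: dict = field(default_factory=dict)
    seed: int = 0
    bounds: np.ndarray | None = None        # optional (2, 3) world AABB
    padding_voxels: int = 2

    def __post_init__(self):
        if not (0.0 <= self.v_L <= 0.2):
            raise ValueError("v_L must be in [0, 0.2]")
        if not self.primitives:
            raise ValueError("spec needs at least one primitive")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic bookkeeping emitted next to every phantom."""

    mass_properties: MassProperties
    landmarks: dict
    realized_v_L: float
    seed: int
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VoxelizedPhantom:
    grayscale: VoxelVolume
    mask: VoxelVolume
    truth: GroundTruth


def _grid_for(spec: PhantomSpec):
    bounds = np.stack([
        np.min([p.bounds()[0] for p in spec.primitives], axis=0),
        np.max([p.bounds()[1] for p in spec.primitives], axis=0),
    ])
    if spec.bounds is not None:
        outer = np.asarray(spec.bounds, float)
        if np.any(bounds[0] < outer[0]) or np.any(bounds[1] > outer[1]):
            raise ValueError("primitive exceeds the requested volume bounds")
        bounds = outer
    pad = spec.padding_voxels * spec.spacing
    lo = bounds[0] - pad
    hi = bounds[1] + pad
    shape = np.maximum(np.ceil((hi - lo) / spec.spacing).astype(int), 1)
    origin = lo + spec.spacing / 2.0
    return origin, tuple(shape)


def _paint(primitive, origin, shape, spacing, out):
    """OR the primitive's occupancy into `out`, visiting only its AABB."""
    b = primitive.bounds()
    lo_idx = np.maximum(np.floor((b[0] - origin) / spacing).astype(int) - 1, 0)
    hi_idx = np.minimum(np.ceil((b[1] - origin) / spacing).astype(int) + 2,
                        shape)
    if np.any(lo_idx >= hi_idx):
        return
    crop = tuple(hi_idx - lo_idx)
    axes = [np.arange(lo_idx[k], hi_idx[k]) * spacing + origin[k]
            for k in range(3)]
    pts = np.empty((int(np.prod(crop)), 3))
    pts[:, 0] = np.repeat(axes[0], crop[1] * crop[2])
    pts[:, 1] = np.tile(np.repeat(axes[1], crop[2]), crop[0])
    pts[:, 2] = np.tile(axes[2], crop[0] * crop[1])
    inside = primitive.contains(pts).reshape(crop)
    sub = out[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
    sub |= inside


def _carve_inclusion(spec: PhantomSpec, rng: np.random.Generator):
    """A low-density sphere of the target volume fraction, fully inside a
    bone primitive (poles checked); None if v_L == 0."""
    if spec.v_L <= 0:
        return None
    bone = [p for p in spec.primitives if p.density_tag == "bone"]
    v_bone = sum(p.volume() for p in bone)
    r = (3.0 * spec.v_L * v_bone / (4.0 * np.pi)) ** (1.0 / 3.0)
    weights = np.array([p.volume() for p in bone])
    weights = weights / weights.sum()
    for _ in range(2000):
        host = bone[rng.choice(len(bone), p=weights)]
        lo, hi = host.bounds()
        c = rng.uniform(lo, hi)
        poles = c + r * np.concatenate([np.eye(3), -np.eye(3)])
        if host.contains(c[None])[0] and host.contains(poles).all():
            return Sphere(center=c, radius=r, density_tag="low")
    raise ValueError(
        f"could not place a low-density inclusion of radius {r:.3g} mm; "
        "reduce v_L or enlarge the bone primitives")


def voxelize(spec: PhantomSpec, density: float = 1.0) -> VoxelizedPhantom:
    """Rasterize a phantom spec into grayscale + mask volumes with analytic
    ground truth.

    The grayscale volume uses the spec's bone/low/background levels; the
    mask is the bone occupancy minus any low-density inclusion, i.e. exactly
    what a 250-1000 grayscale window recovers.  The ground-truth mass
    properties account for the carved inclusion analytically (negative-mass
    composition), so they describe the same solid the mask does.
    """
    rng = np.random.default_rng(spec.seed)
    origin, shape = _grid_for(spec)
    bone = np.zeros(shape, dtype=bool)
    for p in spec.primitives:
        if p.density_tag == "bone":
            _paint(p, origin, shape, spec.spacing, bone)
    inclusion = _carve_inclusion(spec, rng)
    low = np.zeros(shape, dtype=bool)
    if inclusion is not None:
        _paint(inclusion, origin, shape, spec.spacing, low)
        low &= bone
    n_bone_total = int(bone.sum())
    mask_arr = bone & ~low
    gray = np.full(shape, spec.levels[2], dtype=np.int16)
    gray[bone] = spec.levels[0]
    gray[low] = spec.levels[1]

    holes = (inclusion,) if inclusion is not None else ()
    mp = analytic_mass_properties(
        [p for p in spec.primitives if p.density_tag == "bone"],
        density, holes=holes)
    realized = float(low.sum()) / n_bone_total if n_bone_total else 0.0
    truth = GroundTruth(mass_properties=mp,
                        landmarks={k: np.asarray(v, float)
                                   for k, v in spec.landmarks.items()},
                        realized_v_L=realized, seed=spec.seed)
    return VoxelizedPhantom(
        grayscale=VoxelVolume(gray, spec.spacing, origin),
        mask=VoxelVolume(mask_arr.astype(np.uint8), spec.spacing, origin),
        truth=truth)


def brute_force_inertia(mask: VoxelVolume, density: float,
                        axis: Axis3D) -> float:
    """Independent oracle for the moment of inertia: a literal per-voxel
    sum of m_vox * r_perp^2 with no tensor algebra.  Test use only."""
    centers = mask.occupied_centers()
    m_vox = density * mask.voxel_volume
    rel = centers - axis.point
    along = rel @ axis.direction
    perp = rel - along[:, None] * axis.direction
    return float(m_vox * (perp * perp).sum())


# ---------------------------------------------------------------------------
# surface-patch generators (analytic areas)

def elliptical_disc_patch(a: float, b: float, center=(0, 0, 0),
                          rotation=None, n_ring: int = 12,
                          n_sector: int = 96) -> SurfacePatch:
    """Flat triangulated elliptical disc with semi-axes a >= b in its local
    x/y plane.  Polygonal area approaches pi*a*b as n_sector grows."""
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
    center = np.asarray(center, float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_sector, endpoint=False)
    verts = [np.zeros(3)]
    for i in range(1, n_ring + 1):
        f = i / n_ring
        ring = np.stack([f * a * np.cos(theta), f * b * np.sin(theta),
                         np.zeros_like(theta)], axis=1)
        verts.append(ring)
    verts = np.vstack([verts[0][None], *verts[1:]])
    faces = []
    for s in range(n_sector):
        faces.append([0, 1 + s, 1 + (s + 1) % n_sector])
    for i in range(n_ring - 1):
        base0 = 1 + i * n_sector
        base1 = 1 + (i + 1) * n_sector
        for s in range(n_sector):
            s2 = (s + 1) % n_sector
            faces.append([base0 + s, base1 + s, base1 + s2])
            faces.append([base0 + s, base1 + s2, base0 + s2])
    return SurfacePatch(vertices=verts @ rotation.T + center,
                        faces=np.array(faces))


def spherical_cap_patch(radius: float, half_angle: float, center=(0, 0, 0),
                        rotation=None, n_theta: int = 48,
                        n_phi: int = 96) -> SurfacePatch:
    """Spherical cap (polar angle 0..half_angle about local +z), centered on
    the sphere center.  Analytic area 2 pi R^2 (1 - cos half_angle);
    projected area onto the local equatorial plane pi (R sin half_angle)^2."""
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
    center = np.asarray(center, float)
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    verts = [np.array([0.0, 0.0, radius])]
    for i in range(1, n_theta + 1):
        th = half_angle * i / n_theta
        ring = np.stack([radius * np.sin(th) * np.cos(phis),
                         radius * np.sin(th) * np.sin(phis),
                         np.full_like(phis, radius * np.cos(th))], axis=1)
        verts.append(ring)
    verts = np.vstack([verts[0][None], *verts[1:]])
    faces = []
    for s in range(n_phi):
        faces.append([0, 1 + s, 1 + (s + 1) % n_phi])
    for i in range(n_theta - 1):
        base0 = 1 + i * n_phi
        base1 = 1 + (i + 1) * n_phi
        for s in range(n_phi):
            s2 = (s + 1) % n_phi
            faces.append([base0 + s, base1 + s, base1 + s2])
            faces.append([base0 + s, base1 + s2, base0 + s2])
    return SurfacePatch(vertices=verts @ rotation.T + center,
                        faces=np.array(faces))


def hemisphere_patch(radius: float = 1.0, **kw) -> SurfacePatch:
    """Open hemisphere: a spherical cap with a 90-degree half angle."""
    return spherical_cap_patch(radius, np.pi / 2.0, **kw)


# ---------------------------------------------------------------------------
# toy ossicles

#: Stylized per-species dimensions (mm, mg/mm^3), near adult means:
#: sheep malleus total length ~7.9 mm, human ~8.2 mm; sheep footplate
#: 2.03 x 0.93 mm, human 2.81 x 1.27 mm; bone-like density ~2.2.
SCALES = {
    "sheep": dict(
        L_mal=7.88, L_manu=5.26, head_r=1.00, handle_r=0.30,
        incus_body_r=0.85, sp_len=1.90, sp_r=0.25, lp_len=1.00, lp_r=0.22,
        isj_a=0.45, isj_b=0.30,
        fp_a=2.03, fp_b=0.93, fp_t=0.20, st_h=2.10, st_head_r=0.35,
        crus_r=0.12, density=2.2,
        chain=dict(L1=4.16, L2=1.69, axis_y=0.55, axis_z=0.85),
    ),
    "human": dict(
        L_mal=8.15, L_manu=4.78, head_r=1.35, handle_r=0.35,
        incus_body_r=1.10, sp_len=1.80, sp_r=0.30, lp_len=2.60, lp_r=0.25,
        isj_a=0.32, isj_b=0.24,
        fp_a=2.81, fp_b=1.27, fp_t=0.25, st_h=3.28, st_head_r=0.45,
        crus_r=0.15, density=2.3,
        chain=dict(L1=2.50, L2=2.00, axis_y=0.60, axis_z=0.90),
    ),
}


@dataclass(frozen=True)
class ToyFixture:
    """Everything the rest of the pipeline needs for one synthetic specimen."""

    kind: str
    scale: str
    spec: PhantomSpec
    grayscale: VoxelVolume
    mask: VoxelVolume
    mesh: SurfaceMesh
    landmarks: LandmarkSet
    patches: dict
    truth: GroundTruth
    density: float


def _primitives_to_mesh(primitives) -> SurfaceMesh:
    metas = []
    for p in primitives:
        t = np.eye(4)
        t[:3, :3] = p.rotation
        t[:3, 3] = p.center
        if isinstance(p, Sphere):
            tm = trimesh.creation.icosphere(subdivisions=2, radius=p.radius)
            tm.apply_transform(t)
        elif isinstance(p, Ellipsoid):
            tm = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
            tm.apply_scale(p.semi_axes)
            tm.apply_transform(t)
        elif isinstance(p, Cylinder):
            tm = trimesh.creation.cylinder(radius=1.0,
                                           height=2 * p.half_length,
                                           sections=32)
            tm.vertices[:, 0] *= p.radii[0]
            tm.vertices[:, 1] *= p.radii[1]
            tm.apply_transform(t)
        elif isinstance(p, Box):
            tm = trimesh.creation.box(extents=2 * p.half_extents)
            tm.apply_transform(t)
        else:  # pragma: no cover
            raise TypeError(f"no mesh rule for {type(p).__name__}")
        metas.append(tm)
    return SurfaceMesh.from_trimesh(trimesh.util.concatenate(metas))


def _rigid_from_seed(seed):
    """Seeded random rotation + modest translation; identity for seed None."""
    if seed is None:
        return np.eye(3), np.zeros(3)
    rng = np.random.default_rng(seed)
    return random_rotation(rng), rng.uniform(-2.0, 2.0, size=3)


def _apply_rigid(primitives, rot, trans):
    out = []
    for p in primitives:
        out.append(replace(p, center=rot @ p.center + trans,
                           rotation=rot @ p.rotation))
    return tuple(out)


def _malleus_parts(s):
    head = Sphere(center=np.zeros(3), radius=s["head_r"])
    umbo_z = s["head_r"] - s["L_mal"]
    handle = Cylinder(center=np.array([0, 0, (umbo_z - s["head_r"]) / 2]),
                      radii=(s["handle_r"], s["handle_r"]),
                      half_length=(-umbo_z - s["head_r"]) / 2 + 1e-12)
    landmarks = {
        "head_tip": np.array([0.0, 0.0, s["head_r"]]),
        "umbo_tip": np.array([0.0, 0.0, umbo_z]),
        "lateral_process_tip": np.array([0.0, 0.0, umbo_z + s["L_manu"]]),
        "anterior_process": np.array([0.8 * s["head_r"], 0.0,
                                      -0.5 * s["head_r"]]),
    }
    return (head, handle), landmarks


def _incus_parts(s):
    body = Sphere(center=np.zeros(3), radius=s["incus_body_r"])
    d_sp = np.array([1.0, 0.0, 0.0])
    d_lp = unit(np.array([-0.423, 0.0, -0.906]))
    rb = s["incus_body_r"]
    sp = _cylinder_between(rb * d_sp, (rb + s["sp_len"]) * d_sp, s["sp_r"])
    lp = _cylinder_between(rb * d_lp, (rb + s["lp_len"]) * d_lp, s["lp_r"])
    landmarks = {
        "short_process_tip": (rb + s["sp_len"]) * d_sp,
        "isj_centroid": (rb + s["lp_len"]) * d_lp,
    }
    extras = {"isj_normal": d_lp}
    return (body, sp, lp), landmarks, extras


def _stapes_parts(s):
    a2, b2 = s["fp_a"] / 2.0, s["fp_b"] / 2.0
    plate = Cylinder(center=np.array([0, 0, s["fp_t"] / 2]),
                     radii=(a2, b2), half_length=s["fp_t"] / 2)
    head_c = np.array([0, 0, s["st_h"] - s["st_head_r"]])
    head = Sphere(center=head_c, radius=s["st_head_r"])
    crus_top = s["st_h"] - 2 * s["st_head_r"]
    crura = tuple(
        _cylinder_between(np.array([x, 0, s["fp_t"]]),
                          np.array([x, 0, max(crus_top, s["fp_t"] + 0.1)]),
                          s["crus_r"])
        for x in (-a2 / 2.0, a2 / 2.0))
    landmarks = {
        "footplate_center": np.zeros(3),
        "head_center": np.array([0.0, 0.0, s["st_h"]]),
    }
    return (plate, head) + crura, landmarks


def _stapes_patches(s, rot, trans):
    flip = np.diag([1.0, -1.0, -1.0])  # medial surface faces -z
    fp = elliptical_disc_patch(s["fp_a"] / 2.0, s["fp_b"] / 2.0,
                               center=trans, rotation=rot @ flip)
    head = elliptical_disc_patch(0.22, 0.22,
                                 center=rot @ np.array([0, 0, s["st_h"]])
                                 + trans, rotation=rot)
    return {"footplate": fp, "head": head}


def _chain_layout(s):
    """World placement of the three ossicles so that the hinge axis runs
    along +x (anterior-posterior) and L1/L2 match the scale's targets."""
    c = s["chain"]
    ay, az = c["axis_y"], c["axis_z"]
    anterior_process = np.array([1.5, ay, az])
    short_process_tip = np.array([-2.2, ay, az])
    # stapes medial, footplate normal toward +z (lateral)
    s0 = np.array([0.0, 0.0, -3.0])
    isj = np.array([0.0, 0.0, -3.0 + s["st_h"] + 0.15])
    # place the ISJ at exactly L2 from the axis by sliding it in y/z
    d_isj = np.array([0.0, isj[1] - ay, isj[2] - az])
    isj = np.array([isj[0], ay, az]) + c["L2"] * unit(d_isj)
    # umbo: 45-degree anteroinferior tilt in the y/z plane, L1 off the axis
    u_dir = unit(np.array([0.0, -1.0, 1.0]))
    umbo = np.array([2.0, ay, az]) + c["L1"] * u_dir
    return dict(anterior_process=anterior_process,
                short_process_tip=short_process_tip,
                stapes_origin=s0, isj=isj, umbo=umbo)


def _chain_parts(s):
    lay = _chain_layout(s)
    # malleus: head near the anterior end of the axis, handle toward the umbo
    m0 = lay["anterior_process"] + np.array([-0.3, 0.55, 0.35])
    dh = unit(lay["umbo"] - m0)
    head = Sphere(center=m0, radius=s["head_r"])
    handle = _cylinder_between(m0 + s["head_r"] * dh, lay["umbo"],
                               s["handle_r"])
    head_tip = m0 - s["head_r"] * dh
    umbo = lay["umbo"]
    lateral_process = umbo + s["L_manu"] * unit(head_tip - umbo)

    # incus: body between the posterior axis end and the ISJ
    i0 = np.array([-1.0, 0.9, 0.6])
    body = Sphere(center=i0, radius=s["incus_body_r"])
    sp_dir = unit(lay["short_process_tip"] - i0)
    lp_dir = unit(lay["isj"] - i0)
    sp = _cylinder_between(i0 + s["incus_body_r"] * sp_dir,
                           lay["short_process_tip"], s["sp_r"])
    lp = _cylinder_between(i0 + s["incus_body_r"] * lp_dir,
                           lay["isj"], s["lp_r"])

    stapes_parts, stapes_lm = _stapes_parts(s)
    stapes_parts = _apply_rigid(stapes_parts, np.eye(3), lay["stapes_origin"])

    parts = (head, handle, body, sp, lp) + stapes_parts
    part_groups = {"malleus": (head, handle), "incus": (body, sp, lp),
                   "stapes": stapes_parts}
    landmarks = {
        "head_tip": head_tip,
        "umbo_tip": umbo,
        "lateral_process_tip": lateral_process,
        "anterior_process": lay["anterior_process"],
        "short_process_tip": lay["short_process_tip"],
        "isj_centroid": lay["isj"],
        "footplate_center": stapes_lm["footplate_center"]
        + lay["stapes_origin"],
        "head_center": stapes_lm["head_center"] + lay["stapes_origin"],
    }
    return parts, part_groups, landmarks, lay


def toy_ossicle(kind: str, scale: str = "sheep", seed: int | None = 0,
                spacing: float | None = None) -> ToyFixture:
    """Build one synthetic ossicle (or the assembled chain) fixture.

    A seeded random rigid transform is applied to the whole construction so
    fixtures are not axis-aligned; ``seed=None`` keeps the canonical pose.
    The truth record carries the analytic mass properties, landmark world
    positions, characteristic lengths and — for the chain — the hinge axis,
    L1, L2 and the axis-to-COM distance, all computed at generation time.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    s = SCALES[scale]
    density = s["density"]
    rot, trans = _rigid_from_seed(seed)
    patches: dict = {}
    extras: dict = {}

    if kind == "malleus":
        parts, lms = _malleus_parts(s)
        default_spacing = 0.025
        extras.update(L_mal=s["L_mal"], L_manu=s["L_manu"])
    elif kind == "incus":
        parts, lms, inc_extras = _incus_parts(s)
        default_spacing = 0.02
        isj = lms["isj_centroid"]
        n = inc_extras["isj_normal"]
        helper = np.array([0.0, 1.0, 0.0])
        x = unit(np.cross(n, helper))
        patches["isj"] = elliptical_disc_patch(
            s["isj_a"], s["isj_b"], center=isj,
            rotation=np.column_stack([x, np.cross(n, x), n]))
        extras["A_ISJ"] = np.pi * s["isj_a"] * s["isj_b"]
    elif kind == "stapes":
        parts, lms = _stapes_parts(s)
        default_spacing = 0.015
        patches = _stapes_patches(s, np.eye(3), np.zeros(3))
        extras.update(a=s["fp_a"], b=s["fp_b"], h=s["st_h"],
                      A_FT=np.pi * s["fp_a"] * s["fp_b"] / 4.0)
    elif kind == "chain":
        parts, groups, lms, lay = _chain_parts(s)
        default_spacing = 0.03
        patches = _stapes_patches(s, np.eye(3), lay["stapes_origin"])
        extras["part_groups"] = {
            name: analytic_mass_properties(
                _apply_rigid(g, rot, trans), density)
            for name, g in groups.items()}
        extras.update(L1=s["chain"]["L1"], L2=s["chain"]["L2"])
    else:
        raise ValueError(f"unknown ossicle kind {kind!r}")

    parts = _apply_rigid(parts, rot, trans)
    lms = {k: rot @ v + trans for k, v in lms.items()}
    patches = {k: p.transformed(rot, trans) for k, p in patches.items()}

    spec = PhantomSpec(primitives=parts,
                       spacing=spacing or default_spacing,
                       landmarks=lms, seed=0 if seed is None else seed)
    phantom = voxelize(spec, density=density)
    mp = phantom.truth.mass_properties

    if kind == "chain":
        axis = Axis3D(point=lms["anterior_process"],
                      direction=unit(lms["short_process_tip"]
                                     - lms["anterior_process"]))
        extras["hinge_axis"] = axis
        extras["L1_realized"] = axis.distance_to(lms["umbo_tip"])
        extras["L2_realized"] = axis.distance_to(lms["isj_centroid"])
        extras["d_axis_com"] = axis.distance_to(mp.com)
        extras["stapes_axes"] = rot.copy()   # world stapes-frame axes

    truth = GroundTruth(mass_properties=mp, landmarks=lms,
                        realized_v_L=phantom.truth.realized_v_L,
                        seed=0 if seed is None else seed, extras=extras)
    return ToyFixture(kind=kind, scale=scale, spec=spec,
                      grayscale=phantom.grayscale, mask=phantom.mask,
                      mesh=_primitives_to_mesh(parts),
                      landmarks=LandmarkSet(points=lms, side="right"),
                      patches=patches, truth=truth, density=density)
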