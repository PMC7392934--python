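# Methods

## Scope and data model

The package computes rigid-body inertial properties and landmark/mesh
morphometry of middle-ear ossicles and feeds the results into an
ideal-transformer model of middle-ear impedance matching. Its entry points
are pre-segmented data: binary voxel masks (or grayscale volumes plus a
window threshold), STL surface meshes, and named landmark coordinates.
Scanner physics, hand contouring and manual landmark picking are upstream
of the package and out of scope.

Conventions, fixed throughout:

* Arrays are indexed `values[ix, iy, iz]`; the world position of the center
  of voxel `(i, j, k)` is `origin + spacing·(i, j, k)` in mm. Spacing is
  isotropic; anisotropic volumes are rejected rather than resampled.
* Units are mm / mg / mg·mm² (density mg/mm³, numerically equal to g/cm³).
* Grayscale levels are the dimensionless 0–1000 scale of micro-CT
  evaluation software (0 = no attenuation, 1000 = maximum); no attenuation
  calibration is performed. The default segmentation window is 250–1000.
* Left-ear landmark sets are mirrored (x → −x) into a right-ear convention
  at load time, with the flip recorded, so the stapes frame logic can
  assume one handedness (right ears give a right-handed frame).

## Voxel inertia

The inertia integral `I = ∫ r² dm` is discretized with one point mass at
the center of each occupied voxel: `V = n·s³`, `m = ρV`, COM = mean of
occupied centers, and the COM inertia tensor from second moments of the
centered coordinates. An optional per-voxel solid-cube correction
(`+ m_vox s²/6` on each diagonal entry) is available behind a flag and off
by default; both discretizations converge to the same limit, and the
point-mass form is the standard convention for ossicle inertia, so it is
the default. A consequence worth knowing: a single voxel has exactly zero
inertia under the default.

Low-density interior structure (marrow spaces, vessels) is excluded from
the mask and carries zero mass, matching how ossicle masks are usually
produced; the formula `ρ_H = (m − v_L ρ_L V)/((1 − v_L)V)` is provided to
quantify what assigning a density to that volume fraction would change.
The companion *relative factor* is defined as
`(ρ_H(ρ_L=0) − ρ_H(ρ_L))/ρ_H(ρ_L=0) = v_L ρ_L V/m`, i.e. normalized by the
zero-assignment estimate — with the sheep-chain reference values
(m = 22.9 mg, V = 10.4 mm³, water ρ_L = 1) this evaluates to 0.45% at
v_L = 1% and 0.91% at v_L = 2%.

Principal decomposition uses a symmetric eigensolver with moments sorted
ascending and a deterministic sign convention: each axis is flipped so its
largest-magnitude component is positive (ties broken by the first nonzero
component), and the determinant is forced to +1 by flipping the last axis.
For (near-)degenerate spectra — a sphere — any orthonormal eigenbasis is
valid, so comparisons there should be on moments, not axes. Axis moments
are `nᵀ I_COM n + m d²`; composite bodies are combined by transporting each
part's tensor to the joint COM with the tensor parallel-axis rule.

## Morphometry

* Characteristic lengths are Euclidean distances between landmarks, with
  COM-anchored lengths (`L_head`, `L_umbo`, `L_SP`, `L_LP`) evaluated only
  when a COM is supplied (normally from the voxel mask).
* Patch area is the triangle-area sum; the patch centroid is area-weighted.
* The footplate plane is a total-least-squares fit minimizing area-weighted
  orthogonal distances (each face corner weighted by a third of its face
  area). Collinear degenerate patches are rejected.
* Projected area: each triangle is orthogonally projected onto the plane
  and the **exact planar union** of the projected polygons is taken
  (shapely), so folds and overhangs are counted once. This replaces a
  rasterization approach: the union is exact, has no resolution parameter,
  and is cheap at patch sizes of interest. `A_proj ≤ A` always.
* The stapes frame takes the footplate-surface centroid as origin, the
  fitted-plane normal signed toward the head centroid as z (lateral), and
  the long in-plane axis of the projected outline as x. The long axis is
  operationalized as the major principal direction of the area-weighted 2D
  second moments of the projected surface — rotation invariant and
  faithful to "long and short axes" of an oval plate. `a`, `b` are vertex
  extents along x and y; `h` is the footplate-to-head centroid distance;
  `h_c` is the **Euclidean** distance from the footplate centroid to the
  COM (not its z-component), with `x_c`, `y_c` the in-plane COM
  coordinates.
* The hinge axis passes through the malleus anterior process and the incus
  short-process tip; its direction is sign-normalized so the two point
  orders give the same line. `L1`, `L2`, and the axis–COM distance are
  perpendicular point-to-line distances; `L2 = 0` makes the lever ratio
  undefined and raises.
* Ratio aggregation: per-specimen ratios are averaged (mean of ratios, the
  convention behind tabulated ratio ± SD), and a ratio-of-means column is
  emitted alongside, clearly labeled — the two differ in the second decimal
  for realistic cohorts (e.g. 2.47 vs 4.16/1.69 = 2.46 for the sheep lever
  ratio).

## Transformer model

The chain is treated as an ideal transformer with ratio
`(A_TM/A_FP)·(L1/L2)` for pressure and `(A_TM/A_FP)·(L1/L2)²` for
impedance: `Z_TM = Z_cochlea / ((A_TM/A_FP)(L1/L2)²)` and transmitted
energy `T = 4 Z_air Z_TM/(Z_air + Z_TM)²` — the standard two-medium power
transmission coefficient, 1 exactly at impedance match. The cited source
for these relations does not reprint them; this reconstruction is accepted
because it reproduces all four published worked values (Z_TM 1500 and
301 Pa·s/m; T 68% and 97%) to rounding, and that validation is encoded in
the test suite. All impedances are specific acoustic impedances (Pa·s/m);
`Z_cochlea` is a frequency-independent scalar (56 kPa·s/m by default,
Z_air 420 Pa·s/m) — frequency-resolved middle-ear transfer functions are a
non-goal. Default species parameterizations: human A_TM = 68.3 mm²,
A_FP = 2.86 mm², lever 1.25; sheep 44.2 mm², 1.45 mm², 2.47. The footplate
area used in the area ratio is the **projected** area, which is the
acoustically relevant piston area and reproduces the published area ratios
(23.9, 30.5).

## Synthetic phantoms

The generator emulates what the pipeline would receive from a scan — a
grayscale volume (bone 600, low-density 100, background 0, so the 250–1000
window recovers the bone mask exactly), a mask, STL meshes, landmarks —
from unions of analytic solids with closed-form volume and inertia,
composed by the parallel-axis rule. A voxel is occupied iff its center
lies inside the solid, matching the point-mass discretization so the
voxel-vs-analytic bias is second order in spacing. Low-density inclusions
are carved as a single sphere of the radius that realizes the requested
volume fraction, placed at a seeded random interior point; the ground
truth subtracts it analytically (negative-mass composition), so truth and
mask always describe the same solid. Same seed → bit-identical output.

The toy ossicles are stylized, not anatomical: a sphere head with a
slender cylindrical handle (malleus), a sphere body with two cylindrical
processes (incus), an elliptic-cylinder plate with crura and a sphere head
(stapes), at sheep- or human-like scale (total lengths 2–8 mm, masses
~1–20 mg, density 2.2–2.3 mg/mm³, footplates 2.03×0.93 and 2.81×1.27 mm).
Key dimensions are exact by construction (e.g. sheep `L_mal` = 7.88 mm,
chain `L1` = 4.16, `L2` = 1.69 mm), and a seeded random rigid transform is
applied so nothing is axis-aligned. What the phantoms deliberately lack:
trabecular texture, scanner noise and beam hardening, curved anatomical
surfaces, realistic joint geometry. Tests passing on phantoms therefore
validate the *computational chain* (segmentation → inertia → morphometry →
transformer), not the segmentation of real scans.

## Numerical choices and problem sizes

* Default phantom spacings: 0.02–0.03 mm per ossicle (0.025 for the
  malleus, 0.03 for the chain), giving voxel-vs-analytic agreement of
  ~3×10⁻⁴ relative on principal moments — two orders below the 1%
  acceptance band — at a few seconds per fixture.
* The convergence check runs the analytic ellipsoid (0.8, 0.4, 0.2 mm) at
  spacings 0.0125/0.00625/0.003125 mm; the finest puts 64 voxels across
  the shortest semi-axis and the max-norm principal-moment error decreases
  monotonically to ~6×10⁻⁵.
* Plane fitting and frame construction use `eigh` on 3×3 covariance
  matrices; frames validate orthonormality at 1e-8 and declared handedness
  against the determinant sign.
* The NRRD reader/writer is a deliberately minimal in-package codec
  (attached data, raw/gzip, little-endian, `spacings` or diagonal
  `space directions`) — enough for the pipeline's own round-trips; exotic
  NRRD features are out of scope. STL goes through trimesh, TIFF through
  tifffile.
* Reports are timestamp-free and deterministic; CSVs keep full precision.

## Known limitations

* Masks are taken at face value; no morphological cleanup, connected-
  component filtering, or contour editing is applied.
* Uniform density per ossicle; grayscale-calibrated density fields are not
  supported.
* The transformer model is the low-frequency ideal-transformer idealization
  with a scalar cochlear load; it is a comparative index, not a transfer
  function.
* The footplate long-axis operationalization (projected second moments) is
  one reasonable choice among several; for strongly non-elliptical
  footplates other definitions could differ by a few degrees.
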