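# Methods

## Coordinate conventions

Room frame: right-handed, +x toward patient-left (LR), +y superior (SI),
+z anterior (AP); all lengths in mm, angles in deg. A motion estimate is a
proper rigid transform mapping reference-surface coordinates to the current
target surface, so the registration output *is* the patient motion. 6-DoF
reports use extrinsic Euler angles about the fixed room axes in x→y→z order
(`R = Rz·Ry·Rx`). No convention is canonical for this; at the ≤5 deg
motions the system is designed for, the ordering effect is second order,
and the choice is fixed and documented rather than configurable. Extraction
fails loudly at |ry| = 90 deg (gimbal lock) instead of returning an
arbitrary decomposition.

## Registration model

The tracker minimizes the weighted point-to-plane cost
`Σ w_pq ((p − T q)·n_p)²` over rigid `T`. Inner loop per iteration:

1. **Correspondences.** Each valid target point is paired with its nearest
   reference point within a gating distance, via a KD-tree. Because rigid
   maps preserve distances, the query runs as `T⁻¹p` against a tree built
   once over the untransformed reference — the tree is then reusable across
   IRLS iterations, pyramid levels, and whole tracking sessions.
2. **Reweighting.** IRLS weights from Barron's generalized robust loss:
   `w(r) = ((r/c)²/|α−2| + 1)^(α/2−1)`, normalized so `w(0)=1`, with the
   quadratic case α=2 handled exactly (w≡1). Default α = 1.0 (pseudo-Huber
   regime: quadratic near zero, linear tails) — robust enough to downweight
   deforming or mismatched patches without the aggressive truncation of
   Cauchy-type losses. Scale `c = max(2·voxel edge, 1 mm)` ties the
   transition point to the current resolution. Weights are recomputed every
   iteration; c is fixed per level (no annealing) for reproducibility.
3. **Increment.** One damped Gauss-Newton step of the small-angle
   linearization: solve the 6×6 normal equations for (ω, t) with rotation
   taken about the correspondence centroid (better conditioning), re-map to
   a rigid increment via the rotation-vector exponential, and halve the
   step until the cost on the *same* correspondence set does not increase.
   Rank deficiency (all normals within a plane pencil, fewer than 6 pairs)
   raises a degenerate-geometry error rather than returning a garbage pose.

Convergence: increment below 0.01 mm and 0.01 deg, or 30 iterations per
level. The rotation is re-orthonormalized (SVD) after every update.

### Multiscale schedule

Five levels at densities log-spaced from 0.2 to 100 points/cm²
({0.2, 0.95, 4.5, 21, 100}); the endpoints are the published operating
range of this class of tracker, the interior spacing is ours. Each level
registers both clouds voxel-downsampled to its density (voxel edge
`sqrt(1/density)`, centroid representative, averaged re-normalized
normals), warm-started from the previous level. The correspondence gate is
4 voxel edges per level — coarse levels tolerate large initial error, fine
levels reject spurious pairs. Target normals are computed once at full
resolution and carried through the voxel averaging, avoiding the bias of
re-estimating normals on sparse clouds. The target pyramid is built
fine-to-coarse (each coarser level reduces the previous output), which is
numerically equivalent for centroid voxelization and much cheaper.

## Tracking

The user-defined ROI (an *oriented* box, so rotation propagation is exact)
crops only the first frame as given. For frame k the ROI is derived from
the original box and the **total** current estimate `T_k` — never chained
incrementally — so box-pose drift cannot accumulate. The previous estimate
also initializes the registration. Failure policy (empty crop,
no correspondences, degenerate geometry): hold the last estimate, flag the
sample `converged=false`, retry the next frame with the last good ROI. The
reference is the first frame of the session by default; an imported PLY
surface in room coordinates (e.g. extracted from a planning CT) is equally
valid.

## Calibration

Each sensor is mapped to the room frame by a closed-form least-squares
rigid fit (Kabsch/SVD with the det+1 correction) on ≥3 labeled,
non-collinear fiducials; correspondence is by label order (a survey jig has
known labels — no automatic matching). The RMS residual doubles as the
verification metric with a 0.5 mm default threshold, chosen as half the
millimeter-level system accuracy; failures report the worst fiducial.
Fusion maps each sensor cloud through its calibration and concatenates,
with optional voxel thinning of overlap duplicates at the finest schedule
density.

## Simulator

**Phantom.** A superellipsoid cranium (semi-axes 75 × 105 × 85 mm LR/SI/AP,
exponent 2.2, ~39k triangles) with radial-displacement features: nose ridge
(25 mm), eye-socket depressions (−4 mm), chin (6 mm), cheeks (3 mm), plus a
seeded low-order random relief (0.8 mm) so phantoms are individual yet
reproducible. Vertices carry anatomy labels (forehead, nose, cheeks, jaw,
brow, larynx) used by the deformation generator and by visibility audits.

**Cameras.** Two pinhole depth cameras, 848×480 px with a 65°×40° field of
view, flanking the head at (±300, −270, 200) mm looking at the face —
couch-mounted positions about 30 cm above the torso plane, ~450 mm range,
chosen so each camera sees the forehead and its own cheek (nose
self-occlusion shadows the far cheek, which the z-buffer renderer
reproduces). Rendering is a numba-jitted triangle rasterizer with
perspective-correct 1/z interpolation; back-projection yields one
room-frame point per hit pixel, with normals from wide-stencil (±3 px)
central differences of the point grid, invalidated at depth discontinuities
and image borders.

**Noise.** Axial Gaussian noise along the viewing ray with
`σ(z) = σ₀·(z/450 mm)²` and σ₀ = 1 mm — the quadratic range dependence of
stereo-disparity error, with a magnitude plausible for consumer stereo
depth modules; quantization 0.25 mm; optional per-pixel dropout. All
randomness derives from one session seed; frame k / camera j uses
`default_rng([seed, k, j])`, so sessions are bit-reproducible.

**Motion protocols.** The staircase protocol steps each axis in turn
through −5…+5 mm (1 mm steps) and −5…+5 deg (1 deg steps): 11 poses × 6
axes = 66 commanded poses, dwelling 5 frames each by default. Smooth traces
are sums of random sinusoids below 0.5 Hz, shifted to start at zero motion
and rescaled to an exact per-axis peak — statistical stand-ins for replayed
human head-motion recordings, which are not publicly available; no
trace-by-trace comparison to any specific recording is claimed.

**Facial deformations.** Yawn, smile, frown and swallow are cosine-windowed
displacement bumps confined to their labeled regions (jaw, cheeks, brow,
larynx; default peaks 8/4/3/3 mm), with a sin(π·phase) temporal envelope.
The field is projected onto the zero-net-force / zero-net-torque subspace
using a correction that is itself windowed inside the region — this makes
the least-squares rigid fit of (original, deformed) exactly the identity
while keeping every moved point inside its region. The displacement
direction blends the mode direction with the local outward radial direction;
a windowed *constant* direction would lie entirely inside the projection
basis and vanish. A head shake is rigid motion, so the "shake-free" mode is
the zero deformation by definition.

## Evaluation

Tracking error = measured minus ground-truth motion, per axis, with the
truth (the denser signal) linearly interpolated onto the measurement
timestamps. Rotation errors are component-wise Euler differences — valid in
the ≤5 deg regime — with the geodesic rotation angle as a diagnostic
column. Summaries report per-axis mean, sample SD (n−1), quartiles
(linear interpolation) and whiskers at 1.5×IQR clipped to the data range;
the benchmark report applies 1 mm / 1 deg mean-absolute-error gates and can
split sessions into labeled segments (e.g. rigid vs deformation).

## Problem sizes

The acceptance script runs the benchmark at full scale: 848×480 cameras,
the 66-pose staircase with 5-frame dwell (330 frames) plus three 20 s
smooth traces at 5 fps (300 frames). The test suite runs the same protocols
at reduced camera resolution (½ to ¼) and shorter sessions — the package's
choice of test scale; projection geometry, noise behavior and registration
are identical, only the number of pixels and frames changes. The
deformation-sensitivity study uses ten seeded sessions of 8 s rigid + 8 s
deforming motion at quarter resolution.

## What the simulation does and does not show

Passing the simulated benchmark demonstrates the *algorithmic* accuracy of
the tracking chain under depth noise, self-occlusion, two-sensor fusion and
ROI propagation, against exact ground truth. It does not capture real
stereo-matching artifacts (textureless dropout patterns, flying pixels at
edges, sensor-temperature drift), camera synchronization, calibration decay
over time, skin specularity, or hair — so real-hardware accuracy can be
worse than the simulated figures, and the simulator's noise magnitude is a
model assumption, not a measurement.

## Known limitations

- Rigid-motion model only: deformation is simulated and measured, but the
  tracker does not compensate it (the robust loss merely downweights it).
- Euler-angle error reporting degrades near ±90 deg pitch — far outside
  the intended operating range.
- The rasterizer clips triangles crossing the near plane rather than
  splitting them; irrelevant at the ~450 mm working range.
- Voxel downsampling slightly overshoots the requested density on patch
  boundaries (partially covered voxels), bounded by the patch/voxel size
  ratio.
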