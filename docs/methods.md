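# Methods

## Model

The ligament is idealised as a linear elastic, isotropic, small-strain solid
composed of two phases plus bone anchors:

- **Fibre model.** A 3 (rows, Z) x 5 (columns, Y) lattice of square collagen
  prisms, each 20 x 20 um in cross-section and 300 um long (X, the tensile
  axis), separated by 20 um gaps in both Y and Z. Elastin blocks of
  12 x 12 um cross-section span the 20 um gaps between adjacent fibres,
  face-bonded to both ("complete fixation": displacement continuity, no
  sliding or debonding). Two bone blocks cap the +-X ends, bonded to every
  fibre end face.
- **Sheet model.** A single homogeneous prism, 62 um (Y) x 128 um (Z) x
  300 um (X), with the same bone caps, using homogenised ligament moduli.

Material constants (Young's modulus E, Poisson ratio nu):

| component      | E [Pa]   | nu   |
|----------------|----------|------|
| collagen       | 8.9e6    | 0.48 |
| elastin        | 4.0e6    | 0.48 |
| sheet ligament | 12.7e6   | 0.48 |
| bone           | 17.0e6   | 0.30 |

Elastin content is the volume fraction c = Ve / (Ve + Vc), bone excluded.
One block is 20 x 12 x 12 = 2880 um^3 against 1.8e6 um^3 of collagen, so the
sweep contents 0-33.5 % correspond to n = 0..315 blocks. `n_for_content`
inverts the (strictly increasing) content arithmetic; note that a uniform
35-block step does not reproduce every printed content label to one decimal
(21.8 % needs n = 174, 28.1 % needs n = 244), so the sweep selects the
closest block count per label.

### Elastin placement

The placement lattice has 15 equally spaced axial stations (pitch = 20 um,
matching the inter-fibre gap) and 22 adjacent-pair gap lines (12 Y-neighbour
pairs, 10 Z-neighbour pairs). Blocks are laid round-robin: all 22 gap lines
of one station (Y-pairs row-major, then Z-pairs), then the next station.
Blocks are centred on the fibre faces (4 um margins). This is one concrete
realisation of "equal intervals"; the content arithmetic is independent of
the pattern, and the capacity (330 blocks) comfortably covers the sweep.

### Geometric simplifications

Prisms are sharp-edged (no fillets), so an exactly conforming voxel mesh
exists and phase volumes are exact. Fillet radii would reduce volumes at
second order and smooth the corner stress concentrations; max-stress
statistics are therefore taken over element centroids (below), which bounds
the corner-singularity sensitivity. The printed sheet dimensions give a
2.38e6 um^3 ligament volume versus 2.10e6 um^3 for the sharp-corner fibre
model; the sheet dimensions are used as printed and the mismatch is not
reconciled.

## Discretisation

The geometry is voxelised on a regular grid: axis-aligned box-shaped
trilinear hexahedra with uniform per-axis spacing. Every prism boundary
falls on grid planes, so each element carries exactly one material and mesh
volume equals prism volume exactly. The fibre model uses cubic 4 um voxels
(64,800 elements at 33.5 % content, ~260k DOF). The sheet's 62 um width is
not divisible by 4, so the sheet uses (4, 3.875, 4) um spacing — the sole
reason elements are boxes rather than cubes. A refinement check on a
full-length two-fibre slice puts the h = 4 -> 2 um change of mean collagen
von Mises stress under shear at ~3 %.

Element stiffness uses full 2x2x2 Gauss quadrature (exact for a
constant-Jacobian box). No reduced integration or hourglass control is
used; at nu = 0.48 full integration mildly overestimates stiffness
(near-incompressible locking), which cancels in the ratios reported here.

## Solver

Dirichlet constraints are eliminated; the reduced SPD system is solved
directly (SuperLU) below 70k DOF. Larger systems use conjugate gradients
preconditioned by one geometric-multigrid V-cycle: node grids are halved in
index space, prolongation is trilinear interpolation built from integer
node indices (holes in the voxel lattice need no special casing), coarse
operators are Galerkin products P^T A P, smoothing is degree-3
Chebyshev-Jacobi, and the coarsest level (< 24k DOF) is factorized.
Because these slender, near-incompressible systems let CG stagnate near its
attainable-accuracy floor, the solve is wrapped in iterative refinement on
the true residual; the accepted relative residual is at most 1e-9
(typically 1e-10). A full fibre-model solve takes tens of seconds to about
two minutes on one CPU within ~2.5 GB (the elastin-free lattice, whose
fibres couple only through the bones, conditions worst); the full
ten-content sweep with slopes is an hour-plus batch job
(`analysis/03_content_sweep.py`), so the acceptance run and the test suite
restrict themselves to the contents the headline comparisons need.

## Load protocols

All protocols clamp every node of one bone ("fixed bone").

- **Tensile / shear:** uniform traction on the free bone's outer X face
  (area = full cross-sectional footprint), 0.15 Pa along +X or 0.90e-3 Pa
  along +Y, applied as consistent (quarter-split) nodal forces. The global
  strain is the face-averaged displacement component divided by the 300 um
  ligament length. The stress-strain slope is the origin-constrained
  least-squares fit over load scalings; by linearity it equals traction /
  strain at any single load, which the pipeline verifies.
- **Rotation:** the outer face of the free bone is given the linearized
  rigid rotation u = theta (0, -(z - z_c), (y - y_c)) about the X axis
  through the face centroid, theta = 30 degrees. Imposing the rotation as a
  prescribed displacement and reading reactions replaces the original
  apply-stress-until-it-rotates procedure; under linearity the two are
  equivalent up to normalization and need no outer root-finding loop.
  Linearized (rather than finite) rotation keeps the response exactly
  proportional to theta, which is asserted in tests.

### "Stress required to rotate"

The reactions on the rotated face form (to numerical precision) a pure
couple: their net force vanishes by symmetry, so a net-force-over-area
definition would be noise. The reaction torque about X is instead split
into the part carried by Y-forces, T_Y = sum -(z - z_c) F_y, and by
Z-forces, T_Z = sum (y - y_c) F_z, and each is expressed as the uniform
antisymmetric half-face traction pair carrying the same torque:

    sigma_Y = |T_Y| / (A Lz / 4),    sigma_Z = |T_Z| / (A Ly / 4),

with A the face area and Ly, Lz its side lengths. Both are strictly
positive, exactly linear in theta, and strictly increasing in elastin
content. The loaded-surface definition and normalization behind previously
published "stress required" values
are not recoverable, so absolute MPa values carry a geometry-dependent
factor; content trends and sheet/fibre ratios do not depend on it.

## Post-processing

Stress is evaluated once per element at the parent-space centre (the
trilinear element's optimal stress point) and never extrapolated to nodes;
von Mises is the standard second deviatoric invariant. Component summaries
take mean/max von Mises over the component's element centroids and mean/max
displacement magnitude over the component's nodes ("displacement of
collagen" = mean magnitude over collagen nodes — there is no single
standard definition, so this convention is fixed here).
Max-stress localization classifies whether the argmax element shares a face
or edge with a different material. All comparisons between models use each
model's own fixed mesh.

## Synthetic two-channel images

The image module emulates co-registered single-label channels: SHG
(collagen) and autofluorescence (elastin). A Gaussian-smoothed random field
thresholded at a quantile gives a fibrous foreground (default 30 % of
pixels, correlation length `blob_scale` = 8 px); a second smoothed field
partitions the foreground so the elastin pixel share equals the requested
fraction to within one pixel; each pixel emits in exactly one channel, plus
optional additive Gaussian noise clipped at zero. What this does *not*
emulate: channel bleed-through, depth-dependent attenuation, anisotropic
fibre texture, and partial-volume pixels. Estimator tests on these images
therefore validate the counting rule and its noise sensitivity, not
microscope physics. The estimator binarizes each channel at a fixed
threshold; fixed thresholds with a brighter-channel rule for
double-positive pixels and ties to collagen are the simplest rule
consistent with plain pixel counting. A published pixel-count content such
as the 16.4 % porcine value is therefore reproducible only as arithmetic,
not from raw data.

## Problem sizes used by the shipped runs

The unit suite exercises reduced lattices (2 x 2 fibres, 100 um length,
8 um bones; small sheet) chosen so every structural feature of the default
study is present while the suite solves with the direct factorization. The
acceptance run and the analysis scripts use the full default geometry
(h = 4 um; ~260k DOF per fibre solve). The refinement check runs on a
full-length two-fibre slice (~160k DOF at h = 2 um), the largest geometry
that keeps a desk-scale h = 2 um solve.

## Known limitations

- Linear elasticity only: no viscoelasticity, anisotropy, contact, or
  geometric nonlinearity; collagen waviness (toe region) is not modelled,
  so absolute strains at physiological loads are not meaningful — ratios
  and trends are the outputs.
- The 30-degree rotation is linearized; at finite rotation the required
  torque would differ by O(theta^2) geometric terms.
- Sharp corners make pointwise maxima mesh-dependent; centroid statistics
  at a fixed h are reported instead of converged point values.
- The elastin bridges stiffen the lattice geometrically as well as
  materially: replacing the elastin modulus by collagen's does *not* make
  the sweep content-independent (shear strain still changes severalfold
  over the sweep). Content sweeps therefore measure the combined
  geometry + material effect; the
  collagen-material control quantifies how much softer real elastin makes
  the structure at equal bridge count.
- Absolute rotation-stress MPa values depend on the unstated loaded-surface
  normalization (above) and on the bone cap thickness (40 um here, a free
  parameter of the model).
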