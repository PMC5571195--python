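# Methods

This note documents the models implemented in `blastovol`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Coordinate and sampling conventions

All grids are `(z, y, x)` with physical spacing `(L_z, L_y, L_x)` =
`(√2, 0.16, 0.16)` µm by default — the strongly anisotropic sampling of a
light-sheet acquisition of an early *C. elegans* embryo (50 optical
sections per stack, one stack every 30 s).  Physical coordinates refer to
voxel centres at 0-based indices: voxel `(i, j, k)` sits at
`(i·L_z, j·L_y, k·L_x)` µm.  All geometry (centres, normals, displacements)
is computed in µm.

## Synthetic embryos

The generator provides ground truth for every downstream stage:

* **Geometry.**  Blastomeres are spheres, optionally confined by an
  ellipsoidal eggshell of semi-axes 27 × 15 × 15 µm (a typical egg).
  Spheres are the simplest geometry consistent with the spherical-cap
  division model; overlaps beyond a 0.05 µm tolerance are rejected.
* **Membrane channel.**  Each cell paints a bright shell (default
  intensity 180) over the radial band `(R − t, R]` with `t` = 0.4 µm and a
  dimmer cytoplasm (60) inside.  Rendering the shell *inside* the true
  radius means a segmenter that claims up to the membrane ridge recovers
  the true sphere volume — the natural convention for scoring volumetry.
* **Chromatin channel.**  One Gaussian blob (σ = 0.5 µm, amplitude 200)
  per cell at the nucleus/metaphase-plate position, a stand-in for a
  histone stain used only to position tracks.
* **Noise.**  Additive Gaussian camera noise (σ = 5 by default) clipped at
  zero; an optional multiplicative shadowing attenuation accumulating
  along the illumination axis is off by default.
* **Lineage fixture.**  The pre-gastrulation division table covers 27
  divisions (AB through AB16, P₀–P₃, EMS, MS lineage, E, C lineage); the
  default uses the first 25 in rough division-time order (26-cell stage),
  the count being configurable.  Ten mothers divide asymmetrically with
  ground-truth volume ratios P₀ 1.4, P₁ 1.7, P₂ 1.5, P₃ 2.0, EMS 1.15,
  MSa 1.4, MSp 1.3, Ca 1.4, Cp 1.3 and ABar 1.12 — values chosen once as
  plausible for these cells and verified analytically to exceed the
  volume-dependent uncertainty band at the default spacing (ABar only
  marginally, reflecting its borderline status).  All other divisions are
  symmetric.  Volumes cascade from a 25 000 µm³ zygote under exact
  conservation.
* **Displacement samples.**  Somatic spindle displacements are drawn from
  Normal(−0.1, 0.56²) µm and germline displacements from
  Normal(1.36, 0.2²) µm.  The 0.2 µm germline spread is a package choice
  (only a median is reported for real germline cells); it keeps the
  somatic/germline separation detectable by a two-sample KS test at small
  n.
* **Placement.**  Cells in measurement studies receive a seeded sub-voxel
  centre jitter so that voxel-grid alignment is decorrelated from cell
  size — real cells sit at arbitrary positions on the grid.

What the synthetic data deliberately do **not** emulate: optics (PSF,
depth-dependent blur), cell-shape deformation at contacts, motion between
optical sections, and intensity heterogeneity of real membranes.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
geometry and noise, not performance on real stacks.

## Segmentation

Seeded region growing on the membrane channel:

1. 5 × 5 × 1 (x, y, z) box mean filter; global threshold sets background
   to exactly zero.  The default threshold is Otsu's on the filtered stack
   — robust when the embryo occupies a reasonable fraction of the field of
   view, but it can overshoot the cytoplasm level when the foreground is a
   small fraction of the stack; the threshold is therefore always
   overridable.
2. One seed voxel per cell grows simultaneously and iteratively.  Each
   region's boundary is the region minus its erosion with the full 3×3×3
   neighbourhood (26-connectivity).  Per boundary voxel, one outside
   neighbour among its 26 is chosen uniformly at random; it joins the
   region iff its filtered intensity satisfies F_out ≥ q·F_boundary
   (default q = 0.98) and no region claims it yet.  Regions are updated
   sequentially in label order within an iteration; first claim wins and
   voxels are never re-assigned, so regions are monotone and pairwise
   disjoint by construction.  Intensities are read from the *filtered*
   image, consistent with the stated preprocessing order.
3. N = round(300/log₁₀(n+1)) iterations run on an in-plane 2× downscaled
   copy (z is already coarse), labels are upscaled nearest-neighbour, and
   40 further iterations refine at full resolution.  Base-10 logarithm:
   it yields N = 300 at the 9-cell stage, commensurate with the fixed 40
   refinement iterations, where a natural log would not.
4. Cleanup: per-label binary opening then closing with a 15 × 15 × 3
   (x, y, z) box kernel — implemented with separable min/max filters,
   exactly equivalent to binary morphology with a box structuring element
   — followed by a largest-connected-component sweep.  Closed regions
   never claim zeroed background or other labels.

**Known limitation.**  At the √2 µm section spacing the 15 × 15 × 3
opening homogenises consecutive z-layer discs, clipping the equatorial
bulge of small cells: ~30% volume loss at R = 3 µm, ~2% at R = 5 µm, <1%
for R ≥ 9 µm.  Volumetry accuracy claims hold for cells of R ≳ 5 µm,
which covers the pre-gastrulation stages analysed.

The time-series wrapper derives per-stack RNG seeds from a base seed,
computes per-cell median volumes and flags any division whose daughter
volume sum deviates from the mother volume by more than 3% (automated
stand-in for manual stack-by-stack quality control).

## Volumetry and significance

Cell volume is the voxel count times the voxel volume.  Volume ratios:
anterior/posterior daughter for somatic divisions, somatic daughter over
the new germline cell for germline divisions.  The uncertainty band models
the dominant segmentation error — whether or not one extra voxel layer is
included around a cell of radius R = (3V/4π)^⅓: a lateral surface shell of
thickness L_x over the zone between top and bottom sections
(ΔV₁ = 4πR²L_x − 2πRL_zL_x) plus two half-height caps in the extreme
sections (ΔV₂ = πL_z(RL_z − L_z²/6)/2; exactly two spherical caps of
height L_z/2).  Since inclusion is a coin flip, ΔV = (ΔV₁ + ΔV₂)/2, and a
symmetric division with daughter volume V_sym can masquerade as
VR_max = (V_sym + ΔV)/(V_sym − ΔV).  Conventions:

* V_sym = V_mother/2 — the band is a null model of symmetric division.
* Strict exceedance: VR exactly on a bound is *not* significant.
* For R ≤ L_z/2 the layer decomposition is invalid (ΔV₁ < 0); such cells
  are flagged unassessable and excluded from the asymmetric fraction's
  numerator and denominator.
* ΔV₁ is a first-order (thin-shell) approximation; the exact lateral
  voxel-shell volume differs by ~15% at this anisotropy.  The package
  implements the closed forms as stated and tests ΔV₂ against exact
  quadrature and ΔV₁ against the exact shell within a 20% band.

## Spherical-cap model and shift fit

A mother of radius R₀ whose cleavage plane sits Δx off-centre splits into
caps V₁ = π/3·(R₀+Δx)²·(2R₀−Δx) and V₂ = π/3·(R₀−Δx)²·(2R₀+Δx) (exact
conservation; VR strictly increasing in Δx).  Assuming each new germline
cell is spherical again, a single constant Δx predicts EMS, P₂, C, P₃, D
and P₄ from the volume of P₁ alone.  `ConstantShiftModel.fit` minimises
the mean absolute relative deviation over the six predicted cells on a
grid (default 0–3 µm, 0.01 µm steps; grid search for exact
reproducibility; all six cells used when available).  The package default
shift is 1.75 µm.  The ellipsoid variant maps the ellipsoid to the unit
sphere affinely, so its cap volumes are scaled sphere caps.

## Plate geometry

* **Cortical centre.**  ~3000 surface voxels, thinned by farthest-point
  sampling in physical coordinates from a randomly permuted boundary pool
  (random order matters: argmax tie-breaking on a lexicographically
  ordered pool biases the sample once the point set saturates).  The
  centre iterates c ← c + ε·f with f the *mean* unit vector from c toward
  the points and ε = 0.05 µm, stopping when the step is below tol =
  0.01 µm (at most 10⁵ iterations).  The attracting sign is used so the
  sphere centre is a fixed point; the equilibrium is the geometric median
  of the surface sample, which coincides with the surface centroid for
  centrally symmetric cells and deviates for asymmetric ones.  Normalising
  f bounds the step by ε; for strongly asymmetric objects a smaller
  tol/ε ratio sharpens convergence to the median.
* **Division normal.**  d = normalize(mean over stacks of
  normalize(r₂ − r₁)) from daughter-chromatin positions in the stacks
  following the last unambiguous metaphase.  Track roles: daughter 1 is
  the anterior/somatic (larger) daughter, daughter 2 the posterior/new
  germline (smaller) daughter.
* **Displacement sign.**  Δx = d·(c − r₀) with d oriented toward the
  *larger* daughter, so positive displacements mean the plate shifted
  toward the smaller daughter — germline displacements come out positive
  (≈ +1.36 µm on synthetic cells rendered at that offset).
* **Voxel split.**  Every voxel of a cell joins the side of the plane
  through r₀ (optionally shifted along d by an extra 0.45 µm to account
  for 15 s of unmonitored spindle travel at 30 nm/s) given by the sign of
  d·(v − r₀ − d·extra); this is exactly the nearest-of-two-anchors rule
  with a vanishing anchor separation.  Hard voxel classification
  quantises the effective plane position to the grid (bias ≤ L_x/2, up to
  ~2.5% on the volume ratio at R = 10 µm); agreement with the analytic
  caps is therefore assessed as the average over sub-voxel placements of
  the sphere, which estimates the discretisation-free agreement (≈0.4%
  observed).
* **Statistics.**  Somatic displacements: mean, SD, median and
  Jarque–Bera normality p; somatic vs germline: two-sample
  Kolmogorov–Smirnov; optionally the Pearson correlation between somatic
  displacements and their division's volume ratio.  Groups smaller than 3
  skip the tests with explicit flags.

## Spindle mechanics

Constant forces F_A < F_P pull the anterior/posterior spindle poles;
the spindle is a Hookean element (k, rest length L₀) and motion is
overdamped (friction γ; no inertia, no mass parameter anywhere).  Closed
forms: x_MP(t) = (F_P−F_A)t/(2γ), s(t) = (F_P+F_A)/(2k)·(1−e^(−2kt/γ)).
Rupture at s_max gives T = −γ/(2k)·ln(1 − 2k·s_max/(F_P+F_A)) and final
displacement Δx = (F_P−F_A)T/(2γ) — no cell-size dependence, which is the
model's point.  If s_max ≥ (F_P+F_A)/(2k) (equality included: the
asymptote is reached only at infinite time) the model raises a stall
error, mirroring arrest in late metaphase under insufficient force.  L₀
never enters the displacement formulas and is retained only to report the
absolute length L₀ + s(t).  No physical parameter magnitudes are asserted;
defaults are illustrative and results depend only on the dimensionless
combinations (force ratio, k·t/γ, 2k·s_max/(F_P+F_A)).

## Pipeline

`RunConfig` serialises to YAML and round-trips bit-exactly; a single
global seed expands deterministically into per-stage seeds.  Each stage
writes its artifact (CSV/JSON) plus a SHA-256 checksum into the report;
reruns under an unchanged config digest reuse existing artifacts and
reproduce identical checksums, making runs resumable and auditable.
Mis-configured stages (e.g. classification without a division source)
fail with stage-tagged errors before any work is done.

## Problem sizes used in tests and the acceptance script

Rendering and segmenting full-scale embryos for every check would be
wasteful; the packaged studies use compact but non-trivial geometries: a
9 µm mother dividing into 7.9/6.4 µm daughters for volume-conservation
checks (noiseless and default noise), ten germline cells of radii 4–12 µm
for displacement recovery, 10⁴–10⁵ draws for distribution parameters, and
301-point shift grids.  These sizes keep every quantity's estimator well
inside its tolerance; all of them are parameters, not constants.
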