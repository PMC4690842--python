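# Methods

`bresym` registers a prone and a supine breast image by driving both of them,
with an explicit finite-difference hyperelastic simulation, towards a common
*virtually unloaded* configuration — the hypothetical stress-free geometry
with gravity removed. Gravity is treated as the dominant cause of the
prone/supine shape difference; what gravity cannot explain is corrected first
globally (tissue stiffness) and then locally (image-derived forces fed
straight into the simulation). This note records the model, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Deformation model

Tissue is a compressible neo-Hookean solid. The momentum balance with
speed-proportional damping,

    rho_0 u_tt = Div N + rho_0 f - r u_t,

is integrated explicitly in time directly on the image grid (no meshing).
The nominal stress (transposed first Piola–Kirchhoff) is

    N = ( mu (I - C^-1) + lambda ln J · C^-1 ) F^T,

with `F = I + du/dX`, `C = F^T F`, `J = det F`; the implementation evaluates
the algebraically identical `P = mu (F - F^-T) + lambda ln J F^-T`, `N = P^T`,
and the test suite checks it against a numeric gradient of the strain energy.
Space is discretised with central differences (the mixed second derivatives
with the standard 4-point stencil); time with

    U^{n+1} = ((2 rho + h_t r) U^n - rho U^{n-1} + h_t^2 rho K^n) / (rho + h_t r),

`K = (Div N)/rho_0 + f`. Displacements start at zero with homogeneous
Dirichlet conditions on the (padded) image boundary. Accuracy: the spatial
operators are second order; the damping term uses a forward difference, so
trajectories of damped motion are first-order accurate in `h_t` — irrelevant
for the quasi-static states the method extracts, and verified against the
analytic damped oscillator in the tests.

A fused numba kernel reproduces the numpy reference path bit-for-bit (tested)
and carries the hot loop.

### Stability

The time step obeys a CFL-type bound `h_t = safety · min(h) / c_d` with the
dilatational wave speed combined from the *stiffest* node and the *lightest*
node, `c_d = sqrt(max(lambda + 2 mu) / min(rho))`: at a material interface the
stress of the stiff side accelerates nodes of the light side. Compressed
neo-Hookean tissue stiffens like `1/J^2`, so the step is additionally scaled
by the current minimum tissue `J` (clipped to [0.15, 1]) and a block is rolled
back and retried with a halved step if an element inverts. Default safety
factor 0.5.

Two further robustness devices (transient-only; they do not alter the
quasi-static solutions):

* a per-node speed cap (default 0.05 m/s): very soft tissue under full
  gravity would otherwise fall near-ballistically and fold before the
  configuration updates can contract it — standard dynamic-relaxation
  practice;
* a damping sponge (x20) in the outermost three node layers, where weakly
  coupled short-wavelength modes of the collocated stencil otherwise ring.

### Material fields

* Tissue (fat and gland share one global modulus): shear modulus `mu` in Pa,
  `lambda` from a fixed Poisson ratio 0.49 (near-incompressible),
  `rho = 1000 kg/m^3`.
* Chest: same modulus as tissue; its nodes are either prescribed fixed or
  constrained to the chest surface, so stiffening it would only shrink the
  stable time step.
* Background ("air"): `mu/10`, Poisson 0.3, `rho/10`, zero body force, and a
  small-strain linear-elastic law instead of the neo-Hookean one. The
  background only exists so the skin can move freely inside the grid; the
  linear law cannot invert, which keeps heavily compressed background regions
  (ahead of the advancing skin) numerically regular while its stress stays
  ~1% of the gravity-driven tissue stress.
* Damping: `r = 2 rho c_s / t_char`, with `c_s = sqrt(mu/rho)` the tissue
  shear wave speed and `t_char` the mean tissue thickness along gravity
  (tissue volume / projected footprint) — a near-critical estimate for the
  slowest structural mode of the chest-clamped breast, chosen for settling
  speed, not as a physical claim.

## Gravity unloading (prediction–correction)

The stress-free geometry is unknown; only the gravity-loaded one is imaged.
One forward loading simulation is run from the current estimate of the
unloaded configuration, and at regular intervals the *loaded* material
configuration `M = {lambda, mu, rho, f}` is pulled back through the current
displacement field, `M_{m+1}(X) = M_0(X + U(X))`. Because the simulation's
displacement is the forward map (estimate → loaded), this update is plain
image resampling — the backward-Lagrangian convention supplies the inverse
mapping for free, and no iterative field inversion is ever performed. At the
fixed point the grid holds the unloaded configuration and `U` is the pullback
DVF (loaded-from-unloaded sampling map) that warps the loaded image into the
central frame.

Details that matter:

* Resampling interval: every 50 steps, or earlier if the field moved more
  than 0.25 cells since the last update. Material fields are interpolated
  linearly, labels nearest-neighbour.
* The gravity part of the body force is rebuilt from the resampled labels
  rather than interpolated as a field: a linear blend would put weight on
  near-skin background nodes (light but loaded → they never stop falling).
* Gravity is ramped linearly over the first 10% of the step budget.
* Termination alternates: resample until the mean configuration update falls
  below 0.1 mm (or plateaus), then *freeze* the configuration and settle to
  the quasi-static criterion (max nodal speed < 1e-4 m/s), then verify with
  one more resample. The label churn of continuous resampling otherwise
  sustains a small limit cycle at tissue interfaces. A settle that drifts
  more than one grid cell aborts back to resampling (the bulk was still
  moving, e.g. under a much too soft interim material).

## Chest-surface motion constraint

The chest–breast interface band is extracted from the segmentation, and the
Euclidean distance transform of that band yields a correction field `c(X)`
(the exact nearest-surface vector at voxel resolution). Interface ("slave")
nodes whose deformed position leaves the one-voxel surface band are displaced
by `s(v_s) · c(x)` each step; elastic forces regularise the tangential motion,
so the nodes slide along the chest. The scale

    s(v_s) = p / (1 + exp(l (v_s - v_max)))

rolls the correction off for nodes already moving towards the surface faster
than `v_max` (repeated corrections would otherwise pump the explicit scheme).
Constants: `p = 0.005`, `v_max = 0.05 m/s` — the system is insensitive to `p`
precisely because of the speed roll-off. The steepness `l` is a free
parameter; the default `l = 10 / v_max` gives `s(0) ≈ p` with a sharp
roll-off near the limit. `v_s` is positive towards the surface; corrections
are capped at one grid cell per step. Modes: `tied` corrects from both sides,
`sliding` only corrects nodes that left the chest side; in both modes the
chest *interior* (not breast tissue) stays prescribed fixed, and a fully
`fixed` chest is available — the phantom experiment uses it, matching its
ground-truth simulations.

## Material optimisation

Reported breast-tissue stiffness varies widely, so the registration starts
from an extremal global modulus and multiplies/divides `mu` and `lambda` by a
constant factor, re-unloading both sides and evaluating the central-frame SSD
after each step. Only improving steps are accepted; the first non-improving
step is discarded. Default: start at the generic 357.1 Pa and *soften* by
1.2 per step. Softening from stiff means every softer state is reached by a
warm start from the previous equilibrium — a cold start with very soft tissue
(~100 Pa) folds at the coarse grid, which is why the stiff-to-soft direction
is the default even though the search supports both.

## Image-derived forces

Both loaded images are warped into the current central configuration on a
fine force grid and compared with the SSD; its variational derivative gives
one force field per side, `f_P = -(P - S) grad P`, `f_S = -(S - P) grad S`
(masked voxels contribute nothing — marker-clip protocol). Forces are block-
averaged onto the simulation grid (conserving total force), transported by
the side's deformation gradient, ramped in by a piecewise-linear loading
function `s(t)` over one resampling interval, and accumulated in the *loaded*
configuration, from which they are pulled back with every configuration
update like every other field. Recording in the loaded frame uses a
fixed-point inversion of the current DVF (the one deliberate inversion in the
pipeline; 10 sweeps, 0.05 mm tolerance).

The relative weight of image and gravitational forces is a free parameter of
the formulation. It is calibrated once per run so the initial image-force
95th percentile is 10% of gravity; intensities are normalised to [0, 1]
inside the body mask first so the weight transfers across cases. Each force
update runs one resampling block; if the SSD rises, both sides are rolled
back to the best checkpoint and the weight is halved (after four such
rollbacks the level stops). A level also stops when the relative SSD
improvement per cycle falls below 2e-4 — a deliberately tight threshold,
since the landmark error keeps improving slightly after the visually obvious
SSD descent has flattened. Defaults: phantom runs one force level at
9.07/4 = 2.27 mm under a 9.07 mm simulation grid; clinical-style runs would
use an 8 mm simulation grid with 4, 2, 1 mm force levels.

## The numerical phantom

The synthetic-data generator defines the study conditions. The unloaded
geometry is analytic: a cylinder of radius 80.2 mm along the cranio-caudal
axis is the chest wall; the skin is the anterior cylinder elevation plus a
2-D Gaussian. Amplitude (77.6 mm) and the posterior cut plane (20 mm above
the axis) fix the printed AP extent of 137.8 mm; the Gaussian width
(58.23 mm) solves enclosed breast volume = 1.14 L; LR/SI extents are 160.4
and 159.5 mm by construction. The cut height is not determined by the
printed extents: a through-axis cut produces a wide flat mound whose supine
loading slides flank tissue so strongly along the chest that the
correspondence is not invertible at grid resolution — no evaluation could
distinguish registration error from that pathology — so the calibrated
default is the pendulous variant, whose ground-truth fields invert to
< 0.2 mm everywhere.

Ground truth is produced by the same solver family (deliberately: the
external mesh-based engine the original experiment used is replaced by a
forward gravity loading run at a grid twice finer than the registration
simulation, with a prescribed zero-displacement chest and fixed cut planes).
The raw finite-difference solution carries a one-cell shear layer against the
clamped chest that a mesh-based engine would not resolve either; the
generator therefore smooths the converged field with a 4.5 mm Gaussian
(`gt_smoothing_mm`) *before* anything is derived from it — images and
landmark correspondences come from the same smoothed field, so the study is
exactly self-consistent and its ground truth is representable on the
registration grid (resampling the exact field to 9.07 mm and evaluating the
500 landmarks gives 0.36 mm mean / 2.8 mm max, the experiment's
representational floor). The homogeneous tissue modulus, 230 Pa, is
calibrated once so that the 500 uniformly sampled tissue landmarks lie
~19 mm apart between the prone and supine loaded states (observed: 18.6 mm
mean). A seeded band-passed noise texture (bright chest, zero background,
sharp skin edge) stands in for an MR texture; loaded images are synthesised
by inverting the ground-truth forward fields on the image grid (2.2675 mm)
and resampling.

What the phantom does *not* emulate: multi-modal intensity relationships
(MRI vs CT — handled in the package by pseudo-CT intensity inversion, which
the phantom never exercises end-to-end), segmentation errors, coil/imaging
contact deformation, bias fields, heterogeneous fat/gland mechanics, and
observer noise in landmark placement. Passing the phantom experiment
demonstrates the mechanics, the unloading loop, the optimisation and the
force coupling — not clinical accuracy.

## Evaluation

Landmarks picked in the loaded images are mapped into the central frame by
solving `X + D(X) = p` per point (fixed point, ≤ 20 sweeps, 0.01 mm); the TRE
is the Euclidean distance between corresponding prone- and supine-derived
central positions. An inter-observer exclusion rule (threshold 10 mm)
mirrors the clinical evaluation protocol and is provided as a library
function.

Known limitations:

* The collocated central-difference discretisation overestimates compliance
  near incompressibility (checked at Poisson 0.3 against the confined-column
  closed form; at 0.49 the bias is larger at coarse grids).
* The worst-case landmark error of the phantom experiment (~11-12 mm over
  500 landmarks, against a mean of ~1.4 mm and a 99th percentile of ~5 mm)
  sits where tissue meets the fixed cut planes and the steep chest flank: the
  ground truth clamps those planes exactly while the registration pads the
  domain and discretises the fixed chest at 9.07 mm, so the two boundary
  conditions are not equivalent — the same mechanism that produces the
  border maximum in this experiment class, amplified here by the landmark
  density near the planes. It is insensitive to the force weight, the
  padding width and the update schedule. The problem sizes used (domain
  ~160 mm, grids 9.07/4.535/2.2675 mm, 500 landmarks) were chosen so the
  full experiment runs on a single CPU in a few minutes.
* Checkpointing is in-memory snapshot/restore of the simulation state (used
  by the monotone-acceptance rollback); on-disk resume is not implemented.
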