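# Methods

This note documents the models, numerical choices and design decisions
behind `protonlet`, and states what the synthetic studies do and do not
show.

## Beam model

All transport is parametric; there is no Monte Carlo or CT-based
heterogeneity.  The phantom is homogeneous water, so water-equivalent
depth equals geometric depth from the phantom surface along each beam
axis.

**Depth dose.**  A spot of range R (mm) deposits the Bragg–Kleeman
power law `D(z) ∝ (R − z)^(1/p − 1)` with p = 1.77, convolved with a
Gaussian range-straggling kernel of width

    σ_straggle(R) = 0.12 · (R / 100 mm)^0.935 · 10 mm

(≈1.2% of range, mildly sublinear), normalised so the peak of the
convolved curve is 1 per unit spot weight, and set to exactly zero
beyond `R + 4σ`.  The integrable singularity at `z = R` is handled by
integrating the power law analytically over convolution cells of width
σ/4 and placing each cell's mass at the analytic centroid of the
power-law weight; against adaptive quadrature of the same integral
this is accurate to ~0.1% through the peak region.  The curve for each
distinct (R, p, σ) is cached on a fine grid and interpolated linearly.
The model has no nuclear buildup or halo, so its entrance-to-peak
ratio (~0.08 at R = 150 mm) is lower than clinical beams; this affects
absolute entrance doses, not the distal-edge phenomena the package
studies.

**LET depth curve.**  The unrestricted LET of a spot is

    L(z) = L0 + a · ((R − z + s) / 10 mm)^(−b),  clipped to [L0, Lmax]

with defaults L0 = 0.3, a = 2.3, s = 2 mm, b = 0.45, Lmax = 15 keV/µm:
a flat entrance plateau near 0.3–1 keV/µm rising monotonically to ~5
keV/µm at end of range and clipping at 15 in the distal falloff.  The
constants were chosen once so that the curve spans the clinically
debated range and caps of 2.0–4.0 keV/µm are binding; the constructor
rejects parameter sets that would be non-monotone on [0, R].

**Lateral spread.**  Gaussian with σ_lat(z) = σ0 + k·z, σ0 = 4 mm,
k = 0.02 — a linear stand-in for multiple Coulomb scattering plus spot
size.  A spot's dose is the depth-dose times the lateral Gaussian
factor; entries below 10⁻³ of the spot's maximum are dropped, and the
LET map shares the dose map's sparsity pattern.

**Spots and energy layers.**  Energy layers cover the target's depth
extent per beam with spacing `max(scale · 0.8·σ_straggle(mid-range),
0.5 mm)`; static PBS uses scale 1, arc plans scale 0.25 (denser
layers).  The 0.5 mm floor — a quarter of the 2 mm grid resolution —
avoids layers that are numerically indistinguishable on the dose grid.
Lateral spot pitch is 0.7·σ_lat at mid-depth for PBS (automatic mode)
and a constant 6 mm for arcs, each with one pitch of lateral margin.

**Arcs.**  Dynamic arcs are emulated as densely discretized static
beams (default 5° steps over a 130° span starting at 30°); bilateral
arrangements append the mirror arc with a 180° couch kick (gantry
angle negated).  What this preserves is the arc property of interest —
many beam directions sharing distal edges — not delivery dynamics.

## Plan-level quantities

Dose is the exact linear accumulation of per-spot dose times
nonnegative spot weight.  Dose-averaged LET pools all beams:

    LET_d(v) = Σᵢ wᵢ dᵢ(v) Lᵢ(v) / Σᵢ wᵢ dᵢ(v),

reported as 0 wherever the accumulated dose is below a floor (default
10⁻⁴ Gy) so that high-LET voxels with negligible dose do not read as
hotspots.  LET_d is invariant under global weight rescaling and lies
within the envelope of contributing spot LETs; both properties are
asserted in the test suite.  Averaging is in water (the phantom
medium), for the pooled plan.

## RBE models

Two published models are implemented exactly as stated in the README,
plus the constant-1.1 reference.  Numerical details:

* McNamara is evaluated at the per-fraction dose `D_p = total dose /
  n_fractions` (uniform fractionation; 33 or 35 fractions, 2.0/1.8/1.6
  Gy per fraction by target tier).  Below D_p = 10⁻⁶ Gy the analytic
  D_p → 0 limit (RBE_max) is returned to avoid the 0/0 form; at
  D_p = 10⁶ Gy the implementation matches RBE_min to better than 10⁻⁴
  relative.
* The published coefficient table is sometimes rendered with the α/β
  dependence typographically flattened; this package uses the original
  functional forms (`LET_d/(α/β)` in RBE_max, `√(α/β)·LET_d` in
  RBE_min).  Both readings coincide at α/β = 1 Gy, which is where the
  slope checks are performed.
* RBE_min turns negative for extreme LET·√(α/β); it is floored
  (default 0) with a warning, since negative RBE is unphysical.
* Tissue assignment: targets α/β = 10 Gy, nervous OARs 2.5 Gy,
  unlabelled tissue 2.5 Gy (conservative late-responding default);
  where target and OAR overlap the OAR value wins.

The RBE enhancement of a structure is `max(model dose) / max(1.1
dose)` over the structure mask, with the two maxima taken
independently (they may sit at different voxels) — a ratio of maxima,
not a maximum of ratios — using total-course doses.  The plain
voxelwise maximum is used (no small-volume surrogate); a percentile
alternative exists for sensitivity checks.

## Optimizer

Inverse planning minimises a sum of per-structure quadratic penalties
(uniform / max-dose / min-dose), each normalised by structure voxel
count, over nonnegative spot weights, by projected gradient with
Armijo backtracking on the projected-step quadratic model.  The start
is deterministic (uniform weights scaled to the mean target
prescription), so solutions are bit-reproducible.

The LET objective realises "cap LET_d above a dose threshold": in an
outer loop of fixed length (default 5 — LET_d is ratio-dependent and
not monotone under reweighting, so a convergence test on it would be
fragile), voxels of each LET-objective structure with dose at or above
`threshold_fraction × desired_max_dose` are flagged (the
clinical-goal reading of the threshold: 0.8 × 60 Gy = 48 Gy by
default; the sentinel `"global"` flags everything above the dose
floor), and the convex surrogate

    Σ_flagged max(0, Σᵢ wᵢ dᵢ(v)(Lᵢ(v) − cap))²  =  Σ_flagged max(0, d(v)·(LET_d(v) − cap))²

is added before re-solving.  Below-cap contributions offset above-cap
ones inside the hinge, so the optimizer can trade high-LET for
low-LET coverage routes rather than only cutting dose.  If the cap is
at or above every spot LET entry in the flagged region the penalty is
provably zero for all nonnegative weights and the warm-start solution
is returned unchanged.  If no voxel is flagged on the first pass, a
warning is issued and the dose-only solution returned.

**LET objective weight.**  Default 3.0 (per structure, voxel-count
normalised).  Calibrated once during method development: at 1 the
2.5 keV/µm cap barely moves LET_d on the canonical cases; at 10 the
unilateral case loses more than 5% of target V95.  At 3 the flagged
maximum LET_d drops visibly (unilateral: 3.73 → 2.73 keV/µm) with
coverage inside the 5% bound for both canonical geometries.

A hook (`optimize_dose(..., w0=...)` with externally shifted influence
data) allows evaluating a solved plan under perturbed geometry, but no
scenario-based robust optimization is performed.

## The canonical synthetic study

Two seeded case geometries on a 60 × 60 × 1 grid of 2 mm voxels (a
degenerate axial slab; all gantry rotation is in-plane) carry the
qualitative analyses:

* **Bilateral** (three static beams: anterior–posterior plus two
  posterior obliques at gantry 0/150/210; two mirrored 130° arcs): a
  20 mm, 66 Gy/33 fx target with the brainstem analogue
  posterior-midline, 2 mm beyond the target along the AP beam axis,
  and the optic-nerve analogue 14 mm anterior in the entrance region.
  The AP beam's distal edge abuts the OAR; the obliques reach the same
  target voxels through low-LET entrance paths, giving the LET
  optimizer a genuine trade.  This case carries the delivery-mode
  comparisons: enhancement(LET-opt PBS) ≤ enhancement(PBS) ≤
  enhancement(arc) for the distal OAR under both models, and entrance
  OAR < distal OAR.
* **Unilateral** (anterior and posterior oblique at 45/135; single
  arc): the OAR sits medially on the arc's central axis, where both
  obliques' distal edges converge — the archetypal distal-edge
  conflict (OAR maximum physical dose ≈ 60 Gy).  This case carries the
  cap × threshold strategy screen, because with only two beams the
  low-threshold LET penalties genuinely compete with target coverage.

On the screen, target coverage is recorded both as V95 (fraction of
the target at ≥95% of prescription) and D95 (dose covering 95% of the
target).  The threshold orderings are asserted on D95 aggregated over
the cap grid: V95 on a 100–256 voxel target is quantised in steps of
1/|target| and saturates identically across threshold rows, while D95
is the same clinical quantity without the quantisation.  V95 remains
the metric for the "coverage within 5%" check on the LET-optimized
arm.

The synthetic cohort generator varies the target–OAR gap (1–10 mm),
the second OAR's placement, prescription tier, fraction number and
beam arrangement, all driven by a single seed; cases are tagged by
whether any nervous OAR reaches 50 Gy maximum physical dose, the
cohort inclusion rule.

## What the synthetic studies show — and what they do not

The phantoms are homogeneous water slabs with box structures, a
parametric beam model, and no robustness scenarios, MU constraints, or
delivery dynamics.  Passing tests therefore demonstrate that the
*mechanisms* are correctly implemented and that the qualitative
orderings (arc > PBS > LET-optimized PBS enhancement at a distal OAR;
entrance structures enhanced least; low dose thresholds wasteful, very
high thresholds ineffective) emerge from those mechanisms under
controlled geometry.  They do not validate absolute clinical dose or
LET values, cohort-level means on patients, or behaviour under
anatomical heterogeneity.  Published cohort numbers from institutional
patient plans are treated as out of scope; only directions and
orderings are compared.

## Numerical choices and degenerate inputs

* Grids may be degenerate (any axis of length 1); structures on a slab
  are exempt from the containment check along the slab axis.
* Voxel indices are 0-based, C-ordered; depths are measured from the
  phantom entry surface along each beam axis.
* The Bragg curve cache is keyed by (R, p, σ) rounded to 10⁻³ mm.
* Zero-extent depth ranges give a single energy layer; zero-length
  line profiles give a single sample; empty masks, non-positive caps,
  negative weights, mismatched sparsity patterns and beams that miss
  the grid all raise `ValueError`.
* The LET_d cap and all LET quantities are in keV/µm; only κ is in
  µm/keV.
* CSV/JSON outputs contain no timestamps, so identical configs and
  seeds reproduce byte-identical artifacts; manifests record the
  config, its SHA-256, the seed, the package version and content
  hashes of every written file.

## Problem sizes

The canonical cases use 3,600-voxel grids, ~700–900 PBS spots and
~7,000–14,000 arc spots (54 arc beams bilateral, 27 unilateral); a
full three-arm, two-model case evaluates in well under a minute and
the 20-combination strategy screen in about half a minute on one CPU.
These sizes were chosen so the whole study remains interactive at a
desk; all operators are vectorised/sparse and scale to finer grids.
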