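# Methods

## Problem setting

At 7 T the susceptibility difference between air and tissue induces
off-resonance fields in the brain that scale with B0 and concentrate near
the frontal sinus and ear canals.  The quantity minimized throughout this
package is the standard deviation of the off-resonance field over the brain
mask, in Hz.  The population (divide-by-N) convention is used everywhere, so
the std equals the RMS of the demeaned residual — precisely the objective of
the least-squares solver.

Coordinates are scanner-frame millimetres with the origin at isocenter and
z along B0 (toward the head); caudal offsets are negative z.  Field maps are
carried in Hz (γ/2π = 42.577 MHz/T).

## Field maps

A dual-echo gradient-echo acquisition yields the field via the wrapped
per-voxel phase difference, `Δf = wrap(φ₂−φ₁)/(2π·ΔTE)` with the wrap to
(−π, π].  With the typical ΔTE = 1 ms the alias-free range is ±500 Hz; no
spatial unwrapping is attempted (values aliasing beyond that range stay
wrapped — a documented limitation, not corrected).  Masks come from the
synthetic phantom or a companion NIfTI volume; without either, all finite
voxels are used.

## Biot–Savart synthesis

Each shim element is a circular loop approximated by a closed polygon of
`n_segments` chords with vertices on the circle; the z-field of every
straight segment follows the exact finite-segment expression
`B = μ0 I/(4π)·(a×b)(|a|+|b|)/(|a||b|(|a||b|+a·b))`.  Multi-turn elements
are one filament scaled by the turn count; the finite bundle cross-section
matters only for the circuit estimators.  Loops are planar by default
(tangent to the cylindrical former); an optional conformal mode projects the
vertices onto the former, changing near-surface fields by a few percent at
head distances.

Discretization error is second order: the inscribed polygon underestimates
the center field by π²/(3n²) (0.08 % at the default n = 64) and the far
field by the area deficit (2π)²/(6n²) (0.16 % at n = 64).  The default of
64 segments keeps basis columns well under 0.2 % of their peak value from
the converged (n = 4096) result, far below the solver's sensitivity on
noisy field maps.

## The center-plus-ring array

The eight-channel geometry is parametric: a center loop on a 37 cm former
at azimuth 0 and axial offset `z_offset`, surrounded by `n_outer` loops at
on-surface arc distance `r2`, equally spaced around the ring, all of radius
`r1`, with normals radial and tilted by `alpha` toward +z.  The reference
design is n_outer = 7, r1 = 37 mm, r2 = 95 mm, α = 0°, z = −8 mm, 50 turns.
Loops must not overlap (3D center distance ≥ radii sum); violations raise a
structured error naming the pair.  High-count comparison arrays (32/48
channels) are generic cylindrical grids — the published wire paths of such
arrays are not reproduced.

## Circuit estimators

Self-inductance of an N-turn element sums the thin-wire per-turn formula
`μ0 a (ln(8a/r_w) − 7/4)` and all pairwise coaxial mutual inductances
(Maxwell's elliptic-integral form), with the turns placed on a hexagonal
lattice in the winding cross-section.  The lattice pitch is set by a copper
**fill factor**: ideal orthocyclic packing is π/(2√3) ≈ 0.907, but
hand-wound ("wild") windings of enameled wire reach roughly 0.5–0.65, so the
default is 0.60 — the standard planning value for non-orthocyclic coils.
For the reference element (50 turns, 37 mm, 0.5 mm² wire) this predicts
307 µH; ideal close packing would predict 331 µH, which is why the fill
factor is exposed as an explicit model parameter.  The elliptic-integral
mutual is cross-checked in the tests against an independent Neumann
double-integral quadrature.

DC resistance is plain ρL/A with L = N·2πa.  For the reference element this
gives 0.39 Ω with ρ(Cu) = 1.68×10⁻⁸ Ω·m; reported bench values for such
elements can be lower, suggesting a thicker conductor than the nominal
cross-section reading — resistance is therefore a diagnostic, not a
validated quantity.

## Spherical-harmonic shims

SH shim channels are real solid harmonics `r^l Y_lm` up to order 4, each
scaled to unit RMS on a sphere of 90 mm radius so SH coefficients and loop
currents are numerically comparable in one solver.  SH channels are
unconstrained by default: hardware amp limits are not convertible to these
normalized units without a vendor calibration (per-channel bounds can be
supplied).  `remove_sh` is an unconstrained least-squares projection
(always including f0) and therefore idempotent and non-increasing in the
masked std; rank-deficient fits (e.g. through-slice terms on a single-slice
mask) raise an error naming the degenerate columns.

## Shim solving

Static shimming solves `min std(target + A·c)` under per-channel box
bounds.  Because an unbounded f0 column is always appended, minimizing the
sum of squares equals minimizing the variance, and the problem is
bound-constrained linear least squares, solved with scipy's `lsq_linear`
(BVLS active-set, optimality tolerance 1e-10, deterministic).  Sign
convention: the shim field *adds* to the map, so cancelling a field
generated by coefficients `c` returns currents `−c`.

Dynamic (slice-based) shimming solves the static problem per slice on the
mask voxels of the slice and its `window` neighbors (default ±1).  Two
residual summaries are reported: the per-region std (the quantity actually
optimized) and the **global std**, which assembles each slice's residual
from its own voxels under its own shim and takes the std over the whole
brain — the acquisition-faithful metric for a multi-slice scan.

The method roster applies static second-order removal first (`S2` is the
clinical standard), then an optional second stage: a static current-limited
array solve (`S2+MCn`, ±2.5 A per channel) or a dynamic solve with SH order
1–3 plus optionally an array (`D1/D2/D3`, `D1+MCn`).  A configuration
switch (`s2_first`) applies the dynamic SH methods to the raw map instead;
the S2-first reading is the default because dynamic methods are evaluated
as increments over the standard static shim.

## Geometry optimization

The design objective for a candidate geometry is the mean over field maps
of the residual std achieved by the ±2.5 A static solve with that
geometry's Biot–Savart basis — design and deployment use identical solver
and bounds.  The discrete outer-loop count is swept exhaustively (default
candidates 5–9); for each count the four continuous parameters are
optimized by Powell searches from Latin-hypercube starts (seeded,
deterministic), with invalid geometries scoring +∞.  Within the search the
basis may be evaluated at reduced segment counts and on a subsampled mask;
the reported objective is always re-evaluated on the full mask.  A
subject-specific design is compared to a fixed one by re-optimizing per map
with the fixed design as an extra start, which guarantees a nonnegative
improvement up to solver tolerance.

## Synthetic heads

The phantom is an ellipsoidal mask (default semi-axes 65 × 80 × 55 mm on a
64 × 64 × 31 grid of 3.75 mm voxels) with three field components: a random
low-order solid-harmonic background (per-order coefficient RMS 115/80/48 Hz
at the 90 mm reference radius), dipole fields `Δf = (Δχ/3)·f₀·(a/r)³·
(3cos²θ−1)` from air spheres placed at frontal-sinus, sphenoid and
ear-canal positions (Δχ = 9.4 ppm SI, overridable), and 3 Hz white noise.
Cohorts jitter the ellipsoid axes (±7 %), cavity positions (σ = 3 mm) and
susceptibilities (±20 %) with per-subject sub-seeds.

These defaults are calibrated so the cohort-mean unshimmed masked std falls
in the declared band of 100–190 Hz (`CALIBRATION_BAND_HZ`), bracketing the
~144 Hz reported for unshimmed 7 T brains; with the defaults the
ten-subject cohort at seed 1 measures ≈ 144 Hz mean and ≈ 39 Hz after
second-order removal.  The phantom reproduces the *structure* the shim
methods exploit (smooth background + localized inferior-frontal dipoles),
not anatomy: no tissue compartments, no FFT susceptibility solver, no
B0-drift or respiration dynamics.  Passing tests therefore demonstrate
correctness of the solvers and orderings between methods, not absolute
in-vivo performance numbers.

## Comparison protocol

`run_comparison` evaluates a label roster on every cohort subject and
reports mean ± standard error (sd/√n) over subjects.  The default MC
comparison arrays are *nested* (MC8 ⊂ MC32 ⊂ MC48: the ring design plus 24,
then 16 more grid loops), so channel-count monotonicity of the optimal
residual holds by construction and is asserted to 1e-6 Hz.  Pairwise
two-sided paired t tests are Bonferroni-corrected with the pair count
derived from the roster actually compared (5 methods → 10 pairs →
threshold 0.005 at family α = 0.05); zero-variance difference vectors are
flagged degenerate with p = 1.

## Problem sizes and numerical choices

- Default field-map grid 64 × 64 × 31 (≈ 22 000 mask voxels); solver and
  roster tests run on this grid with a ten-subject cohort.  Geometry
  searches use a coarse 32 × 32 × 16 phantom, 16-segment loops and 2×
  voxel subsampling — the recovered optimum is re-scored on the full mask.
- Solver determinism: BVLS with fixed tolerance; no random initialization
  anywhere; every stochastic stage takes an explicit seed.
- Degenerate inputs: empty masks, non-unit normals, overlapping loops,
  infeasible bounds and unknown method labels raise typed exceptions
  (`mcshim.errors`) rather than propagating numerical garbage.

## Known limitations

- Planar filament loops (conformal projection optional); no eddy currents,
  coil forces, thermal or RF-interaction modeling.
- The 32/48-channel arrays are generic nested stand-ins, not published
  geometries; their absolute performance should not be quoted.
- No spatial phase unwrapping; strongly aliased maps must be unwrapped
  upstream.
- The inductance model's fill factor is a winding-practice estimate; it
  sets the bundle's mean turn spacing, not the exact wire layout.
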