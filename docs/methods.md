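# Methods

## Physical model

The head is a piecewise-homogeneous quasistatic volume conductor with four
compartments — scalp, skull, CSF, brain — bounded by closed surfaces (skin,
outer skull, inner skull, pial). Conductivities default to the midpoints of
published ranges: 0.3, 0.006, 1.5, 0.3 S/m. Primary sources are current
dipoles oriented normal to the cortical surface (the orientation of
pyramidal-cell populations); all simultaneously active dipoles share one
moment amplitude q. Under the quasistatic approximation the forward map is
frequency-independent, so every attenuation result holds at all
physiological frequencies; no function in the package accepts a frequency
(asserted by a test).

Atrophy is modelled as a *global shrinkage*: dipole positions contract
toward the median centroid of the unshrunk source cloud by a fraction
s ∈ [0, 0.30], and the brain/CSF boundary contracts with them — in the
spherical model the brain shell radius scales by (1−s), in realistic mode
the pial surface vertices are contracted about the same centre — while
skull and scalp keep their dimensions. This expands the CSF compartment
inward, which is the dominant attenuation mechanism (the CSF both
increases the radial resistance toward the scalp and shunts current
tangentially). Shrinking only the sources while freezing the brain
boundary roughly halves the effect (0.9 vs 2.6 dB at 5%); the package
implements the boundary-shrinking semantics and exposes the source-only
variant through `run_spherical_experiment(shrink_brain_shell=False)`.

"Median centroid" is the coordinate-wise median of the dipole positions
(robust, order-free, exact for the symmetric spherical source spaces);
arithmetic-mean and geometric-median (Weiszfeld) alternatives are available
via `median_centroid(..., method=...)`. The centre is computed once from
the unshrunk sources and reused at every level so that levels are
comparable; dipole orientations are never changed by shrinkage.

## Spherical solver

The multilayer-sphere potential is evaluated as an exact Legendre series.
For each degree n the two radial basis coefficients are propagated from the
outermost no-flux boundary inward through 2×2 interface conditions
(continuity of V and σ r V′), each layer using basis functions normalized
by its outer radius so that all matrix entries stay O(n) and the recursion
is stable to degree several hundred. Matching the singular part in the
source layer yields a per-degree transfer factor G_n; the single-layer
limit G_n = (2n+1)/n and the invisible-interface limit (σ_CSF = σ_brain
collapses to a three-layer model, agreement ≤ 1e-10) pin the algebra, and
the angular conventions are fixed against the exact infinite-medium dipole
potential. Truncation: the series is summed until the running term falls
below a relative tolerance (default 1e-12) or n_max (default 400) is hit,
in which case a `ConvergenceError` carrying the last relative term is
raised; terms decay geometrically with ratio b/R_brain ≈ 0.77, so ~110
terms suffice at default tolerance. The conductivity-sensitivity sweep
reuses the same factors with the conductivity axes batched, which makes the
full 100×100 grid a single vectorized evaluation (&lt;1 s).

This exact series deliberately replaces the multi-dipole (Berg–Scherg)
approximation commonly used for sphere models: it removes one approximation
layer and serves as the oracle for the BEM. A test cross-checks it against
MNE-Python's Berg–Scherg sphere model; the two agree to the fit accuracy of
that approximation (~0.01 dB on attenuation values).

## BEM solver

The Geselowitz double-layer equation is discretized by linear collocation:
potentials linear over plane triangles, equations enforced at vertices.
Element integrals — the solid angle of a linearly-weighted plane triangle —
use the analytic formulas (van Oosterom–Strackee signed solid angle plus
closed-form edge line integrals), not quadrature; a test compares one
element against dense midpoint quadrature. Principal-value terms of
triangles containing the collocation vertex vanish on flat elements; the
curvature deficit is restored by the row-sum ("auto element") correction,
which enforces the smooth-surface identity B(1) = −1/2 on each surface's
self-block. The constant nullspace is removed by deflation (rank-one shift
on the outermost surface), and results are reported in the average
reference.

The low skull conductivity (1:250 contrast) is handled by the isolated
source approach with the inner skull as isolation boundary. The isolated
sub-problem (pial + inner skull, zero conductivity outside) is solved
first; because its exterior representation reproduces the primary potential
exactly, the full system's source term can be rewritten as
σ_skull [B_isk v_iso − ½ v_iso δ_isk] — numerically small and free of the
cancellation between the primary potential and the skull's secondary
sources. The full solution is the correction plus the isolated potential
extended by zero, so scalp potentials come directly from the correction
solve. Both the full and isolated systems are assembled once per geometry
and inverted densely (≤ 2568 unknowns at the default mesh budget,
seconds); per-dipole gains are matrix products with the precomputed
inverses. Electrodes are projected radially onto the skin mesh and
interpolated barycentrically within the containing triangle.

Near-surface sources degrade collocation accuracy: dipoles closer to the
pial mesh than 0.5× its mean edge length trigger a warning, closer than
0.15× are refused (both configurable). The default synthetic source
surface at 0.93× the local pial radius sits near the warning threshold at
subdivision 3 — the warning is informative, not spurious: it marks exactly
the regime where mesh refinement pays off.

### Accuracy at desk scale

On the meshed four-layer concentric-sphere model, linear collocation + ISA
at uniform icosphere subdivision 3 (642 vertices per surface) achieves
RDM ≤ 0.036 and MAG ≈ 0.92 against the exact series (eccentricities
0.3–0.8, radial and tangential dipoles). This ~8% systematic magnitude
deficit is a property of the solver family at this resolution, not of this
implementation: MNE-Python's linear-collocation ISA BEM on identical
meshes matches this solver to ~0.003 in both RDM and MAG. The thin CSF
(0.05 relative units) and skull (0.07) layers are narrower than the mesh
edge (~0.105), which is the known hard regime for collocation. Refining
the three inner meshes one level (subdivision 3 skin / 4 elsewhere)
reaches RDM ≤ 0.015 and MAG 0.981–0.986; uniform subdivision 4 gives
RDM ≤ 0.010, MAG 0.977–0.981 — monotone convergence. Attenuation results
are power *ratios* between two solves on nearly identical geometry, so the
systematic MAG bias cancels almost completely; the synthetic-head
attenuations at subdivision 3 (2.0/3.5 dB) agree with the spherical exact
values to a few tenths of a dB.

## Shrinkage experiment

Per electrode, an active patch of 20 equal-amplitude dipoles is selected on
the *unshrunk* model — by Euclidean proximity to the electrode (spherical
protocol) or by largest squared gain (realistic protocol) — and held fixed
across levels (ties break by dipole index). The electrode amplitude is the
coherent sum of patch gains (simultaneously active, equally driven sources
superpose linearly); power is its square, averaged over the electrode plus
its 4–7 adjacent channels in the power domain, and the reduction is
10 log₁₀(P_intact/P_shrunk). An incoherent (sum-of-squares) variant exists
behind `summation="incoherent"`; for these compact same-sign patches it
changes results by &lt; 0.02 dB. The statistic is exactly independent of q,
of global geometric scale, and of a global conductivity scale (tested).

The spherical protocol exploits symmetry: one electrode radially above the
patch centroid, raw (infinite-reference) potentials. With a whole-scalp
montage the deflated and raw conventions give the same dB to quadrature
accuracy (~0.01 dB for 128 electrodes), because a dipole's scalp potential
has zero sphere-average; a test asserts this reference insensitivity. The
realistic protocol repeats the measurement at all 128 electrodes,
re-assembling the BEM operator per level (the pial surface changed), and
reports mean ± population standard deviation across electrodes together
with the mean CSF thickness — the mean exact point-to-triangle distance
from inner-skull vertices to the shrunk pial surface.

## Conductivity sensitivity

At fixed 10% shrinkage the spherical attenuation is recomputed for every
pair on a grid of CSF ∈ [1.2, 1.8] S/m × skull ∈ [0.003, 0.015] S/m — "100
steps" realized as 100 linearly spaced values including both endpoints
(the most literal reading; including endpoints maximizes the estimated
variation, the conservative choice). Both the intact and shrunk states use
the same conductivities. Two summaries are produced: the max−min spread
(1.04 dB under the defaults) and the maximum absolute deviation from the
default-conductivity attenuation (0.53 dB), the latter being the package's
primary answer to "how much can conductivity uncertainty alter the
attenuation" — deviation-from-default is what that question measures,
while max−min double-counts excursions of opposite sign. The grid is
smooth and monotone along both axes, so a 10×10 sub-grid reproduces either
summary within 20% (fast mode).

## Synthetic head generator

`make_synthetic_head` emulates the qualitative anatomy of an MRI-derived
four-layer model without any subject data: base radii 100/90/83/78 mm (a
5 mm baseline CSF layer), each surface an icosphere whose radius is
modulated by a *shared* random smooth shape field — real spherical
harmonics of degrees 1–4 with seeded Gaussian coefficients, peak-normalized
and scaled by a 3% amplitude. Sharing one field keeps the surfaces
near-parallel (like a real head) and guarantees nesting; generation
nevertheless validates nesting and a minimum inter-surface gap and raises
with the offending pair named. Sources sit on a finer-resolution copy of
the pial shape at 0.93× the local pial radius, oriented along that
surface's vertex normals; 128 electrodes are golden-spiral directions
projected radially onto the skin mesh, with adjacency from the convex-hull
triangulation of the directions, clamped to 4–7 neighbours by distance
rank and kept symmetric. Everything is a deterministic function of one
integer seed.

What the generator does *not* emulate: cortical folding (gyri/sulci), a
separate cerebellum, skull-thickness variation, or realistic electrode-cap
asymmetries. The consequence is visible in the results: per-electrode
standard deviations on the synthetic head (~0.03–0.05 dB) are far smaller
than on a folded cortex (~1 dB), because dipole orientations vary smoothly
here. Passing tests on this geometry therefore demonstrate the solver and
the shrinkage mechanics, not anatomical realism; the spherical results
carry the quantitative claims.

## Default problem sizes

Spherical: 2562 dipoles (icosphere subdivision 4) at 0.99× brain radius,
series tolerance 1e-12. Realistic: four boundary meshes at subdivision 3
(2568 unknowns), 2562 sources, 128 electrodes, shrinkage re-assembly per
level. These desk-scale sizes run the full default experiment in about a
minute on one CPU; subdivision 4 (per surface or inner-only) is available
through the same configuration fields.

## Known limitations

* At uniform subdivision 3 the BEM misses the forward-validation
  thresholds RDM ≤ 0.02 / MAG ∈ [0.95, 1.05] on the four-layer sphere
  (MAG ≈ 0.92; see "Accuracy at desk scale"). The corresponding acceptance
  test is kept at those thresholds and fails; the refined-mesh variant
  passes and is tested alongside.
* The conductivity grid alters the attenuation by at most 0.53 dB, a hair
  above the 0.5 dB figure it is checked against (equal at the one-decimal
  precision that figure is stated with); the acceptance test keeps the
  strict bound and fails. The value is robust: the Berg–Scherg cross-check
  reproduces it to ~0.01 dB, and the incoherent summation variant moves it
  by 0.004 dB.
* STL I/O cannot preserve vertex indexing (the format is a triangle soup);
  OFF round-trips are exact. Electrode projection assumes a star-shaped
  skin surface (true for the synthetic generator).
* The realistic-model numbers depend on the synthetic geometry; they are
  qualitative counterparts of an MRI-based model, not reproductions of any
  subject.
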