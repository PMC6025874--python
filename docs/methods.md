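# Methods

This note documents the models, conventions and numerical choices behind
`nucstress`, and what the synthetic fixtures do and do not establish about
real nucleosome trajectories.

## The physical picture

Nucleosomal DNA is treated as a curved elastic tube. The 147-bp wrapped
region follows a left-handed superhelix around the histone core; the two
20-bp linkers leave it straight. Because the wrap radius (~4 nm) is an order
of magnitude below the bending persistence length of DNA (~50 nm), the
wrapped duplex stores substantial bending and torsional energy. A
double-strand break (two backbone cuts spaced 1 bp around a central A⋯T
pair) releases the constraint: whether the broken end folds back or
straightens out is decided by the competition between DNA–histone adhesion
(characterised by a free-energy barrier along the detachment coordinate ζ)
and internal stress relaxation (characterised by the line-tension and twist
profiles along the tube).

## Tube geometry

**Base pairing.** Both chains are numbered 1..L in their own 5′→3′ sense;
residue *i* of one chain pairs with residue L+1−*i* of the other. For the
187-bp duplex this puts the dyad pair at (94, 94) and makes every annotated
DSB central pair sum to 188. The dyad cut site M3 is the degenerate case:
its printed cut description conflicts with this rule, so the generator
places both cuts between residues 94|95 and flags the central-pair identity
as ambiguous instead of guessing.

**Centerline.** Control points are per-base-pair midpoints of the two
backbone P atoms (pairs whose 5′-terminal residue lacks a phosphate are
dropped with a warning), smoothed by a centered moving average (default
window 5 pairs; results should be reported together with this window, and
the TSV writer embeds it in the header). Tangents come from centered first
differences, curvature and the binormal from second differences projected
orthogonal to the tangent; **b** points toward the local curvature center
and **n** = **τ**×**b** completes a right-handed orthonormal frame. Where
curvature falls below κ_min (default 10⁻³ nm⁻¹, e.g. the straight linkers)
the frame is parallel-transported from the nearest well-curved point. On a
circle of radius R sampled at step h, the second-difference estimator is
second-order accurate and the moving average biases curvature up by roughly
(w²−1)(h/R)²/24 — about 0.7 % for the default geometry, well inside the 3 %
recovery tolerance used in the tests.

**ζ.** The broken end's axis center is the unweighted mean position of the
C4′ and P atoms of the last two base pairs. ζ is the distance from that
center to the closest histone atom, measured in the plane perpendicular to
the superhelical axis; "closest" minimises the same in-plane distance.
Hydrogens are excluded from the histone surface (a "surface atom" is
otherwise undefined); displacements parallel to the superhelical axis are
invisible by construction, and ζ is invariant under rotations about it.

**H-bonds.** Reported lengths are heavy-atom donor–acceptor distances (no
hydrogen geometry), in Å. The bound-fraction summary uses a configurable
cutoff (default 2.1 Å, the upper reference H-bond length at 350 K).

## Stress projection

Input stress fields are 3×3 symmetric tensors (MPa) on a regular grid,
assembled from nine scalar Gaussian-cube files in row-major component order
σxx..σzz. The cube dialect is documented in
`structures.write_tensor_grid`: lengths in nm, values in MPa (or declared
kJ mol⁻¹ nm⁻³, converted on read by ×1.6605), zero atom records, x-slowest
value order. Fields from different boxes are never averaged: the voxelwise
mean requires bit-identical grids, since shifted grids make large positive
and negative values cancel spuriously. The recommended time averaging is
100 frames at 10 ps spacing per 1 ns block.

Two scalar projections are taken per tube slice (slabs of width 0.5 nm
perpendicular to **τ**, centered at per-bp centerline points, restricted to
a 1.2 nm default tube radius; because the per-bp spacing of 0.34 nm is below
the slab width, adjacent slices overlap and the profile is intrinsically
smoothed):

* line tension *t* = **τ**ᵀσ**τ** in the default *cross-section* mode. The
  literal composition of the traction with the lateral tube normal
  (*t* = **r̂**ᵀσ**τ**) is also implemented and selectable
  (`normal_mode="lateral"`), but it vanishes identically for pure axial
  stress and therefore cannot express the bent-rod physics — tensile on the
  outer half, compressive on the inner half, zero on the neutral axis —
  that the cross-section mode reproduces; this irreconcilability is why
  both modes exist and cross-section is the default.
* twist stress *w* = (σ·**τ**)·(**τ**×**r̂**), with **r̂** normalised so *w*
  carries stress units (MPa); the unnormalised variant (MPa·nm) is a config
  option.

**Sign convention.** Compression is *positive*, tension *negative* — the
bent-rod reading, opposite to the continuum-mechanics convention
(`sign_convention="continuum"` flips it). The synthetic bent-rod generator
plants its axial component as A·d with d = (**x**−**c**)·**b**, i.e.
directly in this convention.

Slice membership uses voxel centers; empty slices are reported as missing
(NaN), never as zero. Per-slice means carry grid-alignment discretization
noise of a few percent at 0.15 nm spacing — the symmetry and equivariance
properties (inner/outer antisymmetry, invariance under joint rotation of
field and centerline) therefore hold at the few-percent level for
slice-averaged profiles, and exactly against a brute-force voxel oracle for
any individual slice.

## Essential dynamics

Covariance is the plain displacement covariance (nm², population 1/F
normalisation by default, configurable to 1/(F−1)); masses enter only in
the entropy formula, which keeps the covariance in the units that formula
expects. Frames are first rigid-body fitted to a reference (by default the
time-averaged intact-fragment structure) with a least-squares
superposition. Eigenvalues are reported descending with their fractions of
the total trace; per-mode RMSF is √λₖ times the per-atom eigenvector norm,
numerically in Å — these are relative weights of a collective mode, not
true atomic displacements, and the normalisation makes Σᵢ RMSFᵢ² = λₖ.
Essential-subspace similarity is quantified as RMSIP over the first d modes
(default d = 2, matching the two-eigenvector projection plots).

A caveat the test suite makes explicit: superposition removes rigid-body
motion, so planted covariance modes must be drawn from the rigid-body-
orthogonal complement (`planted_internal_modes`) to be recoverable —
physically, internal vibrational modes are orthogonal to translations and
rotations anyway.

## Schlitter entropy

S = ½k_B ln det[**I** + (k_B T e²/ħ²)**MC**], with **M** the diagonal mass
matrix (each atom's mass repeated for x, y, z) and **e** Euler's number
(≈ 2.71828) — *not* the elementary charge; misreading that symbol is the
classic implementation error. The determinant is evaluated from the
eigenvalues of the symmetrised product **I** + α**M**^½**CM**^½ (same
spectrum, symmetric positive definite) via log1p, with CODATA constants and
the unit chain amu·nm² → SI verified against `scipy.constants` in the
tests. The estimate is an upper bound: on a 1-D quantum harmonic oscillator
with classical variance k_BT/mω² it exceeds the exact oscillator entropy at
every ħω/k_BT tested (0.1, 1, 10) and approaches k_B[1 + ln(k_BT/ħω)] in
the classical limit.

Excess entropy uses time averages over disjoint 100-frame blocks (the
windowing is a package choice, not prescribed): TΔS = T(⟨S_damaged⟩ −
⟨S_intact⟩), reported in kcal/mol at T = 310 K.

## Umbrella sampling and WHAM

The bias convention is u(ζ) = ½k(ζ−ζ₀)² with k in kJ mol⁻¹ nm⁻² (spring
constants defined without the ½ must be doubled). The WHAM iteration solves
the standard self-consistent equations in log space (logsumexp), on
equal-width bins spanning the pooled sample range, until the window
free-energy constants change by less than 10⁻⁸ kcal/mol; adjacent windows
sharing no populated bin trigger a disconnection warning. Profiles are
min-shifted to zero, unpopulated bins are NaN, and each populated bin
carries a k_BT/√n Poisson uncertainty. Rather than reproducing a
progressive bias-reduction ladder inside the solver, each window's k is
taken as given; a ladder is analysed by running the solver per rung.
Barriers are ΔA = max A in a user-specified ζ region minus A at the
region's left edge, and p = 100·exp(−ΔA/k_BT).

Accuracy is assessed over the span covered by the window centers: outside
the ladder the profile is an extrapolation supported by a handful of tail
samples, where the pointwise error is dominated by shot noise. Inside the
ladder, the double-well recovery (3 k_BT barrier, minima 2 nm apart,
15 windows × 10⁴ exact samples) is accurate to well under 0.1 k_BT.

## Synthetic fixtures: scope and limits

The generator is deliberately coarse: per-nucleotide pseudo-atoms (P, C4′,
C1′ and base donor/acceptor sites N1 / O1–O2), the two strands' P atoms
placed diametrically opposite so the per-bp P midpoint lies exactly on the
analytic centerline, a Fibonacci-sphere shell standing in for the histone
core, and sequence filled with repeats except at the annotated cut sites
(linkers are d(AGTC) repeats; the wrapped region places the printed base
identities around M1–M4 so each DSB has an A⋯T center). Superhelix defaults
— radius 4.18 nm, pitch 2.39 nm, rise 0.34 nm/bp, 10.4 bp/turn — give the
canonical ~8 nm wrap diameter, ~1.9 turns and ~14 double-helical twists;
the pitch is a literature-typical value treated as a free parameter, since
geometry alone does not fix it.

Passing tests on these fixtures establish that the estimators are correct
against closed forms — not that real trajectories satisfy their
assumptions. The fixtures have no force-field energetics, no solvent or
ions, no histone tails, Gaussian (harmonic) fluctuations rather than
anharmonic ones, and exactly planted stress fields rather than CCFD output.
The headline trajectory-scale quantities (per-model excess entropies of the
deposited microsecond runs, their pooled eigenvalue fractions of ~65 % /
~55 %) therefore require the deposited condensed trajectories; the one
acceptance test that consumes them fails, by design, when the data are
absent.

## Problem sizes and reproducibility

Default analysis sizes were chosen so every oracle comparison is
statistically decisive at desk scale: 5000–10⁴ frames for covariance
recovery (sampling error ~√(2/F) ≈ 2 % per eigenvalue), 10⁴ samples per
umbrella window, 0.1–0.15 nm stress grids (slice discretization noise a
few percent), 30–150-point centerlines. Every stochastic component takes an
explicit integer seed (numpy `default_rng`); the CLI manifest records
parameters and SHA-256 output hashes, and identical config + seed
reproduce byte-identical outputs.
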