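# Methods

This note documents the models and numerical choices behind `patchscreen`:
what each pipeline stage computes, which parameters matter, what the
synthetic fixtures do and do not emulate, and where the design was
genuinely open.

## Surfaces

The molecular surface is the iso-1 level set of a sum-of-atom Gaussian
density ρ(x) = Σᵢ exp(−κ·(|x−xᵢ|² − rᵢ²)/rᵢ²) with κ = 2.3, sampled on a
regular grid padded 4 Å beyond the atoms and polygonised with marching
cubes (scikit-image).  κ is set so a single atom's density crosses 1 at
its van der Waals radius; the resulting surface closely tracks the vdW
envelope and smooths over atom-atom seams, similar in character to a
solvent-excluded surface without requiring a Poisson–Boltzmann solver.
Default grid spacings are 0.6 Å for proteins and 0.4 Å for ligands so that
a 5 Å patch contains dozens to hundreds of mesh vertices.  Mesh vertices,
outward normals (negative density gradient) and the edge graph (edge
weights = Euclidean lengths) form the `SurfacePointCloud` used everywhere
downstream.

Electrostatic potential at surface points comes either from a screened
Coulomb sum φ(x) = Σᵢ 332.06·qᵢ·exp(−dᵢ/λ)/(ε·dᵢ) with ε = 80 and
λ = 8 Å (kcal/mol/e), or from trilinear interpolation of an imported
OpenDX scalar grid (e.g. APBS output).  Units are never interconverted:
descriptors depend on the sign split and relative magnitudes only.

## Pockets

The pocket center is the mass-weighted centroid of the bound ligand's
heavy atoms.  1000 rays on a Fibonacci sphere are cast from the center up
to 12 Å; each ray keeps the first surface point within 1.2× the median
mesh edge length of its segment, and the hit set is dilated by one
adjacency ring to close pinholes between rays.  First-hit semantics keep
the pocket on the cavity walls rather than the protein's far side.

## Patches, geodesics and APP vectors

Seed points are the surface points nearest heavy atoms lying within 3.5 Å
of the surface, visited in ascending atom-to-surface distance (ties broken
by atom serial, making the iteration deterministic) and accepted under a
3.0 Å minimum mutual separation.  A patch is all surface points within
5.0 Å geodesic (graph shortest-path) distance of the seed; the geodesic
reading guarantees each patch is a single connected region.  Patches may
overlap; no ownership partition is imposed.  The seed point itself is the
patch center for every inter-patch distance.

The approximate patch position (APP) vector of a patch is the histogram of
its geodesic distances to all other patches in 40 bins of 1 Å; infinite
distances (disconnected surface components) land in the last bin with a
warning, and are capped at 40 Å wherever a numeric distance is required.

## 3D Zernike descriptors

Each patch is rasterised into a 64³ voxel grid centered at the patch
centroid and scaled so the farthest point sits at radius 0.7 of the unit
ball — per-patch scaling, so descriptors compare shape rather than size;
overall size differences enter the total score separately.  Rasterisation
splats each point's value onto its eight surrounding voxels with trilinear
weights.  Nearest-voxel rasterisation is available (`mode="nearest"`) but
the splat is the default because it suppresses lattice discretisation
noise: on a spherical-cap control patch the median rotational L2 deviation
of the shape descriptor drops from ~4.7% (nearest) to ~0.2% (trilinear) at
64³.

Three channels are rasterised per patch: occupancy (shape), max(φ, 0)
(positive potential) and |min(φ, 0)| (negative potential).  The voxel
function is projected directly onto the Zernike–Canterakis basis
Z_nlm = R_nl(r)·Y_lm(θ, φ) over the nonzero voxels, and the descriptor
collects F_nl = sqrt(Σ_m |Ω_nlm|²) for all 0 ≤ l ≤ n ≤ 15 with n − l even
(72 invariants per channel).  Two implementation details matter:

* The radial polynomials are built by exact Gram–Schmidt (rational
  arithmetic) of r^l, r^(l+2), … under the ball measure 3r² dr on [0, 1],
  with positive leading coefficients.  Norms F_nl are insensitive to
  per-(n, l) sign conventions, so this is equivalent to the closed-form
  coefficients while avoiding their large alternating terms.
* Spherical harmonics for all (l, m) are evaluated in one vectorised
  recurrence pass (validated against scipy to 1e-12), which makes
  per-patch descriptors cheap enough for library screening.

Direct lattice quadrature leaves a small cubic-anisotropy residue: the
voxelized solid ball shows l > 0 norms at ~1e-3…1e-2 of F₀₀ rather than
zero.  This bounds the achievable rotational invariance and is why the
invariance tests use percentage tolerances, not machine epsilon.

**Descriptor normalization.**  The pipeline rescales each surface's patch
descriptors by per-surface means: shape channels by the mean shape F₀₀,
and both electrostatic channels by the mean combined (pos + neg) F₀₀.
This cancels the systematic dependence on mesh density (pocket and ligand
surfaces are meshed at different resolutions) while preserving the
relative size and potential strength of patches within a surface, both of
which carry correspondence information.  Per-patch F₀₀ normalization
(`descriptor_norm="per_patch"`) is available but discards patch size and
inflates near-empty electrostatic channels into pure noise; raw norms
(`"none"`) are also available.

## Patch matching

The patch-pair distance is w₁·pdist + w₂·appd + w₃·grpd.  `pdist` is
0.717·L2(shape) + 0.283·L2(elec₁₄₄), the fixed internal weights
normalising the two properties' value ranges.  `grpd` measures, for a
candidate pair, the mean absolute difference between its geodesic
distances to already-matched pocket patches and the corresponding ligand
geodesics; with no prior pairs the term is zero.  Couples sharing either
patch with the candidate are excluded from the average.

Because grpd depends on the growing pair list, the search is sequential by
default: the globally cheapest available pair is fixed first, every later
candidate is scored against the pairs fixed so far, and the process runs
until the smaller side is exhausted (N = min(n_A, n_B) pairs).  An
alternative `two_phase` schedule solves a full assignment with grpd
ignored and then re-solves with costs recomputed against the previous
assignment (capped at five rounds).  The sequential schedule is the
default because it recovers native contacts measurably better on the
synthetic complexes and matches the natural reading of grpd accumulating
"over previous search steps".

Each assignment subproblem is solved with an ε-scaling auction: costs are
scaled to integers (×10⁶), ε starts at half the largest benefit and
shrinks by 5× until below 1/(n+1), at which point the integer solution is
exactly optimal.  Rectangular problems are padded with zero-cost dummy
rows (a forward auction alone is not optimality-safe on asymmetric
problems).  Auction totals are verified in tests against exhaustive
permutation minima and scipy's Hungarian solver.

## Scoring

For a matching m between pocket A and ligand B:

* avgZd — mean descriptor distance over matched pairs (an optional
  coverage penalty ×(n_A/N) exists behind a flag but is off by default);
* avgGrpd — mean |G2_A(aᵢ,aⱼ) − G2_B(bᵢ,bⱼ)| over unordered matched
  couples (its Euclidean analogue `rdp` serves the pocket-similarity
  variant); zero with a warning when fewer than two pairs exist;
* pocketSd — |n_A − n_B| / max(n_A, n_B), the patch-count size mismatch.

total_PL = 0.8·avgZd + 0.0·avgGrpd + 0.1·pocketSd with the trained
weights; the pocket-similarity variant uses descriptor-only matching and
the fixed combination 0.06·avgZd + 0.14·rdp + 0.8·pocketSd.  All totals
are lower-is-better.  Library screening averages each ligand's ten lowest
conformer totals; PocketScore aggregates the top-20 ranked conformers with
linear rank weights (k − i + 1), normalised by each type's conformer
count, and predicts the highest-scoring type.  The exact printed forms of
the avgZd/size/PocketScore expressions were not recoverable from the
source material; the prose-faithful forms above are isolated in single
functions for easy replacement.

## Evaluation machinery

A pocket patch and a ligand patch form a native contact when their centers
lie within a cutoff (default 5 Å, also 3/4/6) in the complex frame.  The
maximum number of native contacts is the size of a maximum one-to-one
bipartite matching on the contact graph (networkx Hopcroft–Karp); the
match success rate divides the matching's in-cutoff pair count by that
maximum, so it is always in [0, 1].  Distance-weight optimization scans
the two-parameter grid (w₁,w₂,w₃) = (a·b, a·(1−b), 1−a) for a, b in 0…1
step 0.1 (121 triples, each summing to 1); total-weight optimization scans
the full 11³ grid by mean training AUC, with per-conformer score
components precomputed once.  EF at X% uses a ceiling top-bucket; AUC is
the rank-based probability that an active outscores a decoy with ties at
half.

## Synthetic fixtures

`make_complex_fixture` builds a toy complex: a connected random-walk
ligand of 24 pseudo-atoms (step 1.8 Å, atomic radii drawn from
U(1.1, 2.3) Å for a rugged, drug-sized surface, confined to a 5.5 Å ball)
and a protein wall *cast onto the ligand surface* — wall atoms placed
along the outward surface normals so the realized surface-to-surface gap
is ≈1.6 Å, thinned to 2 Å spacing, with a second layer 2.6 Å further out
for thickness and the top 35% of the cast removed to leave an open cleft.
Under the dipolar charge pattern the wall is uniformly positive and the
ligand uniformly negative.  Casting (rather than a smooth geometric cup)
is essential: it is the only way a toy complex presents locally
complementary patch geometry, the feature the method exploits on real
complexes.  Screening fixtures pair jittered copies of the cavity-filling
ligand (actives, 3 conformers, σ = 0.35 Å) with fresh random-walk blobs of
identical composition and confinement (decoys).

What the fixtures do **not** emulate: real chemistry (elements beyond
C/N/O pseudo-atoms, bond geometry, protonation), realistic charge
distributions, solvent effects, and — most importantly — the scale and
shape diversity of real ligands and binding sites.  Patches of 5 Å radius
on a ~10 Å toy blob are dominated by the blob's gross curvature, so patch
descriptors are far less distinctive than on real molecular surfaces.
Consequently the native-contact recovery margin over random pairing
measured on these fixtures (~1.1–1.2×) is substantially smaller than
published desk-scale expectations drawn from real complex benchmarks, and
screening separation of actives from statistically identical decoy blobs
is weak.  Passing pipeline tests on these fixtures demonstrates
correctness of every stage's computation, determinism and the advertised
invariances — not real-data virtual-screening power.

## Problem sizes

The test suite and the acceptance script size their simulations to run on
a single CPU in minutes: 10–20 synthetic complexes for contact-recovery
statistics (with 100 random-pairing resamples each) and 4–20 screening
libraries of 50 ligands × 3 conformers.  These sizes give stable means
(seed-to-seed standard error of the recovery ratio ≈ 0.05) while keeping
a full run well under typical CI budgets.

## Known limitations

* The Gaussian isosurface is not a true solvent-excluded surface; users
  with APBS can import its OpenDX grids for both the surface-potential
  assignment and (indirectly) validation.
* Conformer generation is out of scope: multi-record SDF input is consumed
  as the conformer ensemble, with deduplication (best-fit heavy-atom RMSD,
  flexibility-dependent cutoffs 0.5/0.8/1.0 Å, max 20 kept) applied on
  read.
* Matching is hard one-to-one; no soft or many-to-many assignments.
* The method scores patch correspondence, not poses: no ligand orientation
  is produced.
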