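# patchscreen

Surface-patch complementarity screening of protein binding pockets against
ligand libraries.

`patchscreen` is for structural bioinformaticians and computational chemists
who want to rank candidate ligands for a binding pocket — or predict a
pocket's binding ligand type — without docking.  Instead of searching poses,
it represents both the pocket and the ligand as sets of segmented
molecular-surface patches, describes each patch with rotation-invariant 3D
Zernike descriptors of its shape and signed electrostatic potential, puts
pocket and ligand patches in one-to-one correspondence with an auction
assignment, and condenses the correspondence into a single complementarity
score.  Because every per-patch descriptor is precomputable, screening a
conformer against a pocket takes milliseconds.

## The method

**Patches.**  The molecular surface is the level set of a sum-of-atom
Gaussian density (an imported Poisson–Boltzmann OpenDX grid can substitute
for the built-in screened-Coulomb electrostatics).  Seed points are surface
points nearest to heavy atoms within 3.5 Å of the surface, accepted under a
3.0 Å mutual-separation constraint; a patch is the connected surface region
within 5.0 Å geodesic distance of its seed.

**Descriptors.**  Each patch is rasterised into the unit ball and expanded
in the Zernike–Canterakis basis; the per-(n, l) norms

    F_nl = sqrt( Σ_m |Ω_nlm|² ),   Ω_nlm = (3/4π) ∫ f(x) conj(Z_nlm(x)) dx

are rotation-invariant.  At order n = 15 the shape function gives 72
invariants and the electrostatic potential 144 (positive and negative
channels, 72 each).

**Matching.**  The distance between pocket patch a and ligand patch b is

    d(a,b) = w1·pdist(a,b) + w2·appd(a,b) + w3·grpd(a,b)

with `pdist` the weighted descriptor distance (0.717·shape + 0.283·elec),
`appd` the difference of approximate-patch-position histograms (40 bins of
1 Å of geodesic distances to the other patches), and `grpd` the geodesic
consistency of the pair with already-matched pairs.  A sequential auction
fixes pairs one at a time; the optimized weights are (0.35, 0.15, 0.5), the
pocket-comparison legacy weights (0.32, 0.48, 0.2).

**Scoring and screening.**  The overall fit of ligand B into pocket A is

    total(A,B) = w1·avgZd + w2·avgGrpd + w3·pocketSd     (lower = better)

with trained weights (0.8, 0.0, 0.1).  A library is ranked by each ligand's
mean of its ten best conformer totals; ligand-type prediction aggregates
the top-20 conformer ranks into a per-type PocketScore (higher = better).
Evaluation utilities cover native-contact match success rates, exhaustive
weight-grid searches, enrichment factors and ROC AUC.

## Worked example

```sh
python examples/match_complex.py
```

builds a synthetic complex (a rugged toy ligand inside a cavity cast onto
it), matches patches and reports native-contact recovery:

```
pocket: 22 patches, ligand: 15 patches
native contacts at 5 Å: 68 pairs, max one-to-one: 15
matched pairs: 15, success rate: 0.33
random-pairing baseline: 0.21
```

Here 33% of the recoverable pocket–ligand contacts were identified by the
matching, versus 21% expected from uniformly random pairing.  The other
examples cover surface/patch construction (`surface_and_patches.py`),
library screening with AUC and enrichment factors (`screen_library.py`),
and conformer deduplication (`conformer_dedup.py`).

A thin CLI mirrors the library (`pls convert | conformers | surface |
pocket | patches | screen | fixtures | run | config`), e.g.

```sh
pls fixtures --seed 7 --out fx/
pls run --protein fx/protein.pqr --ligand fx/ligand.sdf --out run/
```

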