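"""Deduplicate a conformer ensemble with the flexibility-dependent RMSD cutoff.

Conformers are compared by best-fit heavy-atom RMSD after Kabsch
superposition; the cutoff is 0.5 Å for rigid ligands (0-5 rotatable
bonds), 0.8 Å for 6-10, and 1.0 Å beyond, with at most 20 conformers kept.
"""

import warnings

warnings.filterwarnings("ignore", category=UserWarning)

import numpy as np

from patchscreen import ConformerSet, count_rotatable_bonds, filter_conformers, make_molecule
from patchscreen.fixtures import FixtureSpec

base = make_molecule(FixtureSpec(seed=5, n_atoms=12))
rng = np.random.default_rng(0)

conformers = [base]
for k in range(30):
    sigma = 0.05 if k % 3 else 0.8  # mix of near-duplicates and distinct shapes
    conformers.append(base.with_coords(base.coords + rng.normal(scale=sigma, size=(12, 3))))

ensemble = ConformerSet(base.id, conformers)
print(f"rotatable bonds: {count_rotatable_bonds(base)}")
print(f"raw ensemble: {len(ensemble)} conformers")

kept = filter_conformers(ensemble)
print(f"after dedup: {len(kept)} conformers (near-duplicates dropped, capped at 20)")
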