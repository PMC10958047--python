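"""Sample a conformer ensemble with the heat/minimize chain and prune it.

Runs a short high-temperature MD + minimization chain on butane,
applies the 15 kcal/mol energy window, and deduplicates at 0.50 A
heavy-atom RMSD.  The pruned ensemble is the set of distinct low-energy
rotamers.
"""

import warnings

from rdkit import Chem
from rdkit.Chem import AllChem

from tsnap import SamplingConfig, sample_ensemble
from tsnap.conformers import prune_ensemble

mol = Chem.AddHs(Chem.MolFromSmiles("CCCC"))
AllChem.EmbedMolecule(mol, randomSeed=3)

# 60 iterations of 0.1 ps at 1000 K (the production protocol uses 2500 x 1 ps)
config = SamplingConfig(iterations=60, md_length_ps=0.1, seed=5)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    raw = sample_ensemble(mol, config)
print(f"raw ensemble: {len(raw)} conformers, "
      f"energies {raw.e_min:.2f} .. {raw.energies.max():.2f} kcal/mol")

pruned = prune_ensemble(raw, window=config.window_kcal, rmsd_cut=config.rmsd_cut_A)
print(f"after 15 kcal/mol window + 0.50 A dedup: {len(pruned)} conformers")
for c in pruned.conformers:
    print(f"  E = {c.energy:7.3f} kcal/mol  (iteration {c.iteration})")
print("the two survivors are the anti and gauche rotamers of the C-C-C-C torsion.")
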