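"""Compute macrocycle substituent descriptors for library compounds.

Partitions each assembled macrolide into its macrocyclic backbone (the
largest ring of size >= 12) and substituents, then reports the three
axes used to cluster actives: % heavy atoms in substituents, % polar
heavy atoms among substituents, and cLogP.
"""

from tsnap import enumerate_library
from tsnap.descriptors import descriptor_table
from tsnap.fixtures import FixtureSpec, toy_building_blocks

manifest = enumerate_library(toy_building_blocks(FixtureSpec(n_thf=1, n_enoate=2, n_side=3)))
table = descriptor_table(manifest.compounds[::4])  # one stereo variant per triple
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print("\npct_ha_subst: share of heavy atoms outside the macrocycle backbone")
print("pct_polar_ha_subst: N/O/S fraction of those substituent atoms")
print("clogp: Wildman-Crippen octanol-water partition estimate")
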