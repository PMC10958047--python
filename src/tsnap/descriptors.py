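"""Macrocycle-aware physicochemical descriptors.

The descriptor axes used to cluster actives are defined against a
partition of each molecule's heavy atoms into the macrocyclic backbone
(the single perceived ring of size >= 12) and everything else, the
"substituents".  Side chains, exocyclic carbonyl oxygens and fused-ring
atoms not shared with the macrocycle all count as substituents; atoms
shared between the macrocycle and a fused small ring belong to the
backbone.  Polar substituent atoms are N, O and S by default (halogens
count as nonpolar).
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen

POLAR_ELEMENTS = frozenset((7, 8, 16))  # N, O, S

MIN_MACROCYCLE_SIZE = 12


@dataclass(frozen=True)
class MacrocyclePartition:
    """Backbone / substituent split of a molecule's heavy atoms."""

    backbone_atoms: frozenset[int]
    substituent_atoms: frozenset[int]
    polar_substituent_atoms: frozenset[int]

    def __post_init__(self):
        if self.backbone_atoms & self.substituent_atoms:
            raise ValueError("backbone and substituent sets must be disjoint")
        if not self.polar_substituent_atoms <= self.substituent_atoms:
            raise ValueError("polar substituent atoms must be substituent atoms")


def find_macrocycle(mol: Chem.Mol) -> frozenset[int]:
    """Atom indices of the macrocyclic backbone ring.

    The largest SSSR ring of size >= 12; ties broken by most ring
    oxygens (the ester-bearing ring), then by lowest sorted atom
    indices.  Raises ValueError when no ring qualifies.
    """
    rings = [r for r in mol.GetRingInfo().AtomRings() if len(r) >= MIN_MACROCYCLE_SIZE]
    if not rings:
        raise ValueError("not a macrocycle: no ring of size >= 12")

    def sort_key(ring):
        n_oxy = sum(1 for i in ring if mol.GetAtomWithIdx(i).GetAtomicNum() == 8)
        return (-len(ring), -n_oxy, tuple(sorted(ring)))

    return frozenset(min(rings, key=sort_key))


def partition_molecule(mol: Chem.Mol,
                       polar_elements: frozenset[int] = POLAR_ELEMENTS) -> MacrocyclePartition:
    backbone = find_macrocycle(mol)
    heavy = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1}
    substituents = frozenset(heavy - backbone)
    polar = frozenset(i for i in substituents
                      if mol.GetAtomWithIdx(i).GetAtomicNum() in polar_elements)
    return MacrocyclePartition(frozenset(backbone), substituents, polar)


def substituent_percentages(mol: Chem.Mol,
                            partition: MacrocyclePartition | None = None) -> tuple[float, float]:
    """(% heavy atoms in substituents, % polar heavy atoms in substituents).

    The first percentage is relative to all heavy atoms; the second is
    relative to the substituent atoms (0 when there are none).
    """
    if partition is None:
        partition = partition_molecule(mol)
    n_heavy = len(partition.backbone_atoms) + len(partition.substituent_atoms)
    n_sub = len(partition.substituent_atoms)
    pct_ha = 100.0 * n_sub / n_heavy
    pct_polar = 100.0 * len(partition.polar_substituent_atoms) / n_sub if n_sub else 0.0
    return pct_ha, pct_polar


def clogp(mol: Chem.Mol) -> float:
    """Atomic-contribution (Wildman-Crippen) logP."""
    Chem.SanitizeMol(mol)
    return float(Crippen.MolLogP(mol))


def descriptor_table(compounds, include_clogp: bool = True):
    """Descriptor rows (id, pct_ha_subst, pct_polar_ha_subst, clogp) as a DataFrame."""
    import pandas as pd

    rows = []
    for c in compounds:
        mol = c.mol if hasattr(c, "mol") else c
        cid = c.id if hasattr(c, "id") else Chem.MolToSmiles(mol)
        pct_ha, pct_polar = substituent_percentages(mol)
        row = {"id": cid, "pct_ha_subst": pct_ha, "pct_polar_ha_subst": pct_polar}
        if include_clogp:
            row["clogp"] = clogp(mol)
        rows.append(row)
    return pd.DataFrame(rows)
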