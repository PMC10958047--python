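"""Pluggable energy/gradient backends for conformational sampling.

The sampling, restraint, filtering and deduplication logic in
:mod:`tsnap.conformers` only needs a deterministic potential exposing
``energy(coords) -> kcal/mol`` and ``gradient(coords) -> kcal/mol/A`` for
all-atom coordinates in Angstroms.  The production backend wraps the
MMFF94 implementation shipped with RDKit; a cheap quadratic surrogate is
provided for exercising the sampling machinery in tests.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


@runtime_checkable
class ForceFieldBackend(Protocol):
    """Contract: a deterministic potential over all-atom coordinates."""

    def energy(self, coords: np.ndarray) -> float:
        """Potential energy in kcal/mol at ``coords`` (n_atoms, 3) in A."""
        ...

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        """dE/dx in kcal/mol/A, shape (n_atoms, 3)."""
        ...


class MMFFBackend:
    """MMFF94 energies and gradients via RDKit.

    The molecule must carry explicit hydrogens and at least one conformer
    (the force field is parametrized once against that topology).
    MMFF94 here is gas phase; a solvent dielectric can be folded into the
    electrostatic term via ``dielectric`` (distance-dependent model).
    """

    def __init__(self, mol: Chem.Mol, variant: str = "MMFF94", dielectric: float = 1.0):
        if mol.GetNumConformers() == 0:
            raise ValueError("molecule needs an initial 3D geometry")
        self.mol = mol
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant=variant)
        if props is None:
            raise ValueError("MMFF94 cannot parametrize this molecule")
        if dielectric != 1.0:
            props.SetMMFFDielectricConstant(dielectric)
            props.SetMMFFDielectricModel(2)  # distance-dependent
        self._ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        self.n_atoms = mol.GetNumAtoms()

    def _flat(self, coords: np.ndarray) -> list[float]:
        pos = np.asarray(coords, dtype=float)
        if pos.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        # positions must be handed over explicitly as a flat list: the
        # no-argument forms evaluate at stale internal coordinates
        return pos.ravel().tolist()

    def energy(self, coords: np.ndarray) -> float:
        return float(self._ff.CalcEnergy(self._flat(coords)))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        flat = self._flat(coords)
        # CalcGrad reuses terms cached by the last energy evaluation, so a
        # gradient is only trustworthy right after an energy call at the
        # same coordinates
        self._ff.CalcEnergy(flat)
        g = self._ff.CalcGrad(flat)
        return np.asarray(g, dtype=float).reshape(self.n_atoms, 3)

    def masses(self) -> np.ndarray:
        return np.array([a.GetMass() for a in self.mol.GetAtoms()])


class QuadraticBackend:
    """Harmonic well around a reference geometry: E = 0.5 k |x - x0|^2.

    A single-basin surrogate used to test minimization, determinism and
    filtering independently of force-field numerics.
    """

    def __init__(self, reference: np.ndarray, k: float = 10.0):
        self.reference = np.asarray(reference, dtype=float)
        self.k = float(k)

    def energy(self, coords: np.ndarray) -> float:
        d = np.asarray(coords, dtype=float) - self.reference
        return 0.5 * self.k * float(np.sum(d * d))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(coords, dtype=float) - self.reference)


def check_gradient(backend: ForceFieldBackend, coords: np.ndarray,
                   h: float = 1e-5) -> float:
    """Max abs deviation between analytic and central-difference gradient."""
    coords = np.asarray(coords, dtype=float)
    g = backend.gradient(coords)
    worst = 0.0
    for i in range(coords.shape[0]):
        for j in range(3):
            x = coords.copy()
            x[i, j] += h
            ep = backend.energy(x)
            x[i, j] -= 2 * h
            em = backend.energy(x)
            worst = max(worst, abs((ep - em) / (2 * h) - g[i, j]))
    return worst
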