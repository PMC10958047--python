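"""Conformer ensemble generation, restraints, filtering and deduplication.

The sampling protocol is an iterated heat-then-quench chain: short
high-temperature molecular dynamics (default 1 ps at 1000 K, 1 fs steps)
followed by gradient minimization to a tight RMS-gradient tolerance,
each iteration seeded from the previous minimized geometry.  Double-bond
torsions are kept honest during sampling by a soft one-sided harmonic
restraint that engages only beyond a 45 degree deviation from the ideal
E/Z geometry; conformers whose stereochemistry inverts anyway are
discarded.  The raw ensemble is then reduced by an energy window above
the global minimum (default 15 kcal/mol) and greedy RMSD deduplication
(default 0.50 A heavy-atom cutoff, sweeping from the minimum upward).

Energies reported on conformers are unrestrained backend energies; the
torsion restraint is a sampling device, not part of the potential whose
window defines retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from tsnap.forcefield import ForceFieldBackend, MMFFBackend

# 1 kcal/mol/(A*amu) expressed as acceleration in A/fs^2
_ACCEL = 4.184e-4
# Boltzmann constant in kcal/mol/K
_KB = 0.0019872041
# kinetic energy conversion: 0.5*m[amu]*v^2[A^2/fs^2] * _KE2KCAL -> kcal/mol
_KE2KCAL = 1.0 / _ACCEL


@dataclass(frozen=True)
class Conformer:
    """One minimized geometry with its (unrestrained) energy."""

    coords: np.ndarray  # (n_atoms, 3) in A, all atoms incl. hydrogens
    energy: float  # kcal/mol
    iteration: int = 0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.isfinite(self.energy):
            raise ValueError("conformer energy must be finite")


@dataclass
class ConformerEnsemble:
    """Energy-sorted conformer collection for one molecule."""

    mol: Chem.Mol
    conformers: list[Conformer]
    n_discarded_stereo: int = 0
    n_unconverged: int = 0

    def __post_init__(self):
        n = self.mol.GetNumAtoms()
        for c in self.conformers:
            if c.coords.shape != (n, 3):
                raise ValueError(
                    f"conformer has {c.coords.shape[0]} coordinates, molecule has {n} atoms")
        self.conformers = sorted(self.conformers, key=lambda c: c.energy)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def e_min(self) -> float:
        if not self.conformers:
            raise ValueError("empty ensemble has no minimum energy")
        return self.conformers[0].energy

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1])


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling protocol parameters (defaults: the production protocol)."""

    iterations: int = 2500
    md_length_ps: float = 1.0
    timestep_fs: float = 1.0
    temperature_K: float = 1000.0
    window_kcal: float = 15.0
    rmsd_cut_A: float = 0.50
    grad_tol: float = 0.01  # kcal/mol/A, RMS over components
    torsion_k: float = 0.005  # kcal/deg^2, valid range 0.005-0.01
    torsion_threshold_deg: float = 45.0
    dielectric: float = 78.3
    seed: int = 0
    max_minimize_steps: int = 1000

    def __post_init__(self):
        for name in ("iterations", "md_length_ps", "timestep_fs", "temperature_K",
                     "window_kcal", "rmsd_cut_A", "grad_tol", "torsion_k",
                     "torsion_threshold_deg", "dielectric"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.005 <= self.torsion_k <= 0.01):
            raise ValueError("torsion_k must lie in [0.005, 0.01] kcal/deg^2")


# ---------------------------------------------------------------------------
# double-bond torsions and the one-sided harmonic restraint


def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _wrap_deg(delta: float) -> float:
    return (delta + 180.0) % 360.0 - 180.0


def double_bond_torsions(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Torsion quadruples (a, i, j, b) for every stereo-capable C=C bond.

    Reference atoms a/b are the highest-index heavy neighbours on each
    side; bonds lacking a substituent on either side carry no torsion.
    """
    quads = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        bi, bj = bond.GetBeginAtom(), bond.GetEndAtom()
        if bi.GetAtomicNum() != 6 or bj.GetAtomicNum() != 6:
            continue
        if bi.GetIsAromatic() or bj.GetIsAromatic():
            continue
        na = [n.GetIdx() for n in bi.GetNeighbors()
              if n.GetIdx() != bj.GetIdx() and n.GetAtomicNum() > 1]
        nb = [n.GetIdx() for n in bj.GetNeighbors()
              if n.GetIdx() != bi.GetIdx() and n.GetAtomicNum() > 1]
        if na and nb:
            quads.append((max(na), bi.GetIdx(), bj.GetIdx(), max(nb)))
    return quads


def ideal_torsions(mol: Chem.Mol, coords: np.ndarray,
                   quads: Sequence[tuple[int, int, int, int]]) -> np.ndarray:
    """Snap each double-bond torsion of the given geometry to 0 or 180 deg."""
    ideals = []
    for (a, i, j, b) in quads:
        tau = _dihedral_deg(coords[a], coords[i], coords[j], coords[b])
        ideals.append(0.0 if abs(_wrap_deg(tau)) < 90.0 else 180.0)
    return np.array(ideals)


def torsion_penalty(coords: np.ndarray, quads, ideals, k: float,
                    threshold: float = 45.0) -> float:
    """Sum of k*(|dtau| - threshold)^2 over torsions deviating beyond threshold.

    The inequality is strict: a torsion at exactly the threshold incurs
    zero penalty.
    """
    coords = np.asarray(coords, dtype=float)
    pen = 0.0
    for (a, i, j, b), ideal in zip(quads, ideals):
        tau = _dihedral_deg(coords[a], coords[i], coords[j], coords[b])
        dev = abs(_wrap_deg(tau - ideal))
        if dev > threshold:
            pen += k * (dev - threshold) ** 2
    return pen


def restrained_energy(coords: np.ndarray, mol: Chem.Mol,
                      backend: ForceFieldBackend, config: SamplingConfig,
                      quads=None, ideals=None) -> float:
    """Backend energy plus the soft double-bond torsion restraint."""
    coords = np.asarray(coords, dtype=float)
    if quads is None:
        quads = double_bond_torsions(mol)
    if ideals is None:
        ideals = ideal_torsions(mol, coords, quads)
    return backend.energy(coords) + torsion_penalty(
        coords, quads, ideals, config.torsion_k, config.torsion_threshold_deg)


def _penalty_gradient(coords, quads, ideals, k, threshold, h=1e-5) -> np.ndarray:
    """Central-difference gradient of the torsion penalty (sparse: 4 atoms/torsion)."""
    g = np.zeros_like(coords)
    active_atoms = sorted({a for quad in quads for a in quad})
    if not active_atoms:
        return g
    for idx in active_atoms:
        for dim in range(3):
            coords[idx, dim] += h
            ep = torsion_penalty(coords, quads, ideals, k, threshold)
            coords[idx, dim] -= 2 * h
            em = torsion_penalty(coords, quads, ideals, k, threshold)
            coords[idx, dim] += h
            g[idx, dim] = (ep - em) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# stereochemistry bookkeeping


def _chiral_signatures(mol: Chem.Mol, coords: np.ndarray) -> list[tuple[int, float]]:
    """Signed volume at every atom carrying a chiral tag (sign = parity)."""
    sigs = []
    for atom in mol.GetAtoms():
        if atom.GetChiralTag() in (Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                                   Chem.ChiralType.CHI_TETRAHEDRAL_CCW):
            nbrs = [n.GetIdx() for n in atom.GetNeighbors()][:4]
            if len(nbrs) < 3:
                continue
            c = coords[atom.GetIdx()]
            v = [coords[n] - c for n in nbrs[:3]]
            sigs.append((atom.GetIdx(), float(np.dot(np.cross(v[0], v[1]), v[2]))))
    return sigs


def _stereo_preserved(mol, coords, quads, ideals, ref_chiral) -> bool:
    for (a, i, j, b), ideal in zip(quads, ideals):
        tau = _dihedral_deg(coords[a], coords[i], coords[j], coords[b])
        if abs(_wrap_deg(tau - ideal)) > 90.0:
            return False
    cur = dict(_chiral_signatures(mol, coords))
    for idx, ref_vol in ref_chiral:
        if idx in cur and ref_vol * cur[idx] < 0:
            return False
    return True


# ---------------------------------------------------------------------------
# the heat/minimize sampling chain


def _maxwell_boltzmann(rng, masses, temperature) -> np.ndarray:
    sigma = np.sqrt(_KB * temperature / (masses * _KE2KCAL))[:, None]
    return rng.normal(0.0, 1.0, size=(len(masses), 3)) * sigma


def _md_segment(coords, velocities, masses, grad_fn, n_steps, dt_fs,
                temperature, tau_fs=100.0):
    """Velocity-Verlet with Berendsen velocity rescaling; returns final coords."""
    inv_m = (_ACCEL / masses)[:, None]
    x = coords.copy()
    v = velocities
    a = -grad_fn(x) * inv_m
    n_dof = 3 * len(masses)
    for _ in range(n_steps):
        x = x + v * dt_fs + 0.5 * a * dt_fs ** 2
        a_new = -grad_fn(x) * inv_m
        v = v + 0.5 * (a + a_new) * dt_fs
        a = a_new
        ke = 0.5 * float(np.sum(masses[:, None] * v * v)) * _KE2KCAL
        t_inst = 2.0 * ke / (n_dof * _KB)
        if t_inst > 1e-12:
            lam = np.sqrt(max(0.5, min(2.0, 1.0 + (dt_fs / tau_fs) * (temperature / t_inst - 1.0))))
            v = v * lam
    return x


def _minimize(coords, energy_fn, grad_fn, grad_tol, max_steps):
    """L-BFGS to an RMS-gradient tolerance; returns (coords, converged)."""
    shape = coords.shape

    def fun(x):
        return energy_fn(x.reshape(shape))

    def jac(x):
        return grad_fn(x.reshape(shape)).ravel()

    res = _scipy_minimize(fun, coords.ravel(), jac=jac, method="L-BFGS-B",
                          options={"maxiter": max_steps, "gtol": 1e-8, "ftol": 1e-12})
    out = res.x.reshape(shape)
    rms = float(np.sqrt(np.mean(jac(res.x) ** 2)))
    return out, rms <= grad_tol


def sample_ensemble(mol: Chem.Mol, config: SamplingConfig,
                    backend: ForceFieldBackend | None = None) -> ConformerEnsemble:
    """Run the iterated heat/minimize chain and return the raw ensemble.

    ``mol`` must carry explicit hydrogens and an initial 3D conformer.
    Each iteration heats the previous minimized geometry with short MD at
    the target temperature (restrained forces), re-minimizes, and records
    the unrestrained energy.  Deterministic for a fixed config seed:
    per-iteration velocities come from counter-based seed splitting.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule needs an initial 3D geometry (embed it first)")
    if backend is None:
        backend = MMFFBackend(mol, dielectric=config.dielectric)
    coords0 = np.array(mol.GetConformer().GetPositions(), dtype=float)
    if isinstance(backend, MMFFBackend):
        masses = backend.masses()
    else:
        masses = np.array([max(a.GetMass(), 1.0) for a in mol.GetAtoms()])

    quads = double_bond_torsions(mol)
    ideals = ideal_torsions(mol, coords0, quads)
    ref_chiral = _chiral_signatures(mol, coords0)
    k, thr = config.torsion_k, config.torsion_threshold_deg

    def r_energy(x):
        return backend.energy(x) + torsion_penalty(x, quads, ideals, k, thr)

    def r_grad(x):
        g = backend.gradient(x)
        if quads:
            g = g + _penalty_gradient(x, quads, ideals, k, thr)
        return g

    n_md_steps = max(1, int(round(config.md_length_ps * 1000.0 / config.timestep_fs)))
    conformers: list[Conformer] = []
    n_bad_stereo = 0
    n_unconverged = 0

    current, converged = _minimize(coords0, r_energy, r_grad,
                                   config.grad_tol, config.max_minimize_steps)
    if not converged:
        n_unconverged += 1
        current = coords0
    elif _stereo_preserved(mol, current, quads, ideals, ref_chiral):
        conformers.append(Conformer(current, backend.energy(current), 0, config.seed))

    for it in range(1, config.iterations):
        child = np.random.SeedSequence([config.seed, it])
        rng = np.random.default_rng(child)
        v0 = _maxwell_boltzmann(rng, masses, config.temperature_K)
        heated = _md_segment(current, v0, masses, r_grad, n_md_steps,
                             config.timestep_fs, config.temperature_K)
        minimized, converged = _minimize(heated, r_energy, r_grad,
                                         config.grad_tol, config.max_minimize_steps)
        if not converged:
            n_unconverged += 1
            continue
        if not _stereo_preserved(mol, minimized, quads, ideals, ref_chiral):
            n_bad_stereo += 1
            continue
        conformers.append(Conformer(minimized, backend.energy(minimized), it, config.seed))
        current = minimized

    if n_unconverged:
        warnings.warn(f"{n_unconverged} minimizations did not reach "
                      f"RMS gradient {config.grad_tol}; conformers excluded")
    if n_bad_stereo:
        warnings.warn(f"{n_bad_stereo} conformers discarded for stereochemistry inversion")
    return ConformerEnsemble(mol, conformers, n_discarded_stereo=n_bad_stereo,
                             n_unconverged=n_unconverged)


# ---------------------------------------------------------------------------
# filtering and deduplication


def filter_energy_window(ensemble: ConformerEnsemble,
                         window: float = 15.0) -> ConformerEnsemble:
    """Retain conformers within ``window`` kcal/mol of the ensemble minimum."""
    if not ensemble.conformers:
        raise ValueError("cannot filter an empty ensemble")
    e0 = ensemble.e_min
    kept = [c for c in ensemble.conformers if c.energy - e0 <= window]
    return ConformerEnsemble(ensemble.mol, kept,
                             n_discarded_stereo=ensemble.n_discarded_stereo,
                             n_unconverged=ensemble.n_unconverged)


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                atom_subset: Sequence[int] | None = None) -> float:
    """Minimum RMSD over rigid rotations + translations (optimal superposition)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if atom_subset is not None:
        a = a[np.asarray(atom_subset)]
        b = b[np.asarray(atom_subset)]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if a.shape[0] == 1:  # a single point superposes exactly
        return 0.0
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def deduplicate_rmsd(ensemble: ConformerEnsemble, rmsd_cut: float = 0.50,
                     heavy_only: bool = True) -> ConformerEnsemble:
    """Greedy ascending-energy sweep: drop any conformer within ``rmsd_cut``
    of an already-kept (lower-energy) one.  The global minimum always survives."""
    if not ensemble.conformers:
        return ensemble
    subset = ensemble.heavy_atom_indices() if heavy_only else None
    kept: list[Conformer] = []
    for cand in ensemble.conformers:  # already ascending
        if all(kabsch_rmsd(cand.coords, k.coords, subset) >= rmsd_cut for k in kept):
            kept.append(cand)
    return ConformerEnsemble(ensemble.mol, kept,
                             n_discarded_stereo=ensemble.n_discarded_stereo,
                             n_unconverged=ensemble.n_unconverged)


def prune_ensemble(ensemble: ConformerEnsemble, window: float = 15.0,
                   rmsd_cut: float = 0.50) -> ConformerEnsemble:
    """Energy-window filter followed by RMSD deduplication."""
    return deduplicate_rmsd(filter_energy_window(ensemble, window), rmsd_cut)


# ---------------------------------------------------------------------------
# quick embedding-based ensembles and SDF round-trip


def embed_ensemble(mol: Chem.Mol, n_confs: int = 3, seed: int = 0,
                   rmsd_cut: float = 0.5) -> ConformerEnsemble:
    """Distance-geometry ensemble with MMFF-minimized energies.

    A fast alternative to the MD chain for scoring work: embeds
    ``n_confs`` ETKDG starting points, MMFF-minimizes each, and returns
    the pruned ensemble.  Deterministic for a fixed seed.
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if not ids:
        raise ValueError("embedding failed: no conformers generated")
    AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=2000)
    backend = MMFFBackend(molh)
    confs = []
    for i, cid in enumerate(ids):
        coords = np.array(molh.GetConformer(cid).GetPositions(), dtype=float)
        confs.append(Conformer(coords, backend.energy(coords), iteration=i, seed=seed))
    ens = ConformerEnsemble(molh, confs)
    return deduplicate_rmsd(ens, rmsd_cut)


def write_ensemble_sdf(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Serialize as a multi-record SDF (energy and provenance as properties)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    mol = Chem.Mol(ensemble.mol)
    if mol.GetNumConformers() == 0:
        mol.AddConformer(Chem.Conformer(mol.GetNumAtoms()), assignId=True)
    for c in ensemble.conformers:
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, Point3D(*c.coords[i]))
        mol.SetProp("energy_kcal", repr(c.energy))
        mol.SetProp("iteration", str(c.iteration))
        mol.SetProp("seed", str(c.seed))
        writer.write(mol)
    writer.close()


def read_ensemble_sdf(path: str | Path) -> ConformerEnsemble:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"no records in {path}")
    confs = [
        Conformer(np.array(m.GetConformer().GetPositions(), dtype=float),
                  float(m.GetProp("energy_kcal")),
                  int(m.GetProp("iteration")), int(m.GetProp("seed")))
        for m in mols
    ]
    return ConformerEnsemble(mols[0], confs)
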