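"""Sampling chain, torsion restraint, energy window, RMSD machinery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from scipy.spatial.transform import Rotation

from tsnap.conformers import (
    Conformer,
    ConformerEnsemble,
    SamplingConfig,
    _dihedral_deg,
    deduplicate_rmsd,
    double_bond_torsions,
    embed_ensemble,
    filter_energy_window,
    ideal_torsions,
    kabsch_rmsd,
    prune_ensemble,
    read_ensemble_sdf,
    restrained_energy,
    sample_ensemble,
    torsion_penalty,
    write_ensemble_sdf,
)
from tsnap.forcefield import MMFFBackend, QuadraticBackend, check_gradient

from conftest import random_ensemble


def embedded(smiles, seed=1):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return mol


class TestDefaults:
    def test_protocol_parameter_defaults(self):
        cfg = SamplingConfig()
        assert cfg.iterations == 2500
        assert cfg.md_length_ps == 1.0
        assert cfg.temperature_K == 1000.0
        assert cfg.window_kcal == 15.0
        assert cfg.rmsd_cut_A == 0.50
        assert cfg.grad_tol == 0.01

    def test_torsion_k_outside_stated_range_rejected(self):
        with pytest.raises(ValueError):
            SamplingConfig(torsion_k=0.02)


class TestBackends:
    def test_mmff_gradient_matches_finite_differences(self):
        mol = embedded("CCO", 7)
        backend = MMFFBackend(mol)
        coords = np.array(mol.GetConformer().GetPositions())
        rng = np.random.default_rng(0)
        # check off the conformer geometry too, where caching bugs hide
        for x in (coords, coords + rng.normal(0, 0.1, coords.shape)):
            assert check_gradient(backend, x) < 1e-4

    def test_quadratic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(0, 1, (4, 3))
        backend = QuadraticBackend(ref, k=3.0)
        assert check_gradient(backend, ref + 0.5) < 1e-6


class TestRestrainedEnergy:
    @pytest.fixture
    def butene(self):
        return embedded("C/C=C/C", 5)

    def test_zero_penalty_at_ideal_geometry(self, butene):
        quads = double_bond_torsions(butene)
        coords = np.array(butene.GetConformer().GetPositions())
        ideals = ideal_torsions(butene, coords, quads)
        assert torsion_penalty(coords, quads, ideals, k=0.01) == 0.0

    @pytest.mark.parametrize("deviation,expected", [(55.0, 1.0), (45.0, 0.0), (30.0, 0.0)])
    def test_penalty_hand_values(self, butene, deviation, expected):
        # k * (|dtau| - 45)^2 beyond the threshold, strict at the boundary
        quads = double_bond_torsions(butene)
        assert len(quads) == 1
        a, i, j, b = quads[0]
        coords = np.array(butene.GetConformer().GetPositions())
        ideals = ideal_torsions(butene, coords, quads)
        rdMolTransforms.SetDihedralDeg(butene.GetConformer(), a, i, j, b,
                                       ideals[0] + deviation)
        twisted = np.array(butene.GetConformer().GetPositions())
        assert torsion_penalty(twisted, quads, ideals, k=0.01) == pytest.approx(expected, abs=1e-6)

    def test_restrained_equals_backend_plus_penalty(self, butene):
        backend = MMFFBackend(butene)
        cfg = SamplingConfig(torsion_k=0.01)
        coords = np.array(butene.GetConformer().GetPositions())
        assert restrained_energy(coords, butene, backend, cfg) == pytest.approx(
            backend.energy(coords), abs=1e-9)


class TestEnergyWindow:
    @pytest.mark.parametrize("energies,window,n_kept", [
        ([-100.0, -92.0, -85.1], 15.0, 3),   # -85.1 is 14.9 above the minimum
        ([-100.0, -92.0, -84.9], 15.0, 2),
        ([3.0], 0.001, 1),                    # minimum always kept
        ([1.0, 1.0, 1.0], 15.0, 3),
    ])
    def test_window_rule(self, methane, energies, window, n_kept):
        rng = np.random.default_rng(0)
        ens = ConformerEnsemble(methane, [
            Conformer(rng.normal(size=(methane.GetNumAtoms(), 3)), e) for e in energies])
        kept = filter_energy_window(ens, window)
        assert len(kept) == n_kept
        assert kept.e_min == min(energies)

    def test_empty_ensemble_is_an_error(self, methane):
        with pytest.raises(ValueError):
            filter_energy_window(ConformerEnsemble(methane, []), 15.0)


class TestKabschRmsd:
    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 2, (6, 3))
        rot = Rotation.from_rotvec([0.3, 1.2, -0.5]).as_matrix()
        b = a @ rot.T + np.array([5.0, -1.0, 2.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.normal(0, 1, (2, 7, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-9)

    def test_matches_numerical_minimization_oracle(self):
        # 4-atom rigid frame with one displaced atom: brute-force over
        # rotations with scipy, independent of the Kabsch route
        from scipy.optimize import minimize

        a = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        b = a.copy()
        b[3, 2] += 1.0

        def rmsd_at(rv):
            rot = Rotation.from_rotvec(rv).as_matrix()
            bb = (b - b.mean(0)) @ rot.T
            aa = a - a.mean(0)
            return np.sqrt(np.mean(np.sum((aa - bb) ** 2, axis=1)))

        best = min(
            minimize(rmsd_at, x0, method="Nelder-Mead").fun
            for x0 in ([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1])
        )
        assert kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-4)

    def test_invariant_to_pre_rotation_of_either_input(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, (2, 6, 3))
        base = kabsch_rmsd(a, b)
        rot = Rotation.random(random_state=9).as_matrix()
        assert kabsch_rmsd(a @ rot.T, b) == pytest.approx(base, abs=1e-9)
        assert kabsch_rmsd(a, b @ rot.T) == pytest.approx(base, abs=1e-9)

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDeduplicate:
    def test_identical_geometries_keep_only_minimum(self, methane):
        coords = np.random.default_rng(0).normal(size=(methane.GetNumAtoms(), 3))
        ens = ConformerEnsemble(methane, [Conformer(coords, e) for e in (0.0, 1.0, 2.0)])
        kept = deduplicate_rmsd(ens, 0.5)
        assert len(kept) == 1
        assert kept.conformers[0].energy == 0.0

    def test_close_pair_plus_distant_third(self):
        mol = embedded("CCO", 2)
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        rng = np.random.default_rng(1)
        base = rng.normal(0, 2, (mol.GetNumAtoms(), 3))
        near = base.copy()
        near[heavy[0]] += np.array([0.4, 0.3, 0.2])
        far = base.copy()
        far[heavy] += rng.normal(0, 3, (len(heavy), 3))
        d01 = kabsch_rmsd(base, near, heavy)
        d02 = kabsch_rmsd(base, far, heavy)
        d12 = kabsch_rmsd(near, far, heavy)
        assert d01 < 0.5 and d02 > 0.5 and d12 > 0.5
        ens = ConformerEnsemble(mol, [
            Conformer(base, 0.0), Conformer(near, 1.0), Conformer(far, 2.0)])
        kept = deduplicate_rmsd(ens, 0.5)
        # brute force: among all subsets that are pairwise >= 0.5 apart and
        # cannot be extended downward in energy, greedy picks {base, far}
        assert [c.energy for c in kept.conformers] == [0.0, 2.0]

    def test_all_separated_is_noop(self):
        mol = embedded("CC", 2)
        rng = np.random.default_rng(2)
        ens = random_ensemble(mol, 5, rng, coord_scale=8.0)
        heavy = ens.heavy_atom_indices()
        pairwise_ok = all(
            kabsch_rmsd(a.coords, b.coords, heavy) >= 0.5
            for i, a in enumerate(ens.conformers) for b in ens.conformers[i + 1:])
        assert pairwise_ok
        kept = deduplicate_rmsd(ens, 0.5)
        assert [c.energy for c in kept.conformers] == [c.energy for c in ens.conformers]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_monotonicity_and_idempotence(self, seed):
        mol = Chem.AddHs(Chem.MolFromSmiles("CC"))
        rng = np.random.default_rng(seed)
        ens = random_ensemble(mol, 8, rng, coord_scale=0.8)
        loose = deduplicate_rmsd(ens, 0.3)
        tight = deduplicate_rmsd(ens, 0.9)
        assert len(tight) <= len(loose)  # non-increasing in the cutoff
        twice = deduplicate_rmsd(loose, 0.3)
        assert [c.energy for c in twice.conformers] == [c.energy for c in loose.conformers]
        narrow = filter_energy_window(ens, 2.0)
        wide = filter_energy_window(ens, 8.0)
        assert len(narrow) <= len(wide)  # non-decreasing in the window
        again = filter_energy_window(narrow, 2.0)
        assert len(again) == len(narrow)


class TestSampling:
    def test_single_basin_system_converges_to_one_energy(self, methane):
        coords = np.array(methane.GetConformer().GetPositions())
        backend = QuadraticBackend(coords, k=8.0)
        cfg = SamplingConfig(iterations=30, md_length_ps=0.05, seed=11)
        ens = sample_ensemble(methane, cfg, backend)
        assert len(ens) == 30
        assert np.ptp(ens.energies) < 1e-3

    def test_butane_finds_multiple_torsion_basins(self):
        mol = embedded("CCCC", 3)
        cfg = SamplingConfig(iterations=60, md_length_ps=0.1, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = sample_ensemble(mol, cfg)
        basins = {
            round(_dihedral_deg(*[c.coords[i] for i in (0, 1, 2, 3)]) / 120) % 3
            for c in ens.conformers
        }
        assert len(basins) >= 2

    def test_same_seed_reproduces_energy_list(self):
        mol = embedded("CCO", 7)
        cfg = SamplingConfig(iterations=15, md_length_ps=0.05, seed=42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = sample_ensemble(mol, cfg).energies
            e2 = sample_ensemble(mol, cfg).energies
        assert np.array_equal(e1, e2)

    def test_requires_initial_geometry(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        with pytest.raises(ValueError, match="3D"):
            sample_ensemble(mol, SamplingConfig(iterations=2))


class TestSdfRoundTrip:
    def test_lossless(self, tmp_path):
        ens = embed_ensemble(Chem.MolFromSmiles("OCCCO"), n_confs=3, seed=1)
        path = tmp_path / "ens.sdf"
        write_ensemble_sdf(ens, path)
        back = read_ensemble_sdf(path)
        assert len(back) == len(ens)
        assert np.allclose(back.energies, ens.energies)
        for c1, c2 in zip(ens.conformers, back.conformers):
            assert np.allclose(c1.coords, c2.coords, atol=1e-4)


class TestPruneEnsemble:
    def test_filter_then_dedup_composition(self, methane):
        rng = np.random.default_rng(7)
        ens = random_ensemble(methane, 10, rng)
        combined = prune_ensemble(ens, window=5.0, rmsd_cut=0.5)
        manual = deduplicate_rmsd(filter_energy_window(ens, 5.0), 0.5)
        assert [c.energy for c in combined.conformers] == [c.energy for c in manual.conformers]
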