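# tsnap

**Targeted sampling of natural-product space** for macrolide library
design: build a virtual combinatorial library of tetrahydrofuran-
containing polyketide macrolides (THF pMLs) from fragment building
blocks, generate and prune conformer ensembles, score every compound's
3D shape and pharmacophore similarity to a natural-product reference
panel, and prioritize candidates for synthesis — plus the statistics
used to call activity in the downstream assays (morphological-profiling
activity scores, MIC from growth curves, MTT viability).

The package is aimed at computational chemists designing
natural-product-inspired libraries: the combinatorics and stereo
enumeration, the conformational filtering rules, the similarity
statistic and the selection rule are exactly specified and unit-tested,
while the chemistry-facing steps (SMILES/SDF handling, MMFF94, distance-
geometry embedding, Crippen logP) ride on RDKit.

## The core statistic

Fragment triples (tetrahydrofuranol × enoic acid × side chain) are
assembled into macrolactones and expanded over E/Z ring-closing-olefin
geometry and R/S carbinol configuration, so `n₁ × n₂ × n₃` triples give
`4·n₁n₂n₃` compounds.  Each compound's conformers within 15 kcal/mol of
its global minimum (deduplicated at 0.50 Å heavy-atom RMSD) are overlaid
against each reference conformer, scoring

    combo = shape Tanimoto + colour Tanimoto            ∈ [0, 2]
    shape Tanimoto = V_AB / (V_AA + V_BB − V_AB)

with first-order Gaussian overlap volumes V.  For one reference,

    C_s = mean over reference conformers of (best combo match) / 2   ∈ [0, 1]

and C_s^max, the best score across the reference panel, drives
selection: a candidate group (the six compounds sharing one macrocycle
backbone — three side chains × two carbinol epimers) is prioritized for
synthesis when any member has C_s^max in [0.55, 0.70] — similar enough
to be natural-product-like, not so similar as to replicate the panel.

## Worked example

```bash
python examples/enumerate_library.py
```

```
7 building blocks:
  THF1  thf        [*:1]OC(C=O)C1CCC(O1)C=[*:2]
  ...
enumerated 48 compounds (0 combinations skipped)
first four (one fragment triple, four stereo variants):
  THF1.MC1.SC1.ER        NC(=O)C[C@@H](O)C1OC(=O)CCCC/C=C/C2CCC1O2
  THF1.MC1.SC1.ES        NC(=O)C[C@H](O)C1OC(=O)CCCC/C=C/C2CCC1O2
  THF1.MC1.SC1.ZR        NC(=O)C[C@@H](O)C1OC(=O)CCCC/C=C\C2CCC1O2
  THF1.MC1.SC1.ZS        NC(=O)C[C@H](O)C1OC(=O)CCCC/C=C\C2CCC1O2
12 candidate groups (same macrocycle backbone), sizes [4]
```

Each line is one virtual compound: the id records the fragment triple
and stereo variant, and the SMILES shows the assembled macrolactone with
controlled olefin geometry (`/C=C/` vs `/C=C\`) and carbinol
configuration (`@` vs `@@`).  With three side chains the groups reach
their canonical size of six.

The other examples follow the same pattern, each printing what it
computes and what the numbers mean:

| script | capability |
| --- | --- |
| `examples/enumerate_library.py` | fragment loading, assembly, stereo enumeration, grouping |
| `examples/conformer_sampling.py` | heat/minimize sampling chain, energy window, RMSD dedup |
| `examples/shape_similarity.py` | Gaussian shape + colour overlay, combo scores, C_s profile |
| `examples/prioritize_targets.py` | C_s^max band selection, coverage report |
| `examples/assay_statistics.py` | activity calls, MIC reading, viability normalization |
| `examples/macrocycle_descriptors.py` | backbone/substituent partition, descriptor axes |

A thin CLI mirrors the pipeline for shell use
(`tsnap enumerate | conformers | score | prioritize | descriptors | fixtures`).

## Layout

```
src/tsnap/        blocks, conformers, forcefield, shape, color, overlay,
                  scoring, prioritize, assays, descriptors, fixtures, cli
tests/            unit + property tests per module, acceptance suite
examples/         one narrative script per capability
docs/methods.md   models, parameters, numerical choices, limitations
```
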