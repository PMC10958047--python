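"""Deterministic toy inputs for every pipeline stage.

Real fragment sets and reference natural products for this compound
class are not machine-readable, so the package ships generators that
emulate their *structure*: chemically valid toy fragments with the
correct attachment-point chemistry per role, macrocycle-like reference
ensembles (optionally with a planted twin of a library compound, giving
ground truth for similarity-recovery tests), and synthetic assay plates
with planted actives and MIC steps.

Toy fragments are deliberately small (<= 12 heavy atoms) so that full
pipelines — enumerate, embed conformers, score, prioritize — run in
minutes.  All outputs are seed-deterministic: the same spec regenerates
byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from tsnap.assays import dilution_series
from tsnap.blocks import (
    BuildingBlock,
    StereoVariant,
    assemble_compound,
    validate_block,
)
from tsnap.conformers import ConformerEnsemble, embed_ensemble


@dataclass(frozen=True)
class FixtureSpec:
    """One knob set for all toy generators; same spec => identical outputs."""

    seed: int = 0
    n_thf: int = 2
    n_enoate: int = 3
    n_side: int = 2
    n_references: int = 6
    planted_reference: tuple[str, str, str, str, str] | None = None
    # (thf_id, enoate_id, side_id, alkene_geometry, carbinol_config)
    ref_conf_range: tuple[int, int] = (1, 3)
    # assay plates
    n_features: int = 20
    effect_size: float = 10.0
    planted_mic_step: int = 7
    n_assay_compounds: int = 4
    n_negative_wells: int = 16
    n_replicates: int = 3


# --- fragment template pools -------------------------------------------------
# The macrolactone ester oxygen carries class 1, the ring-closing olefin
# terminus class 2; the thf aldehyde is the future carbinol site.

def _thf_templates() -> list[str]:
    out = []
    for link in ("", "C"):
        for deco in ("C1CCC(O1)C", "C1CC(C)C(O1)C", "C1C(C)CC(O1)C",
                     "C1CCC(O1)C(C)" if link == "" else "C1CCC(O1)C"):
            out.append(f"[*:1]OC(C=O){link}{deco}=[*:2]")
    out.append("[*:1]OC(C=O)C(C)C1CCC(O1)C=[*:2]")
    out.append("[*:1]OC(C=O)CC(C)C1CCC(O1)C=[*:2]")
    return out


def _enoate_templates() -> list[str]:
    decos = [None, ("C", 0), ("C", 1), ("C", 2), ("O", 0), ("O", 1), ("O", 2), ("F", 1)]
    out = []
    # chains of >= 4 methylenes keep the assembled macrolactone at >= 12 atoms
    for chain in (4, 5, 6, 7):
        for deco in decos:
            body = ""
            for pos in range(chain):
                if deco is not None and pos == deco[1]:
                    body += f"C({deco[0]})"
                else:
                    body += "C"
            out.append(f"[*:1]C(=O){body}C=[*:2]")
    return out


#: reference-only enoates: never drawn by :func:`toy_building_blocks`, so
#: unplanted references are guaranteed to differ from every library member.
_REF_ENOATES = [
    "[*:1]C(=O)CCCCCCC=[*:2]",
    "[*:1]C(=O)C(Cl)CCCC=[*:2]",
    "[*:1]C(=O)CC(Cl)CCC=[*:2]",
    "[*:1]C(=O)C(C)(C)CCC=[*:2]",
    "[*:1]C(=O)CCC(C)(C)CC=[*:2]",
    "[*:1]C(=O)C(Cl)CCCCC=[*:2]",
]

_SIDE_TEMPLATES = [
    "[*:3]CC(N)=O",        # amide-like
    "[*:3]Cc1cscn1",       # thiazole-like
    "[*:3]C1CCOCC1",       # pyran-like
    "[*:3]CC(=O)NC",
    "[*:3]Cc1ccco1",
    "[*:3]CCO",
]


def _unique_fragments(templates: list[str], n: int, role: str,
                      prefix: str) -> list[BuildingBlock]:
    blocks, seen = [], set()
    for smi in templates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        block = BuildingBlock(id=f"{prefix}{len(blocks) + 1}", role=role, smiles=smi)
        validate_block(block)
        blocks.append(block)
        if len(blocks) == n:
            return blocks
    raise ValueError(f"template pool exhausted: only {len(blocks)} distinct "
                     f"{role} fragments available, {n} requested")


def toy_building_blocks(spec: FixtureSpec) -> list[BuildingBlock]:
    """Chemically valid toy fragment set sized per the spec (file order stable)."""
    for name in ("n_thf", "n_enoate", "n_side"):
        if getattr(spec, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    thfs = _unique_fragments(_thf_templates(), spec.n_thf, "thf", "THF")
    enoates = _unique_fragments(_enoate_templates(), spec.n_enoate, "enoate", "MC")
    sides = _unique_fragments(_SIDE_TEMPLATES, spec.n_side, "sidechain", "SC")
    return thfs + enoates + sides


def write_blocks_csv(blocks: list[BuildingBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "role", "smiles"])
        for b in blocks:
            w.writerow([b.id, b.role, b.smiles])


def toy_reference_set(spec: FixtureSpec) -> dict[str, ConformerEnsemble]:
    """Macrocycle-like reference ensembles with 1-5 conformers each.

    References are assembled from reference-only enoate fragments, so no
    library compound coincides with them — unless ``planted_reference``
    names a library fragment triple, in which case that exact compound
    (with the conformers the library-side seed convention reproduces) is
    duplicated into the reference set under the id ``REF_PLANT``, giving
    ground truth for similarity-recovery tests.
    """
    blocks = toy_building_blocks(spec)
    by_id = {b.id: b for b in blocks}
    thfs = [b for b in blocks if b.role == "thf"]
    sides = [b for b in blocks if b.role == "sidechain"]
    ref_enoates = [BuildingBlock(id=f"REFMC{i + 1}", role="enoate", smiles=s)
                   for i, s in enumerate(_REF_ENOATES)]

    lo, hi = spec.ref_conf_range
    refs: dict[str, ConformerEnsemble] = {}
    i = 0
    while len(refs) < spec.n_references:
        thf = thfs[i % len(thfs)]
        eno = ref_enoates[i % len(ref_enoates)]
        side = sides[(i // len(ref_enoates)) % len(sides)]
        stereo = StereoVariant("E" if i % 2 == 0 else "Z", "R" if i % 4 < 2 else "S")
        compound = assemble_compound(thf, eno, side, stereo)
        n_confs = lo + i % (hi - lo + 1)
        ref_id = f"REF{len(refs) + 1}"
        refs[ref_id] = embed_ensemble(compound.mol, n_confs=n_confs,
                                      seed=spec.seed * 1000 + i)
        i += 1

    if spec.planted_reference is not None:
        thf_id, eno_id, side_id, geom, chir = spec.planted_reference
        compound = assemble_compound(by_id[thf_id], by_id[eno_id], by_id[side_id],
                                     StereoVariant(geom, chir))
        # the plant reuses the spec seed (the library-side conformer seed
        # convention), so the designated compound's own ensemble is
        # reproduced exactly: recovery ground truth by construction
        refs["REF_PLANT"] = embed_ensemble(compound.mol, n_confs=hi, seed=spec.seed)
    return refs


# --- synthetic assay plates --------------------------------------------------


def synth_assay_plates(spec: FixtureSpec) -> dict:
    """Fingerprint, growth and MTT tables with a ground-truth sidecar.

    * fingerprints: negative-control wells drawn from a unit-scale null;
      planted actives have their features scaled by ``effect_size`` at and
      above the planted activation concentration.
    * growth: 16-point two-fold series from 128 uM; planted MIC at
      ``planted_mic_step`` (0-based index into the descending series) for
      the active compounds, no inhibition for the rest.
    * mtt: background, DMSO-control and treatment absorbances with known
      planted viability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
    series = dilution_series(128.0, 16, 2.0)
    concs = series.concentrations_uM
    half = spec.n_assay_compounds // 2
    compounds = [f"CPD{i + 1}" for i in range(spec.n_assay_compounds)]
    active = set(compounds[:half])
    activation_step = max(0, min(spec.planted_mic_step, len(concs) - 1))

    # fingerprints ---------------------------------------------------------
    fp_rows = []
    feat_cols = [f"f{j}" for j in range(spec.n_features)]
    for _ in range(spec.n_negative_wells):
        row = dict(zip(feat_cols, rng.normal(0, 1, spec.n_features)))
        row.update(compound="DMSO", concentration_uM=0.0, is_negative_control=True)
        fp_rows.append(row)
    for cpd in compounds:
        for k, conc in enumerate(concs):
            for _ in range(spec.n_replicates):
                feats = rng.normal(0, 1, spec.n_features)
                if cpd in active and k <= activation_step:
                    feats = feats * spec.effect_size
                row = dict(zip(feat_cols, feats))
                row.update(compound=cpd, concentration_uM=conc,
                           is_negative_control=False)
                fp_rows.append(row)
    fingerprints = pd.DataFrame(fp_rows)

    # growth curves --------------------------------------------------------
    gr_rows = []
    vehicle_growth = 0.5
    for cpd in compounds:
        for _ in range(2):
            t0 = 0.05 + rng.normal(0, 0.002)
            gr_rows.append(dict(compound=cpd, role="vehicle", concentration_uM=0.0,
                                od600_t0=t0, od600_t20=t0 + vehicle_growth + rng.normal(0, 0.01)))
            t0 = 0.04 + rng.normal(0, 0.002)
            gr_rows.append(dict(compound=cpd, role="blank", concentration_uM=0.0,
                                od600_t0=t0, od600_t20=t0 + rng.normal(0, 0.002)))
        for k, conc in enumerate(concs):
            t0 = 0.05 + rng.normal(0, 0.002)
            if cpd in active and k <= spec.planted_mic_step:
                growth = 0.02 * vehicle_growth  # ~98 % inhibition
            else:
                growth = vehicle_growth * (1.0 + rng.normal(0, 0.02))
            gr_rows.append(dict(compound=cpd, role="treatment", concentration_uM=conc,
                                od600_t0=t0, od600_t20=t0 + growth + rng.normal(0, 0.005)))
    growth = pd.DataFrame(gr_rows)

    # MTT ------------------------------------------------------------------
    mtt_rows = []
    background, dmso_level = 0.10, 0.90
    for _ in range(8):
        mtt_rows.append(dict(compound="MTT_ONLY", role="mtt_only", concentration_uM=0.0,
                             absorbance=background + rng.normal(0, 0.005)))
    for _ in range(16):
        mtt_rows.append(dict(compound="DMSO", role="vehicle", concentration_uM=0.0,
                             absorbance=dmso_level + rng.normal(0, 0.01)))
    planted_viability = {}
    for i, cpd in enumerate(compounds):
        viability = 0.15 if cpd in active else 0.95
        planted_viability[cpd] = viability * 100.0
        for conc in concs[:4]:
            a = background + viability * (dmso_level - background) + rng.normal(0, 0.004)
            mtt_rows.append(dict(compound=cpd, role="treatment",
                                 concentration_uM=conc, absorbance=a))
    mtt = pd.DataFrame(mtt_rows)

    truth = {
        "active_compounds": sorted(active),
        "min_active_concentration_uM": {c: float(concs[activation_step]) for c in active},
        "mic_uM": {c: (float(concs[spec.planted_mic_step]) if c in active else None)
                    for c in compounds},
        "planted_viability_pct": planted_viability,
    }
    return {"fingerprints": fingerprints, "growth": growth, "mtt": mtt, "truth": truth}


def write_assay_plates(plates: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("fingerprints", "growth", "mtt"):
        plates[name].to_csv(out / f"{name}.csv", index=False)
    import json

    with open(out / "truth.json", "w") as fh:
        json.dump(plates["truth"], fh, indent=1)
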