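"""Fragment building blocks and combinatorial macrolide enumeration.

The virtual library is assembled from three fragment roles:

* ``thf`` — a tetrahydrofuranol fragment carrying the macrolactone ester
  oxygen (attachment class 1), one olefin terminus of the ring-closing
  junction (attachment class 2) and exactly one aldehyde group, which
  becomes the hydroxymethine (carbinol) stereocenter when the side chain
  is attached.
* ``enoate`` — a polyketide-like enoic acid fragment carrying the acyl
  carbon of the ester junction (class 1) and the second olefin terminus
  (class 2).
* ``sidechain`` — a monovalent fragment whose single attachment (class 3)
  bonds to the carbinol carbon.

Attachment points are encoded as numbered dummy atoms in SMILES
(``[*:1]`` ester junction, ``[*:2]`` olefin junction, ``[*:3]`` carbinol
junction).  Joining a thf and an enoate closes the macrolactone: a single
(ester) bond between the class-1 neighbours and a double bond with
controlled E/Z geometry between the class-2 neighbours.  The side chain
is then attached by converting the thf aldehyde ``-CH=O`` into a carbinol
``-CH(OH)-`` bonded to the side chain, with controlled R/S configuration.

Every fragment triple is expanded into the four stereochemical variants
(E/Z at the new olefin, R/S at the new carbinol), so a library of
``n_thf x n_enoate x n_side`` triples enumerates to four times as many
virtual compounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdMolDescriptors

ROLES = ("thf", "enoate", "sidechain")

ESTER_JUNCTION = 1
OLEFIN_JUNCTION = 2
CARBINOL_JUNCTION = 3

_ALDEHYDE = Chem.MolFromSmarts("[CX3H1]=[OX1]")


class BlockError(ValueError):
    """A building-block definition violates its role contract."""


class AssemblyError(ValueError):
    """Two fragments cannot be joined at their declared attachment points."""


@dataclass(frozen=True)
class BuildingBlock:
    """An annotated fragment: role, structure, and attachment points."""

    id: str
    role: str
    smiles: str
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise BlockError(f"block {self.id!r}: unparsable smiles {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class StereoVariant:
    """One of the four enumerated stereochemistry choices per triple."""

    alkene_geometry: str  # "E" or "Z" at the ring-closing olefin
    carbinol_config: str  # "R" or "S" at the side-chain carbinol

    def __post_init__(self):
        if self.alkene_geometry not in ("E", "Z"):
            raise ValueError(f"alkene_geometry must be E or Z, got {self.alkene_geometry!r}")
        if self.carbinol_config not in ("R", "S"):
            raise ValueError(f"carbinol_config must be R or S, got {self.carbinol_config!r}")

    @property
    def label(self) -> str:
        return self.alkene_geometry + self.carbinol_config


STEREO_VARIANTS = tuple(
    StereoVariant(g, c) for g in ("E", "Z") for c in ("R", "S")
)


@dataclass(frozen=True)
class VirtualCompound:
    """An assembled library member with a deterministic composite id."""

    id: str
    smiles: str
    thf_id: str
    enoate_id: str
    sidechain_id: str
    stereo: StereoVariant

    @property
    def backbone_key(self) -> tuple[str, str, str]:
        """Macrocycle identity: invariant to side chain and carbinol epimer."""
        return (self.thf_id, self.enoate_id, self.stereo.alkene_geometry)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class SkippedCombination:
    thf_id: str
    enoate_id: str
    sidechain_id: str
    stereo: StereoVariant
    reason: str


@dataclass
class LibraryManifest:
    """The enumerated library plus a log of combinations that failed assembly."""

    compounds: list[VirtualCompound]
    skipped: list[SkippedCombination] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.compounds)

    def write(self, smi_path: str | Path, csv_path: str | Path | None = None) -> None:
        smi_path = Path(smi_path)
        with open(smi_path, "w") as fh:
            for c in self.compounds:
                fh.write(f"{c.smiles}\t{c.id}\n")
        if csv_path is None:
            csv_path = smi_path.with_suffix(".csv")
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "thf_id", "enoate_id", "sidechain_id",
                        "alkene_geometry", "carbinol_config", "backbone_key"])
            for c in self.compounds:
                w.writerow([c.id, c.smiles, c.thf_id, c.enoate_id, c.sidechain_id,
                            c.stereo.alkene_geometry, c.stereo.carbinol_config,
                            "|".join(c.backbone_key)])

    def write_skipped(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["thf_id", "enoate_id", "sidechain_id", "stereo", "reason"])
            for s in self.skipped:
                w.writerow([s.thf_id, s.enoate_id, s.sidechain_id, s.stereo.label, s.reason])


def _attachment_map_classes(mol: Chem.Mol) -> list[int]:
    return sorted(a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def validate_block(block: BuildingBlock) -> None:
    """Check the attachment-point contract for the block's role."""
    if block.role not in ROLES:
        raise BlockError(f"block {block.id!r}: unknown role {block.role!r}")
    mol = Chem.MolFromSmiles(block.smiles)
    if mol is None:
        raise BlockError(f"block {block.id!r}: unparsable smiles {block.smiles!r}")
    classes = _attachment_map_classes(mol)
    if not classes:
        raise BlockError(f"block {block.id!r}: missing attachment point")
    if block.role == "sidechain":
        if classes != [CARBINOL_JUNCTION]:
            raise BlockError(
                f"block {block.id!r}: sidechain must expose exactly one "
                f"class-{CARBINOL_JUNCTION} attachment point, found {classes}")
    else:
        if classes != [ESTER_JUNCTION, OLEFIN_JUNCTION]:
            raise BlockError(
                f"block {block.id!r}: {block.role} must expose exactly the "
                f"ester (class {ESTER_JUNCTION}) and olefin (class {OLEFIN_JUNCTION}) "
                f"attachment points, found {classes}")
        n_ald = len(mol.GetSubstructMatches(_ALDEHYDE))
        if block.role == "thf" and n_ald != 1:
            raise BlockError(
                f"block {block.id!r}: thf must carry exactly one aldehyde "
                f"(the future carbinol site), found {n_ald}")
        if block.role == "enoate" and n_ald != 0:
            raise BlockError(
                f"block {block.id!r}: enoate must not carry an aldehyde, found {n_ald}")


def load_building_blocks(path: str | Path, role_filter: str | None = None) -> list[BuildingBlock]:
    """Load blocks from a CSV (``id,role,smiles``) or SMILES (``smiles<TAB>id``) file.

    Row order is preserved.  Rows that violate the role contract raise a
    :class:`BlockError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[int, str, str, str]] = []
    if path.suffix.lower() in (".smi", ".smiles"):
        if role_filter is None:
            raise BlockError("SMILES files carry no role column; pass role_filter")
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BlockError(f"row {i}: expected 'smiles<TAB>id'")
                rows.append((i, parts[1], role_filter, parts[0]))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # header is line 1
                missing = {"id", "role", "smiles"} - set(k for k in row if row[k] is not None)
                if missing:
                    raise BlockError(f"row {i}: missing columns {sorted(missing)}")
                rows.append((i, row["id"].strip(), row["role"].strip(), row["smiles"].strip()))

    blocks: list[BuildingBlock] = []
    seen: set[str] = set()
    for lineno, bid, role, smiles in rows:
        if role_filter is not None and role != role_filter:
            continue
        if bid in seen:
            raise BlockError(f"row {lineno}: duplicate id {bid!r}")
        block = BuildingBlock(id=bid, role=role, smiles=smiles)
        try:
            validate_block(block)
        except BlockError as exc:
            raise BlockError(f"row {lineno}: {exc}") from None
        seen.add(bid)
        blocks.append(block)
    return blocks


def _set_alkene_geometry(mol: Chem.Mol, i: int, j: int, geometry: str) -> bool:
    """Force the i=j double bond to CIP label E or Z; True on success."""
    for flag in (Chem.BondStereo.STEREOTRANS, Chem.BondStereo.STEREOCIS):
        bond = mol.GetBondBetweenAtoms(i, j)
        bi, bj = bond.GetBeginAtom(), bond.GetEndAtom()
        ref_i = max((n.GetIdx() for n in bi.GetNeighbors() if n.GetIdx() != bj.GetIdx()),
                    default=None)
        ref_j = max((n.GetIdx() for n in bj.GetNeighbors() if n.GetIdx() != bi.GetIdx()),
                    default=None)
        if ref_i is None or ref_j is None:
            return False
        bond.SetStereoAtoms(ref_i, ref_j)
        bond.SetStereo(flag)
        rdCIPLabeler.AssignCIPLabels(mol)
        if mol.GetBondBetweenAtoms(i, j).GetPropsAsDict().get("_CIPCode") == geometry:
            return True
    mol.GetBondBetweenAtoms(i, j).SetStereo(Chem.BondStereo.STEREONONE)
    return False


def _set_carbinol_config(mol: Chem.Mol, idx: int, config: str) -> bool:
    """Force the tetrahedral centre at ``idx`` to CIP label R or S."""
    for tag in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW):
        mol.GetAtomWithIdx(idx).SetChiralTag(tag)
        rdCIPLabeler.AssignCIPLabels(mol)
        if mol.GetAtomWithIdx(idx).GetPropsAsDict().get("_CIPCode") == config:
            return True
    mol.GetAtomWithIdx(idx).SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    return False


def compound_id(thf: str, enoate: str, sidechain: str, stereo: StereoVariant) -> str:
    return f"{thf}.{enoate}.{sidechain}.{stereo.label}"


def assemble_compound(thf: BuildingBlock, enoate: BuildingBlock,
                      sidechain: BuildingBlock, stereo: StereoVariant) -> VirtualCompound:
    """Join one fragment triple into a macrolide with the requested stereochemistry.

    Raises :class:`AssemblyError` (naming the blocks involved) if the
    junction chemistry is incompatible or the requested stereo label is
    not attainable (non-stereogenic junction).
    """
    for block, role in ((thf, "thf"), (enoate, "enoate"), (sidechain, "sidechain")):
        if block.role != role:
            raise AssemblyError(f"block {block.id!r} has role {block.role!r}, expected {role!r}")
        validate_block(block)

    combo = Chem.RWMol(thf.mol)
    combo = Chem.RWMol(Chem.CombineMols(combo, enoate.mol))
    combo = Chem.RWMol(Chem.CombineMols(combo, sidechain.mol))

    dummies = []
    for atom in combo.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.GetNeighbors()[0].SetIntProp(f"jct{atom.GetAtomMapNum()}", 1)
            dummies.append(atom.GetIdx())
    for i in sorted(dummies, reverse=True):
        combo.RemoveAtom(i)
    ends = {
        cls: [a.GetIdx() for a in combo.GetAtoms() if a.HasProp(f"jct{cls}")]
        for cls in (ESTER_JUNCTION, OLEFIN_JUNCTION, CARBINOL_JUNCTION)
    }
    names = f"{thf.id!r} + {enoate.id!r}"
    if len(ends[ESTER_JUNCTION]) != 2 or len(ends[OLEFIN_JUNCTION]) != 2:
        raise AssemblyError(f"cannot close macrolactone between {names}: junction atoms missing")
    try:
        combo.AddBond(*ends[ESTER_JUNCTION], Chem.BondType.SINGLE)
        combo.AddBond(*ends[OLEFIN_JUNCTION], Chem.BondType.DOUBLE)
        # NHK-style carbinol formation: thf aldehyde CH=O -> CH(OH)(sidechain)
        matches = combo.GetMol().GetSubstructMatches(_ALDEHYDE)
        if len(matches) != 1:
            raise AssemblyError(
                f"expected one carbinol-precursor aldehyde in {names}, found {len(matches)}")
        c_carb, c_oxy = matches[0]
        combo.GetBondBetweenAtoms(c_carb, c_oxy).SetBondType(Chem.BondType.SINGLE)
        combo.GetAtomWithIdx(c_oxy).SetNumExplicitHs(1)
        combo.AddBond(c_carb, ends[CARBINOL_JUNCTION][0], Chem.BondType.SINGLE)
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
    except AssemblyError:
        raise
    except Exception as exc:  # RDKit raises bare RuntimeError/ValueError
        raise AssemblyError(
            f"incompatible attachment chemistry joining {names} + {sidechain.id!r}: {exc}"
        ) from exc

    i, j = ends[OLEFIN_JUNCTION]
    if not _set_alkene_geometry(mol, i, j, stereo.alkene_geometry):
        raise AssemblyError(
            f"ring-closing olefin of {names} is not stereogenic "
            f"(cannot realise {stereo.alkene_geometry})")
    if not _set_carbinol_config(mol, c_carb, stereo.carbinol_config):
        raise AssemblyError(
            f"carbinol centre of {names} + {sidechain.id!r} is not stereogenic "
            f"(cannot realise {stereo.carbinol_config})")

    # translate internal cis/trans stereo into bond directions so the
    # canonical smiles carries the olefin geometry
    Chem.SetDoubleBondNeighborDirections(mol)
    smiles = Chem.MolToSmiles(mol)
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - canonical smiles round-trips
        raise AssemblyError(f"assembled smiles does not round-trip: {smiles}")
    return VirtualCompound(
        id=compound_id(thf.id, enoate.id, sidechain.id, stereo),
        smiles=smiles,
        thf_id=thf.id,
        enoate_id=enoate.id,
        sidechain_id=sidechain.id,
        stereo=stereo,
    )


def enumerate_library(blocks: Iterable[BuildingBlock]) -> LibraryManifest:
    """Cartesian product over (thf, enoate, sidechain) x the 4 stereo variants.

    Invalid assemblies are recorded in ``manifest.skipped`` with a reason,
    never silently dropped, so
    ``len(compounds) + len(skipped) == n_thf * n_enoate * n_side * 4``.
    """
    by_role: dict[str, list[BuildingBlock]] = {r: [] for r in ROLES}
    for b in blocks:
        if b.role not in by_role:
            raise BlockError(f"block {b.id!r}: unknown role {b.role!r}")
        by_role[b.role].append(b)
    for role in ROLES:
        if not by_role[role]:
            raise BlockError(f"no building blocks with role {role!r}")

    compounds: list[VirtualCompound] = []
    skipped: list[SkippedCombination] = []
    for thf in by_role["thf"]:
        for enoate in by_role["enoate"]:
            for side in by_role["sidechain"]:
                for stereo in STEREO_VARIANTS:
                    try:
                        compounds.append(assemble_compound(thf, enoate, side, stereo))
                    except (AssemblyError, BlockError) as exc:
                        skipped.append(SkippedCombination(
                            thf.id, enoate.id, side.id, stereo, str(exc)))
    return LibraryManifest(compounds=compounds, skipped=skipped)


def group_key(compound: VirtualCompound) -> tuple[str, str, str]:
    """Candidate-group key: shared macrocycle backbone.

    Invariant to the side chain and the carbinol epimer, so a full library
    groups into sets of six (3 side chains x 2 epimers).
    """
    return compound.backbone_key


def molecular_formula(compound: VirtualCompound) -> str:
    return rdMolDescriptors.CalcMolFormula(compound.mol)


def load_manifest(csv_path: str | Path) -> LibraryManifest:
    """Read back a manifest written by :meth:`LibraryManifest.write`."""
    compounds = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            compounds.append(VirtualCompound(
                id=row["id"], smiles=row["smiles"],
                thf_id=row["thf_id"], enoate_id=row["enoate_id"],
                sidechain_id=row["sidechain_id"],
                stereo=StereoVariant(row["alkene_geometry"], row["carbinol_config"]),
            ))
    return LibraryManifest(compounds=compounds)
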