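"""Pharmacophore "color" features and their Gaussian overlap.

A documented, versioned substructure-pattern table types each conformer
into six feature classes (donor, acceptor, cation, anion, hydrophobe,
ring).  Features are spherical Gaussians (radius 1.0 A, same amplitude
convention as the shape model) and overlap is accumulated only between
features of the same type, mirroring the colour term of volumetric
similarity scoring.

Typing rules (v1, applied in this order):

1. **anion** — carboxylate / deprotonatable carboxylic acid
   (``C(=O)[O-,OH]``), plus any other formally negative atom.  Feature at
   the centroid of the matched oxygens.  Matched atoms are *claimed*:
   they are not additionally typed as donor/acceptor.
2. **cation** — formally positive atoms and protonatable aliphatic
   amines (primary/secondary/tertiary N not amide, not aromatic).
   Claimed likewise.
3. **donor** — unclaimed O-H or N-H.
4. **acceptor** — unclaimed neutral O, or neutral N with an available
   lone pair (not pyrrole-type, not amide N).
5. **ring** — centroid of every 5-7 membered SSSR ring.
6. **hydrophobe** — connected clusters of >= 3 aliphatic carbons having
   no heteroatom neighbours, feature at the cluster centroid; halogens
   bonded to carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from tsnap.shape import alpha_from_radius, gaussian_pair_overlap

COLOR_TABLE_VERSION = 1

FEATURE_TYPES = ("donor", "acceptor", "cation", "anion", "hydrophobe", "ring")

COLOR_RADIUS = 1.0  # A

# group patterns: matched atom sets become one feature at their centroid
_ANION_GROUPS = [
    Chem.MolFromSmarts("[CX3](=[OX1])[OX1-]"),      # carboxylate
    Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]"),     # deprotonatable acid
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX1-,OX2H1]"),  # sulfonate/sulfonic
]
_ANION_ATOM = Chem.MolFromSmarts("[-1,-2;!$([O-]C=O);!$([O-]S(=O)=O)]")
_CATION_ATOM = Chem.MolFromSmarts("[+1,+2;!$([N+](=O)[O-])]")
_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$(N~[!#6;!#1]);!$(NC=[O,S,N]);!$(Na);!$(N=*);!$(NC=C)]")
_DONOR = Chem.MolFromSmarts("[$([OX2;H1]),$([NX3;!H0]),$([nX3;H1])]")
_ACCEPTOR = Chem.MolFromSmarts(
    "[$([OX1;+0]),$([OX2;+0]),$([NX2;+0;!$(N=O)]),$([NX1;+0]),$([nX2;+0])]")
_HALOGEN = Chem.MolFromSmarts("[F,Cl,Br,I;$(*[#6])]")


@dataclass(frozen=True)
class ColorFeature:
    type: str
    center: np.ndarray  # (3,) A
    radius: float = COLOR_RADIUS

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class ColorModel:
    """The typed feature set of one conformer (possibly empty)."""

    features: tuple[ColorFeature, ...] = ()
    version: int = COLOR_TABLE_VERSION

    def __len__(self) -> int:
        return len(self.features)

    def by_type(self) -> dict[str, np.ndarray]:
        out: dict[str, list[np.ndarray]] = {}
        for f in self.features:
            out.setdefault(f.type, []).append(f.center)
        return {t: np.array(cs) for t, cs in out.items()}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ColorModel":
        rot = np.asarray(rotation)
        return ColorModel(tuple(
            ColorFeature(f.type, f.center @ rot.T + translation, f.radius)
            for f in self.features), self.version)


def _hydrophobe_clusters(mol: Chem.Mol) -> list[list[int]]:
    """Connected aliphatic-carbon clusters (>= 3 atoms, no heteroatom neighbours)."""
    eligible = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if any(n.GetAtomicNum() not in (1, 6) for n in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    clusters = []
    todo = set(eligible)
    while todo:
        seed = min(todo)
        stack, comp = [seed], []
        todo.discard(seed)
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in todo:
                    todo.discard(j)
                    stack.append(j)
        if len(comp) >= 3:
            clusters.append(sorted(comp))
    return clusters


def perceive_color_features(mol: Chem.Mol, coords: np.ndarray) -> ColorModel:
    """Apply the v1 typing table to one conformer."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError("coordinate array does not match molecule")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ValueError(f"unsanitizable molecule: {exc}") from exc

    features: list[ColorFeature] = []
    claimed: set[int] = set()

    for patt in _ANION_GROUPS:
        for match in mol.GetSubstructMatches(patt):
            oxy = [i for i in match if mol.GetAtomWithIdx(i).GetAtomicNum() == 8]
            if claimed.intersection(match):
                continue
            features.append(ColorFeature("anion", coords[oxy].mean(axis=0)))
            claimed.update(match)
    for (i,) in mol.GetSubstructMatches(_ANION_ATOM):
        if i not in claimed:
            features.append(ColorFeature("anion", coords[i]))
            claimed.add(i)

    for patt in (_CATION_ATOM, _AMINE):
        for (i,) in mol.GetSubstructMatches(patt):
            if i not in claimed:
                features.append(ColorFeature("cation", coords[i]))
                claimed.add(i)

    for (i,) in mol.GetSubstructMatches(_DONOR):
        if i not in claimed:
            features.append(ColorFeature("donor", coords[i]))
    for (i,) in mol.GetSubstructMatches(_ACCEPTOR):
        if i not in claimed:
            features.append(ColorFeature("acceptor", coords[i]))

    for ring in mol.GetRingInfo().AtomRings():
        if 5 <= len(ring) <= 7:
            features.append(ColorFeature("ring", coords[list(ring)].mean(axis=0)))

    for cluster in _hydrophobe_clusters(mol):
        features.append(ColorFeature("hydrophobe", coords[cluster].mean(axis=0)))
    for (i,) in mol.GetSubstructMatches(_HALOGEN):
        features.append(ColorFeature("hydrophobe", coords[i]))

    return ColorModel(tuple(features))


def color_overlap(color_a: ColorModel, color_b: ColorModel,
                  pose=None) -> tuple[float, float, float]:
    """(v_ab, v_aa, v_bb) Gaussian overlaps gated by feature type.

    Self-overlaps are evaluated at identity pose with the same pairwise
    formula, so identical models at identity pose give a colour Tanimoto
    of exactly 1.
    """
    if pose is not None:
        color_b = color_b.transformed(pose.rotation_matrix(), pose.translation)
    alpha = alpha_from_radius(COLOR_RADIUS)

    def typed(model: ColorModel) -> dict[str, np.ndarray]:
        return model.by_type()

    ta, tb = typed(color_a), typed(color_b)

    def cross(da: dict, db: dict) -> float:
        total = 0.0
        for t in set(da) & set(db):
            ca, cb = da[t], db[t]
            total += gaussian_pair_overlap(
                ca, np.full(len(ca), alpha), cb, np.full(len(cb), alpha))
        return total

    return cross(ta, tb), cross(ta, ta), cross(tb, tb)


def color_tanimoto(v_ab: float, v_aa: float, v_bb: float) -> float:
    denom = v_aa + v_bb - v_ab
    if denom <= 0:
        return 0.0
    return float(np.clip(v_ab / denom, 0.0, 1.0))
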