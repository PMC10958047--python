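"""The C_s conformational-similarity statistic.

For a query compound and one reference compound, every query conformer
is overlaid on every reference conformer and scored by the combined
shape + colour Tanimoto ("combo", range 0-2).  For each reference
conformer the best-matching query conformer is retained, and these top
matches are averaged over the reference's conformers.  Dividing by 2
normalizes the statistic to [0, 1] so that a compound scored against an
identical copy of itself approaches C_s = 1.  Scoring a query against a
reference panel yields one C_s per reference; the largest, C_s^max, is
the prioritization currency.

An optional symmetric mode averages the two aggregation directions
(reference-side and query-side maxima) before normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tsnap.color import perceive_color_features
from tsnap.conformers import ConformerEnsemble
from tsnap.overlay import optimize_overlay
from tsnap.shape import build_shape_model


@dataclass(frozen=True)
class PairMatrix:
    """Combo scores for all (query conformer, reference conformer) pairs."""

    entries: np.ndarray  # (n_query_conf, n_ref_conf), values in [0, 2]

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.size == 0:
            raise ValueError("pair matrix must be 2-D and non-empty")
        if e.min() < -1e-9 or e.max() > 2.0 + 1e-9:
            raise ValueError("combo scores must lie in [0, 2]")
        object.__setattr__(self, "entries", e)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class CsProfile:
    """Per-reference C_s vector for one query compound."""

    reference_ids: tuple[str, ...]
    scores: np.ndarray  # one C_s in [0, 1] per reference

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if len(s) != len(self.reference_ids):
            raise ValueError("one score per reference required")
        object.__setattr__(self, "scores", s)

    @property
    def cs_max(self) -> float:
        return float(self.scores.max())

    @property
    def best_ref(self) -> str:
        return self.reference_ids[int(self.scores.argmax())]


def _conformer_models(ensemble: ConformerEnsemble):
    mol = ensemble.mol
    return [(build_shape_model(mol, c.coords), perceive_color_features(mol, c.coords))
            for c in ensemble.conformers]


def pair_score_matrix(query: ConformerEnsemble, reference: ConformerEnsemble) -> PairMatrix:
    """Optimized-overlay combo score for every conformer pair."""
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("both ensembles must be non-empty")
    q_models = _conformer_models(query)
    r_models = _conformer_models(reference)
    entries = np.empty((len(q_models), len(r_models)))
    for i, (sq, cq) in enumerate(q_models):
        for j, (sr, cr) in enumerate(r_models):
            _, scores = optimize_overlay(sq, cq, sr, cr)
            entries[i, j] = min(scores.combo, 2.0)
    return PairMatrix(entries)


def cs_from_matrix(matrix: PairMatrix, symmetric: bool = False) -> float:
    """Aggregate a pair matrix into C_s in [0, 1].

    Default: per reference conformer (column) take the best query match,
    average over reference conformers, divide by 2.  Symmetric mode also
    averages the query-side maxima and takes the mean of both directions.
    """
    e = matrix.entries
    ref_side = float(e.max(axis=0).mean())
    if symmetric:
        query_side = float(e.max(axis=1).mean())
        return (ref_side + query_side) / 2.0 / 2.0
    return ref_side / 2.0


def cs_profile(query: ConformerEnsemble,
               references: dict[str, ConformerEnsemble] | list[tuple[str, ConformerEnsemble]],
               symmetric: bool = False) -> CsProfile:
    """One C_s per reference compound, in input order."""
    items = list(references.items()) if isinstance(references, dict) else list(references)
    if not items:
        raise ValueError("reference set must be non-empty")
    ids, scores = [], []
    for ref_id, ens in items:
        if len(ens) == 0:
            raise ValueError(f"reference {ref_id!r} has an empty ensemble")
        scores.append(cs_from_matrix(pair_score_matrix(query, ens), symmetric=symmetric))
        ids.append(ref_id)
    return CsProfile(tuple(ids), np.array(scores))
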