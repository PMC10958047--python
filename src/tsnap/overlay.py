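"""Rigid-body overlay optimization and combined shape/colour scoring.

The overlay places the reference (B) onto the query (A):

1. translate both to their Gaussian-weighted shape centroids;
2. align the principal axes of the volume-weighted inertia tensor;
3. enumerate the four proper axis flips (the orientation ambiguity of
   principal axes);
4. from each start, locally maximize the summed shape + colour overlap
   volume over the six rigid degrees of freedom with a derivative-free
   simplex search;
5. score the best pose: shape Tanimoto, colour Tanimoto and their sum
   ("combo", range 0-2).

The optimizer is deterministic: fixed starts, fixed iteration cap,
tolerance 1e-4 on the combined overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from tsnap.color import ColorModel, color_overlap, color_tanimoto
from tsnap.shape import ShapeModel, overlap_volume, shape_tanimoto


@dataclass(frozen=True)
class Pose:
    """Rigid placement x -> R x + t, rotation stored as a unit quaternion (x,y,z,w)."""

    quaternion: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("zero quaternion")
        object.__setattr__(self, "quaternion", q / norm)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3))

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        return cls(Rotation.from_matrix(rotation).as_quat(), translation)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.quaternion).as_matrix()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation_matrix().T + self.translation


@dataclass(frozen=True)
class OverlapScores:
    """Shape/colour Tanimoto pair for one posed conformer pair."""

    v_ab: float
    shape_tanimoto: float
    color_tanimoto: float
    warning: bool = False

    @property
    def combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto


def principal_axes(shape: ShapeModel) -> np.ndarray:
    """Proper rotation whose columns are volume-weighted principal axes."""
    w = shape.weights()
    c = shape.centroid()
    d = shape.centers - c
    cov = (d * w[:, None]).T @ d / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes

_FLIPS = [np.diag(s) for s in
          ((1.0, 1.0, 1.0), (1.0, -1.0, -1.0), (-1.0, 1.0, -1.0), (-1.0, -1.0, 1.0))]


def score_at_pose(shape_a: ShapeModel, color_a: ColorModel,
                  shape_b: ShapeModel, color_b: ColorModel,
                  pose: Pose, warning: bool = False) -> OverlapScores:
    v_ab = overlap_volume(shape_a, shape_b, pose)
    st = shape_tanimoto(v_ab, shape_a.self_volume, shape_b.self_volume)
    c_ab, c_aa, c_bb = color_overlap(color_a, color_b, pose)
    ct = color_tanimoto(c_ab, c_aa, c_bb)
    return OverlapScores(v_ab=v_ab, shape_tanimoto=st, color_tanimoto=ct, warning=warning)


def optimize_overlay(shape_a: ShapeModel, color_a: ColorModel,
                     shape_b: ShapeModel, color_b: ColorModel,
                     maxiter: int = 400, tol: float = 1e-4) -> tuple[Pose, OverlapScores]:
    """Best rigid placement of B onto A and the scores at that pose."""
    if len(shape_a) == 0 or len(shape_b) == 0:
        raise ValueError("both shapes must be non-empty")
    ca, cb = shape_a.centroid(), shape_b.centroid()
    axes_a, axes_b = principal_axes(shape_a), principal_axes(shape_b)

    # precompute flat arrays: the objective runs thousands of times
    from tsnap.color import COLOR_RADIUS
    from tsnap.shape import alpha_from_radius, gaussian_pair_overlap

    alpha_c = alpha_from_radius(COLOR_RADIUS)
    ta, tb = color_a.by_type(), color_b.by_type()
    color_pairs = [(ta[t], np.full(len(ta[t]), alpha_c),
                    tb[t], np.full(len(tb[t]), alpha_c))
                   for t in sorted(set(ta) & set(tb))]

    def objective_factory(r0: np.ndarray):
        def objective(x: np.ndarray) -> float:
            rot = Rotation.from_rotvec(x[:3]).as_matrix() @ r0
            t = ca + x[3:] - rot @ cb
            moved = shape_b.centers @ rot.T + t
            v = gaussian_pair_overlap(shape_a.centers, shape_a.alphas,
                                      moved, shape_b.alphas, shape_a.amplitude)
            for fa, aa, fb, ab in color_pairs:
                v += gaussian_pair_overlap(fa, aa, fb @ rot.T + t, ab)
            return -v
        return objective

    best = None
    n_failed = 0
    for flip in _FLIPS:
        r0 = axes_a @ flip @ axes_b.T
        obj = objective_factory(r0)
        try:
            res = _scipy_minimize(obj, np.zeros(6), method="Nelder-Mead",
                                  options={"maxiter": maxiter, "xatol": tol,
                                           "fatol": tol, "adaptive": False})
            x, fval = res.x, float(res.fun)
        except Exception:
            n_failed += 1
            x, fval = np.zeros(6), obj(np.zeros(6))
        # never return worse than the unoptimized start
        f0 = obj(np.zeros(6))
        if f0 < fval:
            x, fval = np.zeros(6), f0
        if best is None or fval < best[0]:
            best = (fval, x, r0)

    failed_all = n_failed == len(_FLIPS)
    if failed_all:
        warnings.warn("overlay optimizer failed on all starts; "
                      "returning best evaluated start")
    _, x, r0 = best
    # polish: restarting the simplex from the winner escapes degenerate
    # simplexes and tightens convergence across argument orderings
    obj = objective_factory(r0)
    try:
        res = _scipy_minimize(obj, x, method="Nelder-Mead",
                              options={"maxiter": maxiter, "xatol": tol, "fatol": tol})
        if float(res.fun) < best[0]:
            best = (float(res.fun), res.x, r0)
    except Exception:
        pass
    _, x, r0 = best
    rot = Rotation.from_rotvec(x[:3]).as_matrix() @ r0
    pose = Pose.from_matrix(rot, ca + x[3:] - rot @ cb)
    return pose, score_at_pose(shape_a, color_a, shape_b, color_b, pose,
                               warning=failed_all)
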