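"""Unit-cell geometry, reflection generation and centric/epsilon bookkeeping.

Everything downstream (structure factors, Wilson normalization, likelihood
sums) iterates over a Friedel-unique set of Miller indices with d-spacings,
centricity flags and intensity-multiplicity (epsilon) factors.  Coordinates
are fractional internally; orthogonal angstroms appear only at I/O
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "ReflectionSet",
    "d_spacing",
    "generate_reflections",
    "centric_and_epsilon",
    "symops_from_strings",
    "spacegroup_symops",
    "SPACE_GROUP_CLASSES",
]


class InvalidReflectionError(ValueError):
    """Raised for the (0,0,0) triple or other unusable Miller indices."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValueError("cell angles give a non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, A^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (A^-2)."""
        return np.linalg.inv(self.metric_tensor)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Columns are the cell basis vectors in a Cartesian frame (A).

        Standard PDB convention: a along x, b in the xy plane.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> Cartesian (A).  Accepts (..., 3) arrays."""
        return np.asarray(frac) @ self.orthogonalization_matrix.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        """Cartesian (A) -> fractional."""
        return np.asarray(orth) @ np.linalg.inv(self.orthogonalization_matrix).T

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def d_spacing(cell: UnitCell, hkl) -> float:
    """d-spacing (A) of a reflection from the reciprocal metric tensor.

    1/d^2 = h^T G* h.  Raises InvalidReflectionError for (0,0,0).
    """
    h = np.asarray(hkl, dtype=float)
    if h.shape[-1] != 3:
        raise ValueError("hkl must have three components")
    inv_d2 = np.einsum("...i,ij,...j->...", h, cell.reciprocal_metric_tensor, h)
    if np.any(inv_d2 <= 0):
        raise InvalidReflectionError("d-spacing undefined for the zero reflection")
    return 1.0 / np.sqrt(inv_d2)


# -- symmetry ---------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryOps:
    """Explicit symmetry operators acting on fractional coordinates.

    rotations: (n, 3, 3) integer matrices R; translations: (n, 3) fractional
    vectors t, with x' = R x + t.  Must contain the identity.
    """

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotations)
        tra = np.asarray(self.translations, dtype=float)
        if rot.ndim != 3 or rot.shape[1:] != (3, 3) or len(rot) == 0:
            raise ValueError("rotations must be a non-empty (n, 3, 3) array")
        if tra.shape != (len(rot), 3):
            raise ValueError("translations must be (n, 3)")
        dets = np.round(np.linalg.det(rot)).astype(int)
        if not np.all(np.abs(dets) == 1):
            raise ValueError("every rotation matrix must have determinant +/-1")
        if not any(np.array_equal(r, np.eye(3, dtype=rot.dtype)) for r in rot):
            raise ValueError("symmetry operators must include the identity")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "translations", tra)

    def __len__(self) -> int:
        return len(self.rotations)

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls(np.eye(3, dtype=int)[None], np.zeros((1, 3)))


def symops_from_strings(triplets) -> SymmetryOps:
    """Build operators from "x,y,z"-style triplet strings (gemmi parser)."""
    rots, trans = [], []
    for s in triplets:
        op = gemmi.Op(s)
        rots.append(np.array(op.rot, dtype=int) // op.DEN)
        trans.append(np.array(op.tran, dtype=float) / op.DEN)
    return SymmetryOps(np.array(rots), np.array(trans))


def spacegroup_symops(name: str) -> SymmetryOps:
    """Operators for a named space group (e.g. 'P 21 21 21', 'C 2').

    Backed by gemmi's space-group tables; only the rotation parts matter for
    centricity/epsilon, so centring translations are included as given.
    """
    sg = gemmi.SpaceGroup(name)
    return symops_from_strings(op.triplet() for op in sg.operations())


#: Polar/nonpolar classification used by the pose-significance thresholds.
SPACE_GROUP_CLASSES = {"P 1": "P1", "P 21": "polar", "C 2": "polar", "P 21 21 21": "nonpolar"}


def centric_and_epsilon(symops: SymmetryOps, hkl) -> tuple[bool, int]:
    """Centricity flag and epsilon factor of one reflection.

    Reflections transform as h' = R^T h under x' = R x + t.  centric iff some
    operator sends h to -h; epsilon = number of operators fixing h.
    """
    h = np.asarray(hkl, dtype=int)
    if not h.any():
        raise InvalidReflectionError("(0,0,0) has no centricity or epsilon")
    if len(symops) == 0:  # unreachable through the constructor; belt and braces
        raise ValueError("empty symmetry operator list")
    himg = np.einsum("nji,j->ni", symops.rotations, h)  # R^T h for each op
    centric = bool(np.any(np.all(himg == -h, axis=1)))
    epsilon = int(np.sum(np.all(himg == h, axis=1)))
    return centric, epsilon


# -- reflection sets --------------------------------------------------------


@dataclass
class ReflectionSet:
    """Friedel-unique Miller indices with d, centric and epsilon per reflection."""

    hkl: np.ndarray        # (n, 3) int
    d: np.ndarray          # (n,) A
    centric: np.ndarray    # (n,) bool
    epsilon: np.ndarray    # (n,) int >= 1
    dmin: float = 0.0
    cell: UnitCell | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.d = np.asarray(self.d, dtype=float)
        self.centric = np.asarray(self.centric, dtype=bool)
        self.epsilon = np.asarray(self.epsilon, dtype=int)
        n = len(self.hkl)
        if not (len(self.d) == len(self.centric) == len(self.epsilon) == n):
            raise ValueError("per-reflection arrays must be aligned")
        if n and not self.hkl.any(axis=1).all():
            raise InvalidReflectionError("(0,0,0) may not be stored")
        if np.any(self.epsilon < 1):
            raise ValueError("epsilon must be >= 1")

    def __len__(self) -> int:
        return len(self.hkl)

    def concat(self, other: "ReflectionSet") -> "ReflectionSet":
        return ReflectionSet(
            np.vstack([self.hkl, other.hkl]),
            np.concatenate([self.d, other.d]),
            np.concatenate([self.centric, other.centric]),
            np.concatenate([self.epsilon, other.epsilon]),
            dmin=min(self.dmin, other.dmin),
            cell=self.cell,
        )


def _friedel_positive(hkl: np.ndarray) -> np.ndarray:
    """True where hkl is the kept Friedel representative.

    Convention: h > 0, or (h = 0, k > 0), or (h = k = 0, l > 0).
    """
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))


def generate_reflections(cell: UnitCell, symops: SymmetryOps, dmin: float) -> ReflectionSet:
    """All Friedel-unique reflections with d >= dmin.

    Index bounds are rigorous: the index along axis i of a reciprocal vector
    of length s = 1/d is the dot product with the direct basis vector, hence
    |h_i| <= |a_i| / dmin.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    hmax = [int(math.floor(length / dmin)) for length in (cell.a, cell.b, cell.c)]
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[grid.any(axis=1)]
    grid = grid[_friedel_positive(grid)]
    if len(grid) == 0:
        return ReflectionSet(
            np.empty((0, 3), int), np.empty(0), np.empty(0, bool), np.empty(0, int),
            dmin=dmin, cell=cell,
        )
    gstar = cell.reciprocal_metric_tensor
    inv_d2 = np.einsum("ni,ij,nj->n", grid.astype(float), gstar, grid.astype(float))
    d = 1.0 / np.sqrt(inv_d2)
    keep = d >= dmin
    grid, d = grid[keep], d[keep]
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))
    grid, d = grid[order], d[order]
    cen = np.empty(len(grid), bool)
    eps = np.empty(len(grid), int)
    for i, h in enumerate(grid):
        cen[i], eps[i] = centric_and_epsilon(symops, h)
    return ReflectionSet(grid, d, cen, eps, dmin=dmin, cell=cell)
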