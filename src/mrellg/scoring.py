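"""Model-versus-target structural scores.

Least-squares (Kabsch) superposition and r.m.s.d., GDT_TS/GDT_HA with a
seed-and-extend superposition search, the longest-continuous-segment (LCS)
score, a configurable GDT/LCS combination in the LGA_S spirit, and helix
geometry (local axes, bending angles, inter-axis angles).

The GDT search here is a documented simplification of the full LGA
program: seed windows of 3/5/7 residues are superposed, inliers under each
cutoff are iteratively re-fitted, and the best per-cutoff fraction is kept.
Pairing is sequence-dependent (1:1 by residue index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Superposition",
    "ScoreReport",
    "superpose",
    "gdt",
    "lcs",
    "lga_s",
    "score_pair",
    "helix_axes",
    "HelixGeometry",
    "helix_axis",
    "inter_helix_angle",
    "GDT_TS_CUTOFFS",
    "GDT_HA_CUTOFFS",
]

GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class Superposition:
    """Proper rigid motion y ~ R x + t minimizing the r.m.s.d. of paired points."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class ScoreReport:
    rmsd: float
    gdt_ts: float
    gdt_ha: float
    lcs: float
    lga_s: float


def superpose(coords_a, coords_b, pairing=None) -> Superposition:
    """Least-squares superposition of b onto a (Kabsch, SVD).

    ``pairing`` is an optional (k, 2) list of (index_in_a, index_in_b)
    pairs; by default points pair 1:1 by position.  Needs >= 3 pairs with
    non-degenerate geometry.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        a, b = a[pairing[:, 0]], b[pairing[:, 1]]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need matched (n, 3) coordinate arrays")
    n = len(a)
    if n < 3:
        raise ValueError("need at least three pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    aa, bb = a - ca, b - cb
    h = bb.T @ aa
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    resid = aa - bb @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Superposition(rot, trans, rmsd, n)


# -- GDT --------------------------------------------------------------------


def _fraction_within(model_t: np.ndarray, target: np.ndarray, cutoff: float) -> float:
    dist = np.linalg.norm(model_t - target, axis=1)
    return float(np.mean(dist <= cutoff))


def gdt(coords_model, coords_target, superposition=None,
        cutoffs=GDT_TS_CUTOFFS, max_iter: int = 5) -> float:
    """GDT score (percent): mean over cutoffs of the maximal fraction of
    pairs within the cutoff over the searched superpositions.

    With ``superposition`` fixed (a Superposition), no search is performed
    and the score reduces to distance counting under that motion.
    """
    model = np.asarray(coords_model, dtype=float)
    target = np.asarray(coords_target, dtype=float)
    if model.shape != target.shape or len(model) == 0:
        raise ValueError("need equal-length, non-empty paired coordinate sets")
    cutoffs = tuple(float(c) for c in cutoffs)
    if superposition is not None:
        placed = superposition.apply(model)
        return 100.0 * float(np.mean([_fraction_within(placed, target, c) for c in cutoffs]))

    n = len(model)
    best = {c: 0.0 for c in cutoffs}

    def consider(sup: Superposition) -> None:
        placed = sup.apply(model)
        dist = np.linalg.norm(placed - target, axis=1)
        for c in cutoffs:
            frac = float(np.mean(dist <= c))
            if frac > best[c]:
                best[c] = frac
            # iterative extension: refit on the inliers of this cutoff
            inliers = np.flatnonzero(dist <= c)
            prev = -1
            it = 0
            while len(inliers) >= 3 and len(inliers) != prev and it < max_iter:
                prev = len(inliers)
                it += 1
                try:
                    sub = superpose(target[inliers], model[inliers])
                except ValueError:
                    break
                d2 = np.linalg.norm(sub.apply(model) - target, axis=1)
                frac = float(np.mean(d2 <= c))
                if frac > best[c]:
                    best[c] = frac
                inliers = np.flatnonzero(d2 <= c)

    if n >= 3:
        consider(superpose(target, model))
    for w in (3, 5, 7):
        if n < w:
            continue
        for start in range(0, n - w + 1):
            seg = slice(start, start + w)
            try:
                consider(superpose(target[seg], model[seg]))
            except ValueError:
                continue
    return 100.0 * float(np.mean([best[c] for c in cutoffs]))


def lcs(coords_model, coords_target, rmsd_cutoff: float) -> float:
    """Longest continuous segment fittable under the r.m.s.d. cutoff, as a
    percentage of the chain length (exhaustive window search)."""
    model = np.asarray(coords_model, dtype=float)
    target = np.asarray(coords_target, dtype=float)
    if model.shape != target.shape or len(model) == 0:
        raise ValueError("need equal-length, non-empty paired coordinate sets")
    if rmsd_cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    n = len(model)

    def window_fits(length: int) -> bool:
        for start in range(0, n - length + 1):
            seg = slice(start, start + length)
            try:
                if superpose(target[seg], model[seg]).rmsd <= rmsd_cutoff:
                    return True
            except ValueError:
                return True  # degenerate (collinear) windows superpose exactly
        return False

    # window r.m.s.d. is not monotone under extension, so scan lengths
    # exhaustively from the longest down
    longest = min(n, 2)  # 1- and 2-point segments always superpose exactly
    for length in range(n, 2, -1):
        if window_fits(length):
            longest = length
            break
    return 100.0 * longest / n


def lga_s(gdt_score: float, lcs_score: float, weight: float = 0.75) -> float:
    """Weighted GDT/LCS combination (the exact mix inside LGA_S is not
    published; the default leans toward GDT)."""
    for val in (gdt_score, lcs_score):
        if not 0.0 <= val <= 100.0:
            raise ValueError("scores must lie in [0, 100]")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return weight * gdt_score + (1.0 - weight) * lcs_score


def score_pair(coords_model, coords_target, lcs_cutoff: float = 4.0,
               weight: float = 0.75) -> ScoreReport:
    """Full score report for a 1:1-paired CA set."""
    sup = superpose(coords_target, coords_model)
    g_ts = gdt(coords_model, coords_target, cutoffs=GDT_TS_CUTOFFS)
    g_ha = gdt(coords_model, coords_target, cutoffs=GDT_HA_CUTOFFS)
    l = lcs(coords_model, coords_target, lcs_cutoff)
    return ScoreReport(rmsd=sup.rmsd, gdt_ts=g_ts, gdt_ha=g_ha, lcs=l,
                       lga_s=lga_s(g_ts, l, weight))


# -- helix geometry ---------------------------------------------------------


@dataclass
class HelixGeometry:
    local_axes: np.ndarray      # (m, 3) unit vectors
    local_origins: np.ndarray   # (m, 3) window centroids
    bending_angles: np.ndarray  # degrees, axes one turn apart
    avg_bend: float
    max_bend: float
    shape_class: str


def _local_axes_sugeta_miyazawa(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local helix axes from consecutive 4-CA windows.

    For window i the bond vectors v_i, v_i+1, v_i+2 give two turning
    vectors whose cross product is the local axis direction (Sugeta-
    Miyazawa construction); orientation is made consistent along the chain.
    """
    v = np.diff(ca, axis=0)
    dv = np.diff(v, axis=0)              # turning vectors
    axes = np.cross(dv[:-1], dv[1:])
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms < 1e-10):
        raise ValueError("degenerate geometry: collinear CA stretch")
    axes /= norms[:, None]
    chain_dir = ca[-1] - ca[0]
    flip = (axes @ chain_dir) < 0
    axes[flip] *= -1.0
    origins = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(axes))])
    return axes, origins


def helix_axes(ca_coords, turn_offset: int = 4, kink_threshold: float = 20.0,
               linear_threshold: float = 5.0) -> HelixGeometry:
    """Bending analysis of one helix from its CA trace.

    The bending angle is the angle between local axes one helical turn
    (``turn_offset`` windows, about 4 residues) apart.  Classification:
    kinked when the maximum bend >= ``kink_threshold`` degrees, linear when
    it stays below ``linear_threshold``, else curved.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or len(ca) < 6:
        raise ValueError("need at least six CA positions")
    axes, origins = _local_axes_sugeta_miyazawa(ca)
    if len(axes) <= turn_offset:
        offset = max(1, len(axes) - 1)
    else:
        offset = turn_offset
    dots = np.clip(np.sum(axes[:-offset] * axes[offset:], axis=1), -1.0, 1.0)
    bends = np.degrees(np.arccos(dots))
    avg_b, max_b = float(np.mean(bends)), float(np.max(bends))
    if max_b >= kink_threshold:
        cls = "kinked"
    elif max_b < linear_threshold:
        cls = "linear"
    else:
        cls = "curved"
    return HelixGeometry(axes, origins, bends, avg_b, max_b, cls)


def helix_axis(ca_coords) -> np.ndarray:
    """Overall helix axis: least-squares line fit through the local-axis
    origin points, oriented along the chain."""
    geom = helix_axes(ca_coords)
    pts = geom.local_origins - geom.local_origins.mean(axis=0)
    _, _, vt = np.linalg.svd(pts)
    axis = vt[0]
    if axis @ (ca_coords[-1] - ca_coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def inter_helix_angle(axis_1, axis_2, reference=None) -> float:
    """Angle between helix axes in degrees.

    Unsigned in [0, 180] by default.  With a ``reference`` vector the angle
    is signed by the triple product sign convention, in (-180, 180].
    """
    a1 = np.asarray(axis_1, dtype=float)
    a2 = np.asarray(axis_2, dtype=float)
    n1, n2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("axis vectors must be non-zero")
    cosang = float(np.clip(a1 @ a2 / (n1 * n2), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    if reference is None:
        return ang
    sign = np.sign(np.dot(np.cross(a1, a2), np.asarray(reference, dtype=float)))
    return ang if sign >= 0 else -ang
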