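"""Synthetic diffraction laboratory.

Atomic models, direct-summation structure factors, Wilson normalization to
E-values, and controlled simulation of target/model pairs at a specified
coordinate r.m.s.d. and scattering fraction fm.  Scattering factors are the
point-atom approximation f = atomic number: the likelihood machinery
operates on normalized amplitudes, where the resolution dependence of the
form factor cancels, and constant f keeps the independent test oracles
exact.  A hook for single-Gaussian form factors is left in ``Atom.f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .crystal import ReflectionSet, UnitCell

__all__ = [
    "Atom",
    "AtomicModel",
    "StructureFactorSet",
    "calc_structure_factors",
    "wilson_sigma_n",
    "normalize",
    "simulate_pair",
    "simulate_observed",
]


def scattering_factor(element: str) -> float:
    """Point-atom scattering factor: the atomic number."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    return float(el.atomic_number)


@dataclass(frozen=True)
class Atom:
    element: str
    frac: tuple[float, float, float]
    occ: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b < 0:
            raise ValueError("B factor must be non-negative")

    @property
    def f(self) -> float:
        return scattering_factor(self.element)


@dataclass
class AtomicModel:
    """Atoms in a cell, grouped into residues by (chain_id, res_seq).

    Parallel arrays keep the structure-factor sums vectorized; the
    chain/residue identifiers exist for trimming, weighting and I/O.
    """

    cell: UnitCell
    frac: np.ndarray                 # (n, 3) fractional
    elements: list[str]
    occ: np.ndarray                  # (n,)
    b: np.ndarray                    # (n,)
    chain_ids: list[str] = field(default_factory=list)
    res_seq: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frac = np.atleast_2d(np.asarray(self.frac, dtype=float))
        n = len(self.frac)
        if n == 0:
            raise ValueError("model must contain at least one atom")
        self.occ = np.asarray(self.occ, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.elements) == len(self.occ) == len(self.b) == n):
            raise ValueError("per-atom arrays must be aligned")
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b < 0):
            raise ValueError("B factors must be non-negative")
        if not self.chain_ids:
            self.chain_ids = ["A"] * n
        if len(self.res_seq) == 0:
            self.res_seq = np.arange(1, n + 1)
        if not self.atom_names:
            self.atom_names = ["CA"] * n

    def __len__(self) -> int:
        return len(self.frac)

    @property
    def f(self) -> np.ndarray:
        return np.array([scattering_factor(e) for e in self.elements])

    @property
    def total_scattering(self) -> float:
        """Sum of (occ * f)^2 over atoms - the Wilson-statistics weight."""
        return float(np.sum((self.occ * self.f) ** 2))

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("subset would be empty")
        return AtomicModel(
            self.cell,
            self.frac[mask],
            [e for e, m in zip(self.elements, mask) if m],
            self.occ[mask],
            self.b[mask],
            [c for c, m in zip(self.chain_ids, mask) if m],
            self.res_seq[mask],
            [a for a, m in zip(self.atom_names, mask) if m],
        )


@dataclass
class StructureFactorSet:
    """Structure factors aligned with a ReflectionSet.

    ``f`` holds complex values when computed from a model, None when only
    amplitudes are known (simulated observations).  ``e`` and ``sigma_n``
    are filled by :func:`normalize`.
    """

    amp: np.ndarray                       # (n,) |F| >= 0
    f: np.ndarray | None = None           # (n,) complex
    e: np.ndarray | None = None           # (n,) normalized amplitudes
    sigma_n: np.ndarray | None = None     # per-shell Wilson scale
    shell_index: np.ndarray | None = None  # (n,) shell of each reflection

    def __post_init__(self) -> None:
        self.amp = np.asarray(self.amp, dtype=float)
        if np.any(self.amp < 0):
            raise ValueError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.amp)


# -- structure factors ------------------------------------------------------


def calc_structure_factors(model: AtomicModel, reflections: ReflectionSet) -> StructureFactorSet:
    """Direct summation: F(h) = sum_j occ_j f_j exp(-B_j s^2/4) exp(2 pi i h.x_j)."""
    if reflections.cell is not None and reflections.cell != model.cell:
        raise ValueError("model and reflection set have different unit cells")
    if len(reflections) == 0:
        raise ValueError("reflection set is empty")
    s2 = 1.0 / reflections.d**2                                  # (nref,)
    weights = model.occ[None, :] * model.f[None, :] * np.exp(
        -model.b[None, :] * s2[:, None] / 4.0)                   # (nref, nat)
    phase = np.exp(2j * np.pi * (reflections.hkl @ model.frac.T))
    fcalc = np.sum(weights * phase, axis=1)
    return StructureFactorSet(amp=np.abs(fcalc), f=fcalc)


def assign_shells(reflections: ReflectionSet, shells: int) -> np.ndarray:
    """Equal-count resolution shells (by 1/d^2); returns the shell of each reflection."""
    if shells < 1:
        raise ValueError("need at least one shell")
    order = np.argsort(1.0 / reflections.d**2)
    idx = np.empty(len(reflections), int)
    idx[order] = np.minimum((np.arange(len(reflections)) * shells) // len(reflections),
                            shells - 1)
    return idx


def wilson_sigma_n(model: AtomicModel, reflections: ReflectionSet, shells: int) -> np.ndarray:
    """Theoretical Wilson scale per shell.

    SigmaN(shell) = sum_j (occ_j f_j exp(-B_j s^2/4))^2 at the shell's mean s.
    """
    if shells < 1:
        raise ValueError("need at least one shell")
    idx = assign_shells(reflections, shells)
    out = np.empty(shells)
    s = 1.0 / reflections.d
    for sh in range(shells):
        mask = idx == sh
        if not mask.any():
            raise ValueError(f"resolution shell {sh} is empty")
        s_mean = float(np.mean(s[mask]))
        out[sh] = np.sum((model.occ * model.f * np.exp(-model.b * s_mean**2 / 4.0)) ** 2)
    return out


def normalize(sf: StructureFactorSet, reflections: ReflectionSet, shells: int,
              sigma_n: np.ndarray | None = None) -> StructureFactorSet:
    """Normalized amplitudes E = |F| / sqrt(epsilon * SigmaN(shell)).

    With ``sigma_n`` omitted (empirical mode) the shell scale is the observed
    mean of |F|^2/epsilon, which makes the per-shell mean of the
    epsilon-corrected E^2 exactly 1 and renders the operation idempotent and
    scale-invariant.  Passing a theoretical SigmaN (from
    :func:`wilson_sigma_n`) uses that scale instead.
    """
    if len(sf) != len(reflections):
        raise ValueError("structure factors and reflections are not aligned")
    idx = assign_shells(reflections, shells)
    eps = reflections.epsilon.astype(float)
    if sigma_n is None:
        sigma_n = np.empty(shells)
        for sh in range(shells):
            mask = idx == sh
            if not mask.any():
                raise ValueError(f"resolution shell {sh} is empty")
            sigma_n[sh] = np.mean(sf.amp[mask] ** 2 / eps[mask])
            if sigma_n[sh] <= 0:
                raise ValueError(f"resolution shell {sh} has zero power")
    else:
        sigma_n = np.asarray(sigma_n, dtype=float)
        if sigma_n.shape != (shells,):
            raise ValueError("sigma_n must have one entry per shell")
    e = sf.amp / np.sqrt(eps * sigma_n[idx])
    return StructureFactorSet(amp=sf.amp, f=sf.f, e=e, sigma_n=sigma_n, shell_index=idx)


# -- simulation -------------------------------------------------------------


def _random_model(n_residues: int, cell: UnitCell, rng: np.random.Generator,
                  min_dist: float = 1.5, b: float = 0.0) -> AtomicModel:
    """Random single-atom (carbon) residues with minimum-distance rejection."""
    orth = cell.orthogonalization_matrix
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_residues:
        cand = rng.random(3)
        attempts += 1
        if attempts > 1000 * n_residues:
            raise RuntimeError("cell too crowded for the minimum-distance guard")
        if placed:
            diff = np.array(placed) - cand
            diff -= np.round(diff)                      # nearest periodic image
            if np.min(np.linalg.norm(diff @ orth.T, axis=1)) < min_dist:
                continue
        placed.append(cand)
    frac = np.array(placed)
    n = len(frac)
    return AtomicModel(cell, frac, ["C"] * n, np.ones(n), np.full(n, float(b)))


def perturb_exact_rmsd(model: AtomicModel, rmsd: float, rng: np.random.Generator,
                       rescale_mask: np.ndarray | None = None) -> AtomicModel:
    """Isotropic Gaussian displacements rescaled to an exact realized r.m.s.d.

    The rescaling norm is taken over ``rescale_mask`` atoms (all atoms when
    None), so the realized r.m.s.d. over that subset equals the request to
    floating-point accuracy.
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    n = len(model)
    disp = rng.normal(size=(n, 3))
    mask = np.ones(n, bool) if rescale_mask is None else np.asarray(rescale_mask, bool)
    realized = np.sqrt(np.mean(np.sum(disp[mask] ** 2, axis=1)))
    disp *= 0.0 if realized == 0 else rmsd / realized
    orth_coords = model.cell.orthogonalize(model.frac) + disp
    return replace(model, frac=model.cell.fractionalize(orth_coords))


def simulate_pair(n_residues: int, cell: UnitCell, rmsd: float, fm: float,
                  seed: int) -> tuple[AtomicModel, AtomicModel]:
    """A random target and a model at exactly the requested rmsd and fm.

    The retained-atom subset is chosen first; the Gaussian displacements are
    rescaled so the realized r.m.s.d. over the retained pairs equals the
    request exactly, then the (1 - fm) scattering fraction is deleted.  With
    identical atoms, fm in scattering equals fm in atom count.
    """
    if not 0.0 < fm <= 1.0:
        raise ValueError("fm must lie in (0, 1]")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    rng = np.random.default_rng(seed)
    target = _random_model(n_residues, cell, rng)
    n_keep = max(1, int(round(fm * n_residues)))
    keep = np.zeros(n_residues, bool)
    keep[rng.choice(n_residues, size=n_keep, replace=False)] = True
    moved = perturb_exact_rmsd(target, rmsd, rng, rescale_mask=keep)
    model = moved.subset(keep) if n_keep < n_residues else moved
    return target, model


def simulate_observed(target_sf: StructureFactorSet, noise_fraction: float,
                      seed: int) -> np.ndarray:
    """Observed amplitudes: |F| with multiplicative Gaussian noise, clipped at 0."""
    if noise_fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    amp = target_sf.amp.copy()
    if noise_fraction == 0:
        return amp
    rng = np.random.default_rng(seed)
    return np.maximum(amp * (1.0 + noise_fraction * rng.normal(size=amp.shape)), 0.0)
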