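"""Amplitude likelihood, LLG, VRMS refinement and pose significance.

The likelihood of one reflection is the probability of the observed
normalized amplitude given the calculated one and sigma-A: the Rice
distribution for acentric reflections and the Woolfson (two-component
Gaussian) form for centric ones.  The log-likelihood gain (LLG) subtracts
the Wilson baseline - the log-probability of the same observation under a
random arrangement of the same atoms - so a model with sigma-A = 0
contributes exactly zero.

All densities here are in normalized amplitudes E with unit Wilson
variance; epsilon factors are divided into the normalization upstream
(:func:`mrellg.diffraction.normalize`), so no epsilon appears below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import i0e

from .crystal import ReflectionSet
from .diffraction import AtomicModel, calc_structure_factors, normalize
from .sigmaa import SigmaAParams, sigma_a

__all__ = [
    "LLGResult",
    "llg",
    "expected_llg_mc",
    "refine_vrms",
    "classify_pose",
    "weighting_benefit",
    "POSE_LLG_THRESHOLDS",
]

#: Space-group-class-dependent LLG thresholds above which a pose is
#: probably correct.
POSE_LLG_THRESHOLDS = {"nonpolar": 60.0, "polar": 50.0, "P1": 30.0}


@dataclass
class LLGResult:
    total: float
    per_reflection: np.ndarray
    sigma_a: np.ndarray
    refined_vrms: float | None = None

    def __post_init__(self) -> None:
        self.per_reflection = np.asarray(self.per_reflection, dtype=float)
        self.sigma_a = np.asarray(self.sigma_a, dtype=float)
        if self.refined_vrms is not None and self.refined_vrms < 0:
            raise ValueError("refined VRMS must be non-negative")


def _log_cosh(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def _log_i0(x: np.ndarray) -> np.ndarray:
    return np.log(i0e(x)) + x


def llg_per_reflection_values(e_obs, e_calc, sa, centric) -> np.ndarray:
    """Per-reflection log p(Eobs | Ecalc, sigmaA) - log pWilson(Eobs)."""
    e_obs = np.asarray(e_obs, dtype=float)
    e_calc = np.asarray(e_calc, dtype=float)
    sa = np.asarray(sa, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    if not (e_obs.shape == e_calc.shape == sa.shape == centric.shape):
        raise ValueError("e_obs, e_calc, sigma_a and centric must be aligned")
    if np.any((sa < 0) | (sa > 1)):
        raise ValueError("sigma-A must lie in [0, 1]")
    out = np.empty(e_obs.shape)
    exact = sa == 1.0
    if exact.any():
        out[exact] = np.where(np.isclose(e_obs[exact], e_calc[exact]), 0.0, -np.inf)
    ok = ~exact
    v = 1.0 - sa[ok] ** 2
    eo, ec, s = e_obs[ok], e_calc[ok], sa[ok]
    acn = (-np.log(v) - (eo**2 + s**2 * ec**2) / v + eo**2
           + _log_i0(2.0 * s * eo * ec / v))
    cen = (-0.5 * np.log(v) - (eo**2 + s**2 * ec**2) / (2.0 * v) + eo**2 / 2.0
           + _log_cosh(s * eo * ec / v))
    out[ok] = np.where(centric[ok], cen, acn)
    return out


def llg(e_obs, e_calc, sigma_a_values, centric) -> LLGResult:
    """Total LLG with per-reflection contributions (Rice/Woolfson vs Wilson)."""
    per = llg_per_reflection_values(e_obs, e_calc, sigma_a_values, centric)
    return LLGResult(total=float(np.sum(per)), per_reflection=per,
                     sigma_a=np.asarray(sigma_a_values, dtype=float))


def sample_pair(sa: float, centric: bool, n: int, rng: np.random.Generator):
    """Draw (E_obs, E_calc) amplitude pairs from the joint sigma-A model."""
    if centric:
        ec_signed = rng.normal(size=n)
        eo = np.abs(sa * ec_signed + rng.normal(scale=np.sqrt(1.0 - sa * sa), size=n))
        return eo, np.abs(ec_signed)
    zc = (rng.normal(size=n) + 1j * rng.normal(size=n)) * np.sqrt(0.5)
    zo = sa * zc + (rng.normal(size=n) + 1j * rng.normal(size=n)) * np.sqrt((1.0 - sa * sa) / 2.0)
    return np.abs(zo), np.abs(zc)


def expected_llg_mc(sigma_a_value: float, centric: bool, n_sims: int,
                    seed: int) -> tuple[float, float]:
    """Monte-Carlo estimate of the per-reflection expected LLG.

    Returns (mean, standard error).  This is the independent oracle for the
    analytic :func:`mrellg.sigmaa.ellg_per_reflection`.
    """
    if not 0.0 <= sigma_a_value < 1.0:
        raise ValueError("sigma-A must lie in [0, 1)")
    if n_sims < 2:
        raise ValueError("need at least two simulations")
    rng = np.random.default_rng(seed)
    eo, ec = sample_pair(sigma_a_value, centric, n_sims, rng)
    vals = llg_per_reflection_values(
        eo, ec, np.full(n_sims, sigma_a_value), np.full(n_sims, centric))
    return float(np.mean(vals)), float(np.std(vals, ddof=1) / np.sqrt(n_sims))


# -- VRMS refinement --------------------------------------------------------


def _llg_at_rmsd(rmsd: float, e_obs, e_calc, fm, reflections, fsol, bsol) -> LLGResult:
    sa = sigma_a(SigmaAParams(rmsd, fm, fsol, bsol), reflections.d)
    sa = np.minimum(np.asarray(sa, dtype=float), 1.0 - 1e-12)
    return llg(e_obs, e_calc, sa, reflections.centric)


class VrmsConvergenceError(RuntimeError):
    pass


def refine_vrms(e_obs, e_calc, fm: float, reflections: ReflectionSet,
                init: float = 1.2, bounds: tuple[float, float] = (0.01, 5.0),
                fsol: float = 0.0, bsol: float = 0.0) -> tuple[float, LLGResult]:
    """Effective r.m.s.d. (VRMS) maximizing the total LLG.

    The sigma-A curve at the given fm links rmsd to per-reflection sigma-A;
    the single parameter is optimized by a coarse grid followed by bounded
    Brent search in the best bracket.  The default starting value is 1.2 A.
    """
    if init <= 0:
        raise ValueError("initial VRMS must be positive")

    def neg(r: float) -> float:
        return -_llg_at_rmsd(r, e_obs, e_calc, fm, reflections, fsol, bsol).total

    grid = np.linspace(bounds[0], bounds[1], 41)
    vals = np.array([neg(r) for r in grid])
    if not np.all(np.isfinite(vals)):
        raise VrmsConvergenceError("LLG not finite across the VRMS search grid")
    ib = int(np.argmin(vals))
    lo = grid[max(ib - 1, 0)]
    hi = grid[min(ib + 1, len(grid) - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    if not res.success:
        raise VrmsConvergenceError(f"VRMS optimizer failed: {res.message}")
    best = float(res.x) if res.fun <= vals[ib] else float(grid[ib])
    result = _llg_at_rmsd(best, e_obs, e_calc, fm, reflections, fsol, bsol)
    init_llg = -neg(init) if bounds[0] <= init <= bounds[1] else -np.inf
    if result.total + 1e-9 < init_llg:
        raise VrmsConvergenceError("optimum LLG below the value at the start point")
    result.refined_vrms = best
    return best, result


def classify_pose(llg_total: float, space_group_class: str) -> bool:
    """Probably-correct pose test: LLG strictly above the class threshold
    (60 nonpolar, 50 polar, 30 in P1)."""
    try:
        threshold = POSE_LLG_THRESHOLDS[space_group_class]
    except KeyError:
        raise ValueError(
            f"unknown space-group class {space_group_class!r}; "
            f"expected one of {sorted(POSE_LLG_THRESHOLDS)}") from None
    return llg_total > threshold


# -- error weighting --------------------------------------------------------


def _best_llg_for_model(model: AtomicModel, e_obs, reflections, fm, shells) -> float:
    sf = normalize(calc_structure_factors(model, reflections), reflections, shells)
    _, res = refine_vrms(e_obs, sf.e, fm, reflections)
    return res.total


def weighting_benefit(target: AtomicModel, model_with_errors, reflections: ReflectionSet,
                      shells: int = 10, uniform_b_grid=None) -> tuple[float, float]:
    """LLG with per-atom error weighting versus the best uniform B.

    ``model_with_errors`` is a PredictedModel carrying per-residue error
    estimates Delta; per-atom B = 8 pi^2 Delta^2 / 3 downweights the poorly
    predicted residues in Ecalc.  The uniform alternative gives every atom
    the same B, optimized over ``uniform_b_grid`` (default 0-80 A^2).  VRMS
    is refined for both so each weighting gets its best sigma-A curve.
    Returns (LLG weighted, LLG best-uniform).
    """
    from .modelprep import error_to_bfactor  # deferred: modelprep imports this module

    deltas = getattr(model_with_errors, "delta_per_atom", None)
    if deltas is None:
        raise ValueError("model carries no per-residue error estimates")
    base = model_with_errors.atoms
    fm = min(1.0, base.total_scattering / target.total_scattering)
    obs_sf = normalize(calc_structure_factors(target, reflections), reflections, shells)
    e_obs = obs_sf.e

    from dataclasses import replace
    weighted = replace(base, b=error_to_bfactor(np.asarray(deltas)))
    llg_weighted = _best_llg_for_model(weighted, e_obs, reflections, fm, shells)

    if uniform_b_grid is None:
        uniform_b_grid = np.linspace(0.0, 80.0, 33)
    llg_uniform = -np.inf
    for b in uniform_b_grid:
        uni = replace(base, b=np.full(len(base), float(b)))
        llg_uniform = max(llg_uniform, _best_llg_for_model(uni, e_obs, reflections, fm, shells))
    return llg_weighted, llg_uniform
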