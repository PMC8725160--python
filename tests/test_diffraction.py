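"""Structure factors, Wilson normalization and the pair simulator."""

import cmath
import math
from dataclasses import replace

import numpy as np
import pytest

from mrellg import (
    AtomicModel,
    SymmetryOps,
    UnitCell,
    calc_structure_factors,
    generate_reflections,
    normalize,
    simulate_observed,
    simulate_pair,
    wilson_sigma_n,
)
from mrellg.diffraction import _random_model, scattering_factor

from conftest import random_cell


def reference_structure_factor(model, hkl, d):
    """Independent oracle: plain per-atom Python loop, no vectorization."""
    s2 = 1.0 / d**2
    total = 0 + 0j
    for j in range(len(model)):
        f = scattering_factor(model.elements[j])
        w = model.occ[j] * f * math.exp(-model.b[j] * s2 / 4.0)
        phase = 2.0 * math.pi * (hkl[0] * model.frac[j, 0]
                                 + hkl[1] * model.frac[j, 1]
                                 + hkl[2] * model.frac[j, 2])
        total += w * cmath.exp(1j * phase)
    return total


def small_model(cell, frac, elements=None, occ=None, b=None):
    n = len(frac)
    return AtomicModel(cell, np.array(frac, float),
                       elements or ["C"] * n,
                       np.ones(n) if occ is None else np.array(occ, float),
                       np.zeros(n) if b is None else np.array(b, float))


class TestStructureFactors:
    def test_single_atom_at_origin(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 5.0)
        model = small_model(cubic_cell, [[0.0, 0.0, 0.0]], elements=["N"])
        sf = calc_structure_factors(model, refl)
        assert np.allclose(sf.amp, scattering_factor("N"), atol=1e-10)

    def test_destructive_interference(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 8.0)
        model = small_model(cubic_cell, [[0, 0, 0], [0.5, 0, 0]])
        sf = calc_structure_factors(model, refl)
        idx = np.flatnonzero((refl.hkl == [1, 0, 0]).all(axis=1))[0]
        assert sf.amp[idx] == pytest.approx(0.0, abs=1e-10)

    def test_against_reference_loop_on_random_models(self, p1_ops):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cell = random_cell(rng)
            n = int(rng.integers(5, 51))
            model = small_model(
                cell, rng.random((n, 3)),
                elements=[["C", "N", "O", "S"][int(rng.integers(4))] for _ in range(n)],
                occ=rng.uniform(0.3, 1.0, n), b=rng.uniform(0.0, 40.0, n))
            refl = generate_reflections(cell, p1_ops, 4.0)
            if len(refl) > 50:
                from mrellg import ReflectionSet
                refl = ReflectionSet(refl.hkl[:50], refl.d[:50],
                                     refl.centric[:50], refl.epsilon[:50], cell=cell)
            sf = calc_structure_factors(model, refl)
            for i in range(len(refl)):
                ref = reference_structure_factor(model, refl.hkl[i], refl.d[i])
                assert sf.f[i] == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_friedel_symmetry_by_direct_evaluation(self, cubic_cell, p1_ops):
        rng = np.random.default_rng(2)
        model = small_model(cubic_cell, rng.random((10, 3)), b=rng.uniform(0, 20, 10))
        refl = generate_reflections(cubic_cell, p1_ops, 6.0)
        from mrellg import ReflectionSet
        neg = ReflectionSet(-refl.hkl, refl.d, refl.centric, refl.epsilon, cell=cubic_cell)
        f_pos = calc_structure_factors(model, refl).f
        f_neg = calc_structure_factors(model, neg).f
        assert np.allclose(f_neg, np.conj(f_pos), rtol=1e-12, atol=1e-12)

    def test_mismatched_cells_rejected(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 6.0)
        other = small_model(UnitCell(20, 20, 20), [[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError):
            calc_structure_factors(other, refl)


class TestWilsonSigmaN:
    def test_point_atoms_give_sum_f_squared(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 4.0)
        model = small_model(cubic_cell, np.random.default_rng(0).random((8, 3)),
                            elements=["C", "N", "O", "S"] * 2)
        sn = wilson_sigma_n(model, refl, shells=4)
        expected = sum(scattering_factor(e) ** 2 for e in model.elements)
        assert np.allclose(sn, expected, rtol=1e-12)

    def test_occupancy_scaling_is_quadratic(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 4.0)
        rng = np.random.default_rng(1)
        model = small_model(cubic_cell, rng.random((6, 3)), occ=[0.4] * 6)
        doubled = replace(model, occ=model.occ * 2)
        assert np.allclose(wilson_sigma_n(doubled, refl, 3),
                           4 * wilson_sigma_n(model, refl, 3), rtol=1e-12)

    def test_mean_intensity_tracks_sigma_n(self, p1_ops):
        # Wilson statistics: <|F|^2> per shell ~ epsilon * SigmaN for
        # uniformly random atoms (no excluded volume, the Wilson premise)
        cell = UnitCell(28, 28, 28)
        rng = np.random.default_rng(8)
        model = small_model(cell, rng.random((300, 3)))
        refl = generate_reflections(cell, p1_ops, 2.2)
        assert len(refl) >= 4000
        sf = calc_structure_factors(model, refl)
        sn = wilson_sigma_n(model, refl, shells=2)
        from mrellg.diffraction import assign_shells
        idx = assign_shells(refl, 2)
        for sh in range(2):
            mean_i = np.mean(sf.amp[idx == sh] ** 2)
            assert mean_i == pytest.approx(sn[sh], rel=0.05)


class TestNormalize:
    def test_equal_amplitudes_give_unit_e(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 6.0)
        from mrellg import StructureFactorSet
        sf = StructureFactorSet(amp=np.full(len(refl), 7.5))
        out = normalize(sf, refl, shells=1)
        assert np.allclose(out.e, 1.0, atol=1e-12)

    def test_scale_invariance_and_idempotence(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 4.0)
        rng = np.random.default_rng(4)
        model = small_model(cubic_cell, rng.random((30, 3)))
        sf = calc_structure_factors(model, refl)
        from mrellg import StructureFactorSet
        scaled = StructureFactorSet(amp=sf.amp * 10.0)
        e1 = normalize(sf, refl, 5).e
        e2 = normalize(scaled, refl, 5).e
        assert np.allclose(e1, e2, rtol=1e-12)
        twice = normalize(StructureFactorSet(amp=e1), refl, 5).e
        assert np.allclose(twice, e1, rtol=1e-9)

    def test_per_shell_second_moment_is_one(self, cubic_cell, p1_ops):
        refl = generate_reflections(cubic_cell, p1_ops, 3.0)
        rng = np.random.default_rng(5)
        model = small_model(cubic_cell, rng.random((50, 3)))
        out = normalize(calc_structure_factors(model, refl), refl, 8)
        for sh in range(8):
            mask = out.shell_index == sh
            assert np.mean(out.e[mask] ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_acentric_fourth_moment_near_two(self, p1_ops):
        cell = UnitCell(28, 28, 28)
        rng = np.random.default_rng(9)
        model = small_model(cell, rng.random((300, 3)))
        refl = generate_reflections(cell, p1_ops, 2.4)
        out = normalize(calc_structure_factors(model, refl), refl, 4)
        assert np.mean(out.e ** 4) == pytest.approx(2.0, rel=0.1)

    def test_theoretical_vs_empirical_scale(self, p1_ops):
        cell = UnitCell(26, 26, 26)
        rng = np.random.default_rng(10)
        model = small_model(cell, rng.random((250, 3)))
        refl = generate_reflections(cell, p1_ops, 2.4)
        sf = calc_structure_factors(model, refl)
        emp = normalize(sf, refl, 4)
        theo = normalize(sf, refl, 4, sigma_n=wilson_sigma_n(model, refl, 4))
        for sh in range(4):
            assert theo.sigma_n[sh] == pytest.approx(emp.sigma_n[sh], rel=0.10)


class TestSimulatePair:
    def test_exact_realized_rmsd_over_retained_pairs(self, cubic_cell):
        target, model = simulate_pair(150, cubic_cell, rmsd=0.8, fm=0.7, seed=3)
        t_orth = cubic_cell.orthogonalize(target.frac)
        m_orth = cubic_cell.orthogonalize(model.frac)
        kept = {(c, int(r)): i for i, (c, r) in
                enumerate(zip(target.chain_ids, target.res_seq))}
        idx = [kept[(c, int(r))] for c, r in zip(model.chain_ids, model.res_seq)]
        realized = np.sqrt(np.mean(np.sum((m_orth - t_orth[idx]) ** 2, axis=1)))
        assert realized == pytest.approx(0.8, abs=1e-9)

    def test_complete_model_at_fm_one(self, cubic_cell):
        target, model = simulate_pair(100, cubic_cell, rmsd=0.5, fm=1.0, seed=1)
        assert len(model) == len(target) == 100

    def test_scattering_fraction(self, cubic_cell):
        target, model = simulate_pair(200, cubic_cell, rmsd=0.5, fm=0.6, seed=2)
        assert model.total_scattering / target.total_scattering == pytest.approx(
            0.6, abs=0.01)

    def test_seed_determinism(self, cubic_cell):
        a1 = simulate_pair(50, cubic_cell, 0.8, 0.9, seed=7)
        a2 = simulate_pair(50, cubic_cell, 0.8, 0.9, seed=7)
        b = simulate_pair(50, cubic_cell, 0.8, 0.9, seed=8)
        assert np.array_equal(a1[0].frac, a2[0].frac)
        assert np.array_equal(a1[1].frac, a2[1].frac)
        assert not np.array_equal(a1[1].frac, b[1].frac)

    def test_invalid_fm(self, cubic_cell):
        with pytest.raises(ValueError):
            simulate_pair(10, cubic_cell, 0.5, 0.0, seed=0)


class TestSimulateObserved:
    def _sf(self, n=10000, seed=0):
        from mrellg import StructureFactorSet
        rng = np.random.default_rng(seed)
        return StructureFactorSet(amp=rng.uniform(5, 50, n))

    def test_zero_noise_is_identity(self):
        sf = self._sf()
        assert np.array_equal(simulate_observed(sf, 0.0, seed=1), sf.amp)

    def test_noise_magnitude(self):
        sf = self._sf()
        obs = simulate_observed(sf, 0.05, seed=1)
        rel = (obs - sf.amp) / sf.amp
        assert np.std(rel) == pytest.approx(0.05, rel=0.10)

    def test_seeded_reproducibility(self):
        sf = self._sf()
        assert np.array_equal(simulate_observed(sf, 0.1, 5), simulate_observed(sf, 0.1, 5))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_observed(self._sf(10), -0.1, seed=0)
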