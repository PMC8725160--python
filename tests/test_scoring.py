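"""Superposition, GDT/LCS scores and helix geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mrellg import (
    gdt,
    helix_axes,
    helix_axis,
    inter_helix_angle,
    lcs,
    lga_s,
    superpose,
)
from mrellg.scoring import GDT_HA_CUTOFFS, GDT_TS_CUTOFFS, Superposition, score_pair


def rot_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def ideal_helix(n, rise=1.5, twist=100.0, radius=2.3, start=0):
    t = np.arange(start, start + n)
    ang = np.radians(twist) * t
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * t], axis=1)


def scipy_rmsd(a, b):
    """Independent minimal-rmsd oracle via scipy's Kabsch."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return rssd / np.sqrt(len(a))


class TestSuperpose:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).random((10, 3)) * 20
        sup = superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_applied_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.random((25, 3)) * 15
        r = rot_z(37.0)
        b = (a - a.mean(0)) @ r.T + np.array([3.0, -2.0, 7.0])
        sup = superpose(a, b)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation @ r, np.eye(3), atol=1e-9)

    def test_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(2)
        sup = superpose(rng.random((12, 3)), rng.random((12, 3)))
        assert np.allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((15, 3)) * 10, rng.random((15, 3)) * 10
        base = superpose(a, b).rmsd
        moved = b @ rot_z(63.0).T + [5, 5, 5]
        assert superpose(a, moved).rmsd == pytest.approx(base, abs=1e-9)

    def test_not_beaten_by_random_rotation_search(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((30, 3)) * 12, rng.random((30, 3)) * 12
        opt = superpose(a, b).rmsd
        ac, bc = a - a.mean(0), b - b.mean(0)
        rand = Rotation.random(10000, rng=42).as_matrix()
        best = min(np.sqrt(np.mean(np.sum((ac - bc @ r.T) ** 2, axis=1))) for r in rand)
        assert opt <= best + 1e-12
        assert opt == pytest.approx(scipy_rmsd(a, b), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestGDT:
    def test_perfect_model_scores_100(self):
        pts = ideal_helix(30)
        assert gdt(pts, pts) == 100.0
        assert gdt(pts, pts, cutoffs=GDT_HA_CUTOFFS) == 100.0

    def test_fixed_superposition_hand_countable(self):
        target = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        model = target.copy()
        model[3, 2] += 20.0  # one of four atoms displaced far away
        fixed = Superposition(np.eye(3), np.zeros(3), 0.0, 4)
        assert gdt(model, target, superposition=fixed) == 75.0
        assert gdt(model, target, superposition=fixed, cutoffs=GDT_HA_CUTOFFS) == 75.0

    def test_ha_never_exceeds_ts(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            target = ideal_helix(n) + rng.normal(scale=0.3, size=(n, 3))
            model = target + rng.normal(scale=rng.uniform(0.1, 3.0), size=(n, 3))
            ts = gdt(model, target, cutoffs=GDT_TS_CUTOFFS)
            ha = gdt(model, target, cutoffs=GDT_HA_CUTOFFS)
            assert ha <= ts + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gdt(np.empty((0, 3)), np.empty((0, 3)))


def lcs_bruteforce(model, target, cutoff):
    """Exhaustive window-search oracle built on the scipy Kabsch."""
    n = len(model)
    best = min(n, 2)
    for length in range(3, n + 1):
        for start in range(0, n - length + 1):
            m = model[start:start + length]
            t = target[start:start + length]
            if scipy_rmsd(t, m) <= cutoff:
                best = max(best, length)
                break
    return 100.0 * best / n


class TestLCS:
    def test_identical_structures(self):
        pts = ideal_helix(40)
        assert lcs(pts, pts, 1.0) == 100.0

    def test_half_displaced_chain(self):
        target = ideal_helix(100)
        model = target.copy()
        model[50:] += [40.0, 0, 0]  # rigid displacement of the second half
        assert lcs(model, target, 0.5) == 50.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        target = ideal_helix(40)
        model = target + rng.normal(scale=1.2, size=target.shape)
        vals = [lcs(model, target, c) for c in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        target = ideal_helix(n)
        model = target + rng.normal(scale=0.8, size=(n, 3))
        model[rng.integers(10, 50):] += rng.normal(scale=3.0, size=3)
        for cutoff in (1.0, 2.0):
            assert lcs(model, target, cutoff) == lcs_bruteforce(model, target, cutoff)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lcs(np.empty((0, 3)), np.empty((0, 3)), 1.0)


class TestLgaS:
    def test_pure_weights(self):
        assert lga_s(80.0, 40.0, weight=1.0) == 80.0
        assert lga_s(80.0, 40.0, weight=0.0) == 40.0

    def test_convexity(self):
        for w in (0.1, 0.5, 0.9):
            val = lga_s(70.0, 30.0, w)
            assert 30.0 <= val <= 70.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lga_s(120.0, 50.0)
        with pytest.raises(ValueError):
            lga_s(50.0, 50.0, weight=1.5)


class TestHelixGeometry:
    def test_straight_helix_is_linear(self):
        geom = helix_axes(ideal_helix(25))
        assert geom.max_bend < 1.0
        assert geom.shape_class == "linear"

    def test_constructed_kink_angle_recovered(self):
        first = ideal_helix(15)
        axis_dir = np.array([0.0, 0.0, 1.0])
        kinked_dir = np.array([np.sin(np.radians(25.0)), 0, np.cos(np.radians(25.0))])
        rot = Rotation.align_vectors(kinked_dir[None], axis_dir[None])[0].as_matrix()
        second = ideal_helix(15, start=15)
        pivot = first[-1]
        second = (second - pivot) @ rot.T + pivot
        geom = helix_axes(np.vstack([first, second]))
        assert geom.max_bend == pytest.approx(25.0, abs=2.0)
        assert geom.shape_class == "kinked"

    def test_classification_sense_of_moderate_vs_strong_bends(self):
        # a 7-8 degree maximum bend must not classify as kinked while a
        # 25-26 degree bend must (model 'curved' versus target 'kinked')
        for angle, expect_kinked in ((7.4, False), (25.7, True)):
            first = ideal_helix(15)
            tilt = Rotation.from_euler("y", angle, degrees=True).as_matrix()
            second = ideal_helix(15, start=15)
            pivot = first[-1]
            second = (second - pivot) @ tilt.T + pivot
            geom = helix_axes(np.vstack([first, second]))
            assert (geom.shape_class == "kinked") is expect_kinked

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            helix_axes(ideal_helix(5))


class TestInterHelixAngle:
    def test_parallel_axes(self):
        assert inter_helix_angle([0, 0, 1], [0, 0, 2]) == pytest.approx(0.0)

    def test_antiparallel_axes(self):
        assert inter_helix_angle([0, 0, 1], [0, 0, -1]) == pytest.approx(180.0)

    def test_perpendicular_constructed_helices(self):
        h1 = ideal_helix(15)
        h2 = ideal_helix(15) @ Rotation.from_euler("y", 90, degrees=True).as_matrix().T
        ang = inter_helix_angle(helix_axis(h1), helix_axis(h2))
        assert ang == pytest.approx(90.0, abs=1.0)

    def test_signed_convention_flips_with_order(self):
        a1, a2 = np.array([0, 0, 1.0]), np.array([np.sin(0.4), 0, np.cos(0.4)])
        ref = np.array([0, 1.0, 0])
        s1 = inter_helix_angle(a1, a2, reference=ref)
        s2 = inter_helix_angle(a2, a1, reference=ref)
        assert s1 == pytest.approx(-s2)
        assert abs(s1) == pytest.approx(np.degrees(0.4), abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            inter_helix_angle([0, 0, 0], [0, 0, 1])


class TestScorePair:
    def test_report_consistency(self):
        rng = np.random.default_rng(7)
        target = ideal_helix(40)
        model = target + rng.normal(scale=0.5, size=target.shape)
        rep = score_pair(model, target)
        assert rep.gdt_ha <= rep.gdt_ts
        assert 0 <= rep.lcs <= 100
        assert min(rep.gdt_ts, rep.lcs) - 1e-9 <= rep.lga_s <= max(rep.gdt_ts, rep.lcs) + 1e-9
        assert rep.rmsd == pytest.approx(scipy_rmsd(target, model), abs=1e-9)
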