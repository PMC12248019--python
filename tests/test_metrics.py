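"""Global metrics: superposition, TM-score, GDT_TS, lDDT, TM-align."""

import numpy as np
import pytest

import naassess as na
from naassess.metrics import (LDDTParams, _kabsch_rt, d0_for, gdt_ts,
                              kabsch_superpose, lddt, tm_align, tm_score)
from naassess.structures import Chain, Residue, Structure, StructureError

from conftest import random_walk_structure


def quaternion_superpose_rmsd(X, Y):
    """Independent oracle: Horn's closed-form quaternion method."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Sxx = X.T @ Y
    A = Sxx - Sxx.T
    delta = np.array([A[1, 2], A[2, 0], A[0, 1]])
    tr = np.trace(Sxx)
    Q = np.empty((4, 4))
    Q[0, 0] = tr
    Q[0, 1:] = Q[1:, 0] = delta
    Q[1:, 1:] = Sxx + Sxx.T - tr * np.eye(3)
    lam = np.linalg.eigvalsh(Q)[-1]
    e0 = float((X ** 2).sum() + (Y ** 2).sum())
    return np.sqrt(max(0.0, e0 - 2 * lam) / len(X))


def rigid_move(structure, angle=0.7, axis=(0.3, -1.0, 0.5), shift=(5.0, -3.0, 9.0)):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return structure.transform(R, np.asarray(shift, dtype=float))


class TestKabsch:
    def test_pure_translation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        sup = kabsch_superpose(X, X + [1.0, 0, 0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rotation_about_z(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        Rz = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])
        sup = kabsch_superpose(X, X @ Rz.T)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        sup = kabsch_superpose(X, Y)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(X, Y),
                                         abs=1e-6)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        sup = kabsch_superpose(X, X * [-1, 1, 1])  # mirrored target
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _corr(model, reference):
    return na.residue_correspondence(model, reference)


class TestTMScore:
    def test_self_is_exactly_one(self, hairpin):
        assert tm_score(hairpin, hairpin, _corr(hairpin, hairpin)) == 1.0

    def test_single_displaced_residue_closed_form(self):
        s = random_walk_structure(30, seed=2)
        model = s.copy()
        d = 60.0
        res = model.chains[0].residues[29]
        for k in res.atoms:
            res.atoms[k] = res.atoms[k] + np.array([d, 0.0, 0.0])
        d0 = d0_for(30, "RNA")
        got = tm_score(model, s, _corr(model, s))
        # 29 perfect residues plus a tiny contribution from the far one
        expected_floor = 29 / 30
        expected_ceiling = (29 + 1 / (1 + ((d - 5) / d0) ** 2)) / 30
        assert expected_floor < got <= expected_ceiling + 1e-9

    def test_normalized_by_reference_length(self):
        ref = random_walk_structure(30, seed=5)
        model = ref.copy()
        model.chains[0].residues = model.chains[0].residues[:20]
        got = tm_score(model, ref, _corr(model, ref))
        assert got == pytest.approx(20 / 30, abs=1e-9)

    def test_too_few_residues(self):
        s = random_walk_structure(2, seed=0)
        ref = random_walk_structure(2, seed=0)
        with pytest.raises(StructureError):
            tm_score(s, ref, na.Correspondence(
                pairs=[((s.chains[0], r), (ref.chains[0], q))
                       for r, q in zip(s.chains[0], ref.chains[0])]))


class TestGDT:
    def test_self_is_one(self, hairpin):
        assert gdt_ts(hairpin, hairpin, _corr(hairpin, hairpin)) == 1.0

    def test_half_displaced_rigidly(self):
        s = random_walk_structure(10, seed=7)
        model = s.copy()
        for res in model.chains[0].residues[5:]:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([300.0, 0, 0])
        assert gdt_ts(model, s, _corr(model, s)) == pytest.approx(0.5)

    def test_zero_to_one_scale(self, hairpin):
        m = na.perturb_model(hairpin, na.PerturbationSpec(2.0, seed=1))
        v = gdt_ts(m, hairpin, _corr(m, hairpin))
        assert 0.0 <= v <= 1.0


def _three_residue_pair():
    """Hand-enumerable 3-residue single-atom-per-residue toy."""
    ref_pts = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    mod_pts = np.array([[0.0, 0, 0], [4.6, 0, 0], [9.5, 0, 0]])
    def mk(pts, name):
        residues = [Residue("A", i + 1, "", {"C4'": p.copy()})
                    for i, p in enumerate(pts)]
        return Structure(name, [Chain("A", "RNA", residues)])
    return mk(mod_pts, "model"), mk(ref_pts, "ref")


class TestLDDT:
    def test_self_is_one(self, hairpin):
        assert lddt(hairpin, hairpin, _corr(hairpin, hairpin)) == 1.0

    def test_three_residue_manual_enumeration(self):
        model, ref = _three_residue_pair()
        # reference distances: (1,2)=4, (1,3)=8, (2,3)=4
        # model distances:     (1,2)=4.6, (1,3)=9.5, (2,3)=4.9
        # deltas: 0.6, 1.5, 0.9 -> preserved at 0.5 A: 0/3; 1 A: 2/3;
        # 2 A: 3/3; 4 A: 3/3 -> mean (0 + 2/3 + 1 + 1)/4 = 2/3
        got = lddt(model, ref, _corr(model, ref))
        assert got == pytest.approx((0 + 2 / 3 + 1 + 1) / 4, abs=1e-9)

    def test_clash_penalty_strictly_lowers_score(self, hairpin):
        clean = na.perturb_model(hairpin, na.PerturbationSpec(0.3, seed=5))
        fused = clean.copy()
        res = fused.chains[0].residues[0]
        # fuse two atoms of different residues at one point: severe clash
        res.atoms["C4'"] = fused.chains[0].residues[1].atoms["C4'"].copy()
        corr_clean = _corr(clean, hairpin)
        corr_fused = _corr(fused, hairpin)
        with_penalty = lddt(fused, hairpin, corr_fused)
        without_penalty = lddt(fused, hairpin, corr_fused,
                               LDDTParams(steric_penalty=False))
        assert with_penalty < without_penalty
        assert with_penalty < lddt(clean, hairpin, corr_clean)

    def test_no_qualifying_distances_raises(self):
        a = Structure("a", [Chain("A", "RNA", [
            Residue("A", 1, "", {"C4'": np.zeros(3)})])])
        with pytest.raises(StructureError):
            lddt(a, a, na.Correspondence(
                pairs=[((a.chains[0], a.chains[0].residues[0]),
                        (a.chains[0], a.chains[0].residues[0]))]))


class TestTMAlign:
    def test_self_alignment_is_one(self, hairpin):
        _, score = tm_align(hairpin, hairpin)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_sequence_independence(self, hairpin):
        other = hairpin.copy()
        for i, r in enumerate(other.chains[0].residues):
            r.number = 100 + i
            r.name = "C"
        _, score = tm_align(other, hairpin)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_chains_score_low(self):
        scores = []
        for k in range(25):
            a = random_walk_structure(40, seed=2 * k)
            b = random_walk_structure(40, seed=2 * k + 1)
            scores.append(tm_align(a, b)[1])
        assert max(scores) < 0.3

    def test_degenerate_input(self):
        tiny = random_walk_structure(4, seed=1)
        with pytest.raises(StructureError):
            tm_align(tiny, tiny)


class TestInvariants:
    @pytest.mark.parametrize("metric", [tm_score, gdt_ts, lddt])
    def test_rigid_motion_invariance(self, hairpin, metric):
        m = na.perturb_model(hairpin, na.PerturbationSpec(1.0, seed=11))
        base = metric(m, hairpin, _corr(m, hairpin))
        moved = rigid_move(m)
        assert metric(moved, hairpin, _corr(moved, hairpin)) == \
            pytest.approx(base, abs=1e-6)

    def test_tm_align_rigid_motion_invariance(self, hairpin):
        m = na.perturb_model(hairpin, na.PerturbationSpec(1.0, seed=11))
        base = tm_align(m, hairpin)[1]
        assert tm_align(rigid_move(m), hairpin)[1] == \
            pytest.approx(base, abs=1e-6)

    def test_monotone_degradation(self):
        spec = na.random_secstruct(16, seed=40)
        ref = na.build_structure(spec, seed=40)
        corrs = {}
        means = []
        for sigma in (0.0, 0.5, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(20):
                m = na.perturb_model(ref, na.PerturbationSpec(sigma, seed=seed))
                c = _corr(m, ref)
                vals.append(np.mean([tm_score(m, ref, c), gdt_ts(m, ref, c),
                                     lddt(m, ref, c)]))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_tm_score_is_a_lower_bound_for_tm_align(self, hairpin):
        """The sequence correspondence is one legal structural alignment,
        so the alignment search can only do better."""
        for seed in range(5):
            m = na.perturb_model(hairpin, na.PerturbationSpec(1.5, seed=seed))
            fixed = tm_score(m, hairpin, _corr(m, hairpin))
            free = tm_align(m, hairpin)[1]
            assert fixed <= free + 1e-9
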