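"""Trajectory metrics: oracles, invariances, rotamer/beta assignments."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from crossbeta import builder as B
from crossbeta import traj_analysis as T
from crossbeta._geom import nerf_place

from conftest import toy_assembly, random_rigid_transform


RNG = np.random.default_rng(20240917)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        a = toy_assembly([[1.0, 2.0, 3.0]])
        assert T.radius_of_gyration(a.xyz, a) == 0.0

    def test_two_equal_masses(self):
        a = toy_assembly([[0, 0, 0], [2, 0, 0]])
        assert T.radius_of_gyration(a.xyz, a) == pytest.approx(1.0, abs=1e-12)

    def test_matches_pairwise_double_loop_oracle(self):
        """Rg^2 == sum_ij m_i m_j |r_i - r_j|^2 / (2 M^2), an independent
        identity that never forms the centre of mass."""
        xyz = RNG.normal(scale=5.0, size=(20, 3))
        elements = RNG.choice(["C", "N", "O", "S"], size=20)
        a = toy_assembly(xyz, elements=list(elements))
        from crossbeta.constants import ATOMIC_WEIGHTS
        m = np.array([ATOMIC_WEIGHTS[e] for e in elements])
        M = m.sum()
        acc = 0.0
        for i in range(20):
            for j in range(20):
                acc += m[i] * m[j] * np.sum((xyz[i] - xyz[j]) ** 2)
        oracle = np.sqrt(acc / (2.0 * M ** 2))
        assert T.radius_of_gyration(a.xyz, a) == pytest.approx(oracle, abs=1e-10)

    def test_empty_selection_rejected(self):
        a = toy_assembly(RNG.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            T.radius_of_gyration(a.xyz, a, selection=np.array([], dtype=int))


class TestRmsd:
    def test_self_zero(self):
        x = RNG.normal(size=(10, 3))
        assert T.rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        x = RNG.normal(size=(15, 3))
        R, t = random_rigid_transform(RNG)
        assert T.rmsd(x @ R.T + t, x, superpose_first=True) < 1e-8

    def test_three_atom_closed_form(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        mob = ref + np.array([[0.3, 0, 0], [0, 0, 0], [0, 0, 0.4]])
        expected = np.sqrt((0.3 ** 2 + 0.4 ** 2) / 3.0)
        assert T.rmsd(mob, ref, superpose_first=False) == pytest.approx(expected,
                                                                       abs=1e-12)

    def test_matches_mdanalysis_oracle(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        x = RNG.normal(size=(20, 3))
        y = x + 0.5 * RNG.normal(size=(20, 3))
        ours = T.rmsd(y, x, superpose_first=True)
        theirs = mda_rmsd(y, x, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            T.rmsd(RNG.normal(size=(4, 3)), RNG.normal(size=(5, 3)))


class TestInterSheetDistance:
    def test_fresh_build_mean_planes(self, st10_sh4):
        d = T.inter_sheet_distance(st10_sh4.xyz, st10_sh4, 0, 1, "mean_planes")
        assert d == pytest.approx(10.8, abs=1e-6)

    def test_rigid_transform_invariance(self, st10_sh4):
        R, t = random_rigid_transform(RNG)
        moved = st10_sh4.xyz @ R.T + t
        for mode in ("mean_planes", "representative_pair"):
            d0 = T.inter_sheet_distance(st10_sh4.xyz, st10_sh4, 1, 2, mode)
            d1 = T.inter_sheet_distance(moved, st10_sh4, 1, 2, mode)
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_unknown_sheet_rejected(self, st10_sh4):
        with pytest.raises(ValueError):
            T.inter_sheet_distance(st10_sh4.xyz, st10_sh4, 0, 9)


class TestChi1:
    @pytest.mark.parametrize("angle,state", [
        (180.0, "trans"), (-60.0, "gauche-"), (300.0, "gauche-"),
        (60.0, "gauche+"), (119.999, "gauche+"), (120.0, "trans"),
        (239.999, "trans"), (240.0, "gauche-"), (0.0, "gauche+"),
    ])
    def test_classification(self, angle, state):
        assert T.classify_chi1(angle) == state

    @given(st.floats(min_value=-1e4, max_value=1e4,
                     allow_nan=False, allow_infinity=False))
    def test_partition_of_the_circle(self, angle):
        assert T.classify_chi1(angle) in ("trans", "gauche+", "gauche-")

    def test_built_assembly_uniform_trans(self, st10_sh4):
        refs, states = T.chi1_states(st10_sh4.xyz, st10_sh4)
        classified = [s for s in states if s is not None]
        assert classified and set(classified) == {"trans"}

    def test_alternating_rule_reproduced(self):
        tpl = B.StrandTemplate(chi1_rule=("trans", "gauche-"))
        spec = B.AssemblySpec("FYFCFYF", 4, 1, template=tpl)
        asm = B.build_assembly(spec)
        refs, states = T.chi1_states(asm.xyz, asm)
        per_strand = {}
        for (sheet, strand, resid), s in zip(refs, states):
            if s is not None:
                per_strand.setdefault(strand, set()).add(s)
        assert all(len(v) == 1 for v in per_strand.values())
        assert per_strand[0] == {"trans"}
        assert per_strand[1] == {"gauche-"}
        assert per_strand[2] == {"trans"}

    def test_missing_gamma_flagged(self):
        asm = B.build_strand("FAF")   # Ala reduced to C-beta: no gamma atom
        refs, states = T.chi1_states(asm.xyz, asm)
        by_resid = {r[2]: s for r, s in zip(refs, states)}
        assert by_resid[2] is None
        assert by_resid[1] == "trans"


def helical_two_strands():
    """Two parallel alpha-helical chains, 4.75 A apart: in-basin contacts
    but helical dihedrals."""
    def chain(phi, psi, n):
        N = np.zeros(3)
        CA = np.array([1.458, 0, 0])
        C = nerf_place(np.array([0., 1., 0.]), N, CA, 1.525, 111.0, 0.0)
        res = [(N, CA, C)]
        for _ in range(n - 1):
            Np = nerf_place(res[-1][0], res[-1][1], res[-1][2], 1.329, 116.6, psi)
            CAp = nerf_place(res[-1][1], res[-1][2], Np, 1.458, 121.7, 180.0)
            Cp = nerf_place(res[-1][2], Np, CAp, 1.525, 111.0, phi)
            res.append((Np, CAp, Cp))
        return res
    xyz, names, resids, strands = [], [], [], []
    for j in range(2):
        for i, (N, CA, C) in enumerate(chain(-57.0, -47.0, 6)):
            for nm, p in (("N", N), ("CA", CA), ("C", C)):
                names.append(nm)
                xyz.append(p + np.array([0.0, 4.75 * j, 0.0]))
                resids.append(i + 1)
                strands.append(j)
    return toy_assembly(np.array(xyz), names=names, resids=resids,
                        strands=strands)


class TestBetaContent:
    def test_ideal_assembly_is_fully_beta(self, st10_sh4):
        frac, labels = T.beta_content(st10_sh4.xyz, st10_sh4)
        assert frac == 1.0
        assert len(labels) > 0

    def test_helical_chain_scores_zero(self):
        asm = helical_two_strands()
        frac, labels = T.beta_content(asm.xyz, asm)
        assert len(labels) > 0
        assert frac == 0.0

    def test_isolated_strand_has_no_contacts(self, strand):
        frac, labels = T.beta_content(strand.xyz, strand)
        assert frac == 0.0

    def test_rigid_transform_invariance(self, st10_sh4):
        R, t = random_rigid_transform(RNG)
        frac, _ = T.beta_content(st10_sh4.xyz @ R.T + t, st10_sh4)
        assert frac == 1.0


class TestSSMinApproach:
    def test_bonded_variant(self, st10_sh4_ss):
        d = T.ss_min_approach(st10_sh4_ss.xyz, st10_sh4_ss, 1)
        assert d == pytest.approx(2.05, abs=1e-3)

    def test_unbonded_bounded_by_spacing(self, st10_sh4):
        d = T.ss_min_approach(st10_sh4.xyz, st10_sh4, 1)
        assert 0 < d <= 10.8

    def test_two_sulfurs_direct(self):
        a = toy_assembly([[0, 0, 0], [0, 0, 3.5]], names=["SG", "SG"],
                         elements=["S", "S"], sheets=[0, 1],
                         resnames=["CYS", "CYS"])
        assert T.ss_min_approach(a.xyz, a, 0) == pytest.approx(3.5, abs=1e-12)

    def test_absent_when_no_facing_cys(self):
        a = toy_assembly([[0, 0, 0], [0, 0, 3.5]], names=["CA", "SG"],
                         elements=["C", "S"], sheets=[0, 1],
                         resnames=["ALA", "CYS"])
        assert T.ss_min_approach(a.xyz, a, 0) is None


class TestRmsip:
    @staticmethod
    def brute_force_rmsip(A_frames, B_frames, k):
        """Independent oracle: explicit covariance + eigh + double loop."""
        def modes(X):
            X = X.reshape(len(X), -1)
            Xc = X - X.mean(axis=0)
            C = np.zeros((X.shape[1], X.shape[1]))
            for row in Xc:
                C += np.outer(row, row)
            C /= (len(X) - 1)
            vals, vecs = np.linalg.eigh(C)
            order = np.argsort(vals)[::-1]
            return vecs[:, order[:k]]
        U = modes(A_frames)
        V = modes(B_frames)
        acc = 0.0
        for i in range(k):
            for j in range(k):
                acc += float(U[:, i] @ V[:, j]) ** 2
        return np.sqrt(acc / k)

    def test_self_identity(self):
        frames = RNG.normal(size=(30, 12, 3))
        tr = T.Trajectory(frames, np.arange(30.0))
        assert T.rmsip(tr, tr, k=6).rmsip == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_subspaces(self):
        base = RNG.normal(size=(8, 3))
        m1 = np.zeros((4, 8, 3))
        m2 = np.zeros((4, 8, 3))
        for i in range(4):
            m1[i, i, 0] = 1.0
            m2[i, i + 4, 1] = 1.0
        fa = base + np.einsum("fk,kni->fni", RNG.normal(size=(12, 4)), m1)
        fb = base + np.einsum("fk,kni->fni", RNG.normal(size=(12, 4)), m2)
        r = T.rmsip(T.Trajectory(fa, np.arange(12.)),
                    T.Trajectory(fb, np.arange(12.)),
                    k=4, superpose_frames=False)
        assert r.rmsip == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        fa = RNG.normal(size=(15, 20, 3))
        fb = RNG.normal(size=(18, 20, 3))
        r = T.rmsip(T.Trajectory(fa, np.arange(15.)),
                    T.Trajectory(fb, np.arange(18.)),
                    k=5, superpose_frames=False)
        oracle = self.brute_force_rmsip(fa, fb, 5)
        assert r.rmsip == pytest.approx(oracle, abs=1e-8)

    def test_symmetry(self):
        fa = RNG.normal(size=(12, 9, 3))
        fb = RNG.normal(size=(12, 9, 3))
        ta = T.Trajectory(fa, np.arange(12.))
        tb = T.Trajectory(fb, np.arange(12.) + 12.0)
        assert (T.rmsip(ta, tb, k=4).rmsip
                == pytest.approx(T.rmsip(tb, ta, k=4).rmsip, abs=1e-12))

    def test_k_too_large_rejected(self):
        frames = RNG.normal(size=(8, 2, 3))
        tr = T.Trajectory(frames, np.arange(8.0))
        with pytest.raises(ValueError):
            T.rmsip(tr, tr, k=7)    # only 6 modes for 2 atoms

    def test_short_window_rejected(self):
        frames = RNG.normal(size=(4, 5, 3))
        tr = T.Trajectory(frames, np.arange(4.0))
        with pytest.raises(ValueError):
            T.rmsip(tr, tr, k=5)


class TestAverageStructure:
    def test_constant_trajectory(self):
        f = RNG.normal(size=(6, 3))
        tr = T.Trajectory(np.repeat(f[None], 5, axis=0), np.arange(5.0))
        avg = T.average_structure(tr, (0, 5))
        assert np.allclose(avg, f, atol=1e-12)

    def test_two_symmetric_frames(self):
        # displacement orthogonal to all rigid-body motions, so the
        # superposition step is (near-)neutral and the mean is the midpoint
        base = RNG.normal(size=(6, 3))
        delta = 0.02 * RNG.normal(size=(6, 3))
        delta -= delta.mean(axis=0)
        r = base - base.mean(axis=0)
        gens = [np.cross(np.eye(3)[k], r) for k in range(3)]
        for g in gens:
            g = g / np.linalg.norm(g)
            delta -= np.sum(delta * g) * g
        tr = T.Trajectory(np.stack([base - delta, base + delta]),
                          np.arange(2.0))
        avg = T.average_structure(tr, (0, 2))
        assert np.abs(avg - base).max() < 1e-3

    def test_empty_window_rejected(self):
        tr = T.Trajectory(RNG.normal(size=(3, 4, 3)), np.arange(3.0))
        with pytest.raises(ValueError):
            T.average_structure(tr, (2, 2))


class TestTrajectoryType:
    def test_time_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            T.Trajectory(RNG.normal(size=(3, 2, 3)), np.array([0.0, 2.0, 1.0]))

    def test_congruence_enforced(self):
        with pytest.raises(ValueError):
            T.Trajectory(RNG.normal(size=(3, 2, 3)), np.arange(4.0))
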