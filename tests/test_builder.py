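"""Builder geometry: by-construction metrics, interface purity, disulfides."""
import numpy as np
import pytest

from crossbeta import builder as B
from crossbeta._geom import dihedral_deg

from conftest import min_nonbonded_distance


def res_atoms(asm, resid, sheet=0, strand=0):
    m = asm.mask(sheet=sheet, strand=strand, resid=resid)
    return {n: asm.xyz[m][i] for i, n in enumerate(asm.names[m])}


class TestStrand:
    def test_sequence_mapping(self, strand):
        expect = {1: "PHE", 2: "TYR", 3: "PHE", 4: "CYS",
                  5: "PHE", 6: "TYR", 7: "PHE"}
        for resid, resname in expect.items():
            m = strand.mask(resid=resid, strand=0)
            assert set(strand.resnames[m]) == {resname}

    def test_single_residue(self):
        s = B.build_strand("F")
        assert s.n_atoms > 4
        assert set(s.resnames) == {"PHE"}

    def test_ca_repeat_equals_rise(self, strand):
        ca = strand.ca_xyz()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.abs(d - 3.45).max() < 1e-6

    def test_custom_rise_honoured(self):
        tpl = B.StrandTemplate(rise=3.3)
        s = B.build_strand("FYF", template=tpl)
        ca = s.ca_xyz()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.abs(d - 3.3).max() < 1e-6

    def test_backbone_torsions_in_beta_basin(self, strand):
        r2, r3, r4 = (res_atoms(strand, i) for i in (2, 3, 4))
        phi = dihedral_deg(r2["C"], r3["N"], r3["CA"], r3["C"])
        psi = dihedral_deg(r3["N"], r3["CA"], r3["C"], r4["N"])
        assert -180 <= phi <= -90
        assert 90 <= psi <= 180

    def test_alternating_faces(self, strand):
        z = {r: res_atoms(strand, r)["CB"][2] for r in range(1, 8)}
        signs = [np.sign(z[r]) for r in range(1, 8)]
        assert signs == [signs[0] * (-1) ** i for i in range(7)]
        # all Phe one face, all Tyr/Cys the other
        assert len({np.sign(z[r]) for r in (1, 3, 5, 7)}) == 1
        assert len({np.sign(z[r]) for r in (2, 4, 6)}) == 1
        assert np.sign(z[1]) != np.sign(z[2])

    def test_backbone_bond_lengths_sane(self, strand):
        for r in range(1, 8):
            a = res_atoms(strand, r)
            assert 0.8 < np.linalg.norm(a["N"] - a["CA"]) < 2.2
            assert 0.8 < np.linalg.norm(a["CA"] - a["C"]) < 2.2
            nxt = res_atoms(strand, r + 1) if r < 7 else None
            n_next = nxt["N"] if nxt else a.get("NT")
            assert n_next is not None
            assert 0.8 < np.linalg.norm(a["C"] - n_next) < 2.2

    def test_amide_cap_toggle(self):
        capped = B.build_strand("FYF", c_terminal_amide=True)
        free = B.build_strand("FYF", c_terminal_amide=False)
        assert "NT" in capped.names
        assert "NT" not in free.names

    @pytest.mark.parametrize("bad", ["FYXZ", "fyf", "F1F", ""])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(B.BuilderError):
            B.build_strand(bad)

    def test_unsupported_code_named_in_error(self):
        with pytest.raises(B.BuilderError, match="Z"):
            B.build_strand("FYZ")

    def test_template_invariants_enforced(self):
        with pytest.raises(B.BuilderError):
            B.StrandTemplate(phi=-60.0, psi=60.0).validate()
        with pytest.raises(B.BuilderError):
            B.StrandTemplate(rise=4.0).validate()
        with pytest.raises(B.BuilderError):
            B.StrandTemplate(phi=-143.0, psi=135.0).validate()


class TestSheet:
    def test_two_strand_nearest_ca(self, strand):
        sh = B.build_sheet(strand, 2, 4.75)
        ca0 = sh.ca_xyz(strand=0)
        ca1 = sh.ca_xyz(strand=1)
        d = np.linalg.norm(ca0[:, None] - ca1[None, :], axis=2)
        assert abs(d.min() - 4.75) < 1e-6

    def test_single_strand_identity(self, strand):
        sh = B.build_sheet(strand, 1, 4.75)
        assert np.allclose(sh.xyz, strand.xyz)

    def test_fifty_strand_extent(self, strand):
        sh = B.build_sheet(strand, 50, 4.75)
        y = sh.ca_xyz()[:, 1]
        assert abs((y.max() - y.min()) - 49 * 4.75) < 1e-6

    def test_antiparallel_directions(self, strand):
        sh = B.build_sheet(strand, 4, 4.75)
        dirs = []
        for j in range(4):
            ca = sh.ca_xyz(strand=j)
            m = sh.mask(strand=j)
            order = np.argsort(sh.resids[m & (sh.names == "CA")])
            v = ca[order][-1] - ca[order][0]
            dirs.append(v / np.linalg.norm(v))
        for a, b in zip(dirs, dirs[1:]):
            assert np.dot(a, b) < 0

    def test_invalid_counts_rejected(self, strand):
        with pytest.raises(B.BuilderError):
            B.build_sheet(strand, 0)
        with pytest.raises(B.BuilderError):
            B.build_sheet(strand, 2, spacing=-1.0)


class TestAssembly:
    def test_st50_sh2_shape(self, st50_sh2):
        assert st50_sh2.n_sheets == 2
        assert st50_sh2.n_strands(0) == st50_sh2.n_strands(1) == 50

    def test_mean_plane_separation_exact(self, st50_sh2):
        sep = st50_sh2.mean_ca_plane_z(1) - st50_sh2.mean_ca_plane_z(0)
        assert abs(sep - 10.8) < 1e-6

    @pytest.mark.parametrize("fixture,layout", [
        ("st10_sh4", ("dry", "wet", "dry")),
        ("st50_sh2", ("dry",)),
    ])
    def test_interface_purity_census(self, request, fixture, layout):
        """Dry slabs carry zero Tyr/Cys side-chain atoms; wet slabs zero Phe."""
        asm = request.getfixturevalue(fixture)
        for k, lab in enumerate(layout):
            z1 = asm.mean_ca_plane_z(k)
            z2 = asm.mean_ca_plane_z(k + 1)
            sc = asm.sidechain_mask()
            slab = (asm.xyz[:, 2] > z1) & (asm.xyz[:, 2] < z2) & sc
            n_polar = int((slab & np.isin(asm.resnames, ("TYR", "CYS"))).sum())
            n_apolar = int((slab & (asm.resnames == "PHE")).sum())
            if lab == "dry":
                assert n_polar == 0
                assert n_apolar > 0
            else:
                assert n_apolar == 0
                assert n_polar > 0

    def test_single_sheet_degenerate(self):
        spec = B.AssemblySpec("FYFCFYF", 3, 1)
        asm = B.build_assembly(spec)
        assert asm.n_sheets == 1

    def test_incompatible_layout_rejected(self):
        with pytest.raises(B.BuilderError, match="alternat"):
            B.AssemblySpec("FYFCFYF", 4, 3,
                           interface_layout=("dry", "dry")).validate()

    def test_layout_length_enforced(self):
        with pytest.raises(B.BuilderError):
            B.AssemblySpec("FYFCFYF", 4, 3, interface_layout=("dry",)).validate()

    def test_no_steric_collapse(self, st10_sh4):
        assert min_nonbonded_distance(st10_sh4) > 1.8

    def test_disulfide_preconditions(self):
        with pytest.raises(B.BuilderError):
            B.AssemblySpec("FYFYFY", 4, 2, interface_layout=("wet",),
                           disulfide=True).validate()  # no Cys
        with pytest.raises(B.BuilderError):
            B.AssemblySpec("FYFCFYF", 4, 2, interface_layout=("dry",),
                           disulfide=True).validate()  # no wet interface


class TestDisulfides:
    def test_ten_pairs_at_wet_interface(self, st10_sh4_ss):
        assert len(st10_sh4_ss.disulfide_pairs) == 10
        sheets = {(r1[0], r2[0]) for r1, r2 in st10_sh4_ss.disulfide_pairs}
        assert sheets == {(1, 2)}

    def test_ss_bond_lengths(self, st10_sh4_ss):
        for r1, r2 in st10_sh4_ss.disulfide_pairs:
            i1 = np.nonzero(st10_sh4_ss.mask(name="SG", sheet=r1[0],
                                             strand=r1[1], resid=r1[2]))[0][0]
            i2 = np.nonzero(st10_sh4_ss.mask(name="SG", sheet=r2[0],
                                             strand=r2[1], resid=r2[2]))[0][0]
            d = np.linalg.norm(st10_sh4_ss.xyz[i1] - st10_sh4_ss.xyz[i2])
            assert abs(d - 2.05) < 1e-3

    def test_thiol_hydrogens_removed_only_at_interface(self, st10_sh4_ss):
        # paired Cys (sheets 1, 2) lose HG; outer-sheet Cys keep theirs
        for sheet, expected in ((0, 10), (1, 0), (2, 0), (3, 10)):
            n_hg = int((st10_sh4_ss.mask(name="HG", sheet=sheet)).sum())
            assert n_hg == expected

    def test_idempotent(self, st10_sh4_ss):
        again = B.add_disulfides(st10_sh4_ss, interface=1)
        assert len(again.disulfide_pairs) == 10
        assert np.allclose(again.xyz, st10_sh4_ss.xyz)

    def test_no_cysteine_returns_unchanged_with_warning(self):
        spec = B.AssemblySpec("FYFYFY", 4, 2, interface_layout=("wet",))
        asm = B.build_assembly(spec)
        with pytest.warns(UserWarning, match="facing Cys"):
            out = B.add_disulfides(asm, interface=0)
        assert out.disulfide_pairs == []
        assert np.allclose(out.xyz, asm.xyz)
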