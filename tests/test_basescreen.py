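"""Scissile-phosphate location, the general-base distance/orientation screen,
and in-line attack geometry."""

import numpy as np
import pytest

from mgforge.basescreen import (
    inline_attack_geometry,
    locate_scissile_phosphate,
    screen_general_bases,
)
from mgforge.errors import SiteError
from mgforge.metalgeom import AtomRef
from mgforge.structio import Atom, Chain, Residue, Structure


class TestLocate:
    def test_pam_annotation_selects_minus3_minus4_linkage(self, duplex10):
        st, manifest = duplex10
        site = locate_scissile_phosphate(st, "D", pam_position=10)
        assert site.position_3p == manifest.ground_truth["scissile_position_3p"]
        assert site.position_5p == manifest.ground_truth["scissile_position_5p"]
        # the P atom belongs to the 3'-side nucleotide of the cut
        assert site.p_atom.seq_num == site.position_3p

    def test_explicit_positions_match_index_arithmetic(self, duplex10):
        st, _ = duplex10
        by_pam = locate_scissile_phosphate(st, "D", pam_position=10)
        explicit = locate_scissile_phosphate(
            st, "D", explicit_positions=(7, 8))
        assert explicit.p_atom == by_pam.p_atom
        assert explicit.pro_rp == by_pam.pro_rp

    def test_short_strand_rejected(self):
        chain = Chain("D", [
            Residue(i, "DT", [Atom("P", "P", np.array([3.0 * i, 0, 0]))])
            for i in range(1, 4)])
        st = Structure("short", [chain])
        with pytest.raises(SiteError, match="3 nucleotides"):
            locate_scissile_phosphate(st, "D", pam_position=3)

    def test_pro_rp_is_a_non_bridging_oxygen(self, two_metal):
        st, _ = two_metal
        site = locate_scissile_phosphate(st, "C", pam_position=5)
        assert site.pro_rp.atom_name in ("OP1", "OP2")
        # in the designed fixture the bridging oxygen (OP1) is the pro-Rp
        assert site.pro_rp.atom_name == "OP1"


class TestScreen:
    def test_planted_candidates_at_designed_distances(self, two_metal):
        st, manifest = two_metal
        site = locate_scissile_phosphate(st, "C", pam_position=5)
        report = screen_general_bases(st, site)
        by_seq = {c.seq_num: c for c in report.candidates}
        truth = manifest.ground_truth["his_ca_p"]
        assert by_seq[982].d_ca_p == pytest.approx(truth["982"], abs=1e-9)
        assert by_seq[985].d_ca_p == pytest.approx(truth["985"], abs=1e-9)
        assert by_seq[982].passes and by_seq[985].passes
        # the metal-coordinating His points its imidazole at the ion, not the
        # phosphorus, and must fail the orientation criterion
        assert not by_seq[983].passes
        assert {c.seq_num for c in report.passing()} == {982, 985}

    def test_distances_match_direct_recomputation(self, two_metal):
        st, _ = two_metal
        site = locate_scissile_phosphate(st, "C", pam_position=5)
        report = screen_general_bases(st, site)
        p = site.p_atom.resolve(st).coords
        for cand in report.candidates:
            ca = st.get_atom(cand.chain_id, cand.seq_num, "CA").coords
            assert cand.d_ca_p == pytest.approx(
                float(np.linalg.norm(ca - p)), abs=1e-9)

    def test_rotated_imidazole_fails_orientation(self, two_metal):
        st, _ = two_metal
        flipped = st.copy()
        his = flipped.get_residue("A", 982)
        ca = his.atom("CA").coords
        nd1 = his.atom("ND1")
        # reflect Nd1 through CA: imidazole now points away from the P
        nd1.coords = 2 * ca - nd1.coords
        site = locate_scissile_phosphate(flipped, "C", pam_position=5)
        report = screen_general_bases(flipped, site)
        cand = next(c for c in report.candidates if c.seq_num == 982)
        assert not cand.passes
        assert cand.orientation_angle > 90.0

    def test_enlarging_radius_never_removes_candidates(self, two_metal):
        st, _ = two_metal
        site = locate_scissile_phosphate(st, "C", pam_position=5)
        seen: set[int] = set()
        for radius in (7.0, 8.0, 10.0, 12.0):
            now = {c.seq_num for c in
                   screen_general_bases(st, site, radius=radius).candidates}
            assert seen <= now
            seen = now

    def test_screen_invariant_under_rigid_motion(self, two_metal, rng):
        st, _ = two_metal
        t = np.radians(31.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(t), -np.sin(t)],
                      [0, np.sin(t), np.cos(t)]])
        moved = st.copy()
        moved.transform(R, np.array([5.0, -9.0, 2.0]))
        s1 = locate_scissile_phosphate(st, "C", pam_position=5)
        s2 = locate_scissile_phosphate(moved, "C", pam_position=5)
        r1 = screen_general_bases(st, s1)
        r2 = screen_general_bases(moved, s2)
        for c1, c2 in zip(r1.candidates, r2.candidates):
            assert c1.seq_num == c2.seq_num
            assert c2.d_ca_p == pytest.approx(c1.d_ca_p, abs=1e-9)
            # arccos loses precision near 0 deg; 1e-4 deg is still exact for
            # any scientific purpose
            assert c2.orientation_angle == pytest.approx(c1.orientation_angle,
                                                         abs=1e-4)

    def test_hnh_state_ranks_the_canonical_base_first(self, oct_site):
        """On the one-metal model the 7.8 A His is the nearest passing His."""
        st, manifest = oct_site
        site = locate_scissile_phosphate(st, "T", pam_position=5)
        report = screen_general_bases(st, site)
        passing = report.passing()
        assert passing and passing[0].seq_num == 840
        assert passing[0].d_ca_p == pytest.approx(
            manifest.ground_truth["his840_ca_p"], abs=1e-9)


class TestInlineGeometry:
    def test_collinear_arrangement_scores_180(self, two_metal):
        st, _ = two_metal
        fixture = st.copy()
        site = locate_scissile_phosphate(fixture, "C", pam_position=5)
        p = site.p_atom.resolve(fixture).coords
        o3 = site.o3_prime.resolve(fixture).coords
        # put a water exactly opposite the leaving group
        w = fixture.get_atom("W", 1, "O")
        w.coords = p - 1.8 * (o3 - p) / np.linalg.norm(o3 - p)
        geom = inline_attack_geometry(fixture, site, AtomRef("W", 1, "O"))
        assert geom.inline_angle == pytest.approx(180.0, abs=1e-6)
        assert geom.deviation_from_inline == pytest.approx(0.0, abs=1e-6)
        assert geom.nucleophile_p_distance == pytest.approx(1.8, abs=1e-9)

    def test_perpendicular_water_deviates_by_90(self, two_metal):
        st, _ = two_metal
        fixture = st.copy()
        site = locate_scissile_phosphate(fixture, "C", pam_position=5)
        p = site.p_atom.resolve(fixture).coords
        o3 = site.o3_prime.resolve(fixture).coords
        axis = (o3 - p) / np.linalg.norm(o3 - p)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        fixture.get_atom("W", 1, "O").coords = p + 2.0 * perp
        geom = inline_attack_geometry(fixture, site, AtomRef("W", 1, "O"))
        assert geom.deviation_from_inline == pytest.approx(90.0, abs=1e-6)

    def test_angle_invariant_under_rigid_motion(self, two_metal):
        st, _ = two_metal
        site = locate_scissile_phosphate(st, "C", pam_position=5)
        nuc = AtomRef("W", 1, "O")
        base = inline_attack_geometry(st, site, nuc)
        t = np.radians(57.0)
        R = np.array([[np.cos(t), -np.sin(t), 0],
                      [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        moved = st.copy()
        moved.transform(R, np.array([-3.0, 8.0, 1.0]))
        site2 = locate_scissile_phosphate(moved, "C", pam_position=5)
        again = inline_attack_geometry(moved, site2, nuc)
        assert again.inline_angle == pytest.approx(base.inline_angle, abs=1e-7)
        assert again.nucleophile_p_distance == pytest.approx(
            base.nucleophile_p_distance, abs=1e-9)
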