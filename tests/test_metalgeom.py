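"""Coordination shells, octahedricity scoring (against the 6!-permutation
oracle), distance tables and shell classification."""

import numpy as np
import pytest

from mgforge.errors import GeometryError
from mgforge.metalgeom import (
    AtomRef,
    CoordinationShell,
    classify_shells,
    coordination_shell,
    find_metal_ions,
    octahedricity,
    octahedricity_bruteforce,
    site_distance_table,
)
from mgforge.structio import Atom, Chain, Residue, Structure
from mgforge.basescreen import locate_scissile_phosphate


def rotate_structure(st, R, t):
    out = st.copy()
    out.transform(R, t)
    return out


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def brute_force_shell(st, metal_ref, cutoff):
    """Independent all-atoms distance scan."""
    center = metal_ref.resolve(st).coords
    found = []
    for c in st.chains:
        for r in c.residues:
            for a in r.atoms:
                ref = AtomRef(c.chain_id, r.seq_num, a.name, r.icode)
                if ref == metal_ref or a.element.upper() not in ("N", "O", "S"):
                    continue
                d = float(np.linalg.norm(a.coords - center))
                if d <= cutoff:
                    found.append((round(d, 9), str(ref)))
    return sorted(found)


class TestFindIons:
    def test_two_metal_fixture_has_two_mg(self, two_metal):
        st, _ = two_metal
        assert len(find_metal_ions(st, "MG")) == 2

    def test_ion_free_structure_gives_empty_list(self, duplex10):
        st, _ = duplex10
        assert find_metal_ions(st, "MG") == []

    def test_element_filter_excludes_other_metals(self, two_metal):
        st, _ = two_metal
        st = st.copy()
        st.chain("M").residues.append(
            Residue(3, "ZN", [Atom("ZN", "ZN", np.array([20.0, 0, 0]))]))
        assert len(find_metal_ions(st, "MG")) == 2
        assert len(find_metal_ions(st, "ZN")) == 1


class TestCoordinationShell:
    def test_ideal_octahedron_six_ligands_at_design_distance(self, oct_site):
        st, manifest = oct_site
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        assert shell.coordination_number == 6
        for lig in shell.ligands:
            assert lig.distance == pytest.approx(2.0, abs=1e-9)

    def test_first_shell_composition_of_two_metal_site(self, two_metal):
        st, _ = two_metal
        residues = set()
        for ref in find_metal_ions(st, "MG"):
            for lig in coordination_shell(st, ref, 2.6).ligands:
                if lig.ref.chain_id == "A":
                    residues.add(lig.ref.seq_num)
        assert residues == {10, 762, 983, 986}

    def test_ligand_classification(self, two_metal):
        st, _ = two_metal
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        classes = {str(l.ref): l.ligand_class for l in shell.ligands}
        assert classes["A/983/ND1"] == "imidazole N"
        assert classes["A/10/OD1"] == "carboxylate O"
        assert classes["C/3/OP1"] == "phosphate O"
        assert classes["W/1/O"] == "water O"

    def test_isolated_metal_has_empty_shell(self):
        st = Structure("iso", [Chain("M", [
            Residue(1, "MG", [Atom("MG", "MG", np.zeros(3))])])])
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        assert shell.coordination_number == 0

    @pytest.mark.parametrize("cutoff", [2.2, 2.6, 4.0, 6.0])
    def test_matches_brute_force_scan(self, two_metal, cutoff):
        st, _ = two_metal
        for metal in find_metal_ions(st, "MG"):
            shell = coordination_shell(st, metal, cutoff)
            got = sorted((round(l.distance, 9), str(l.ref)) for l in shell.ligands)
            assert got == brute_force_shell(st, metal, cutoff)


class TestOctahedricity:
    def test_perfect_octahedron_scores_zero(self, oct_site):
        st, _ = oct_site
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        score = octahedricity(shell, st)
        assert score.complete
        assert score.angular_deviation == pytest.approx(0.0, abs=1e-9)
        assert score.distance_spread == pytest.approx(0.0, abs=1e-9)

    def test_matches_permutation_oracle_when_distorted(self, oct_site):
        st, _ = oct_site
        st = st.copy()
        # push one water so a cis angle opens to ~100 degrees
        w = st.get_atom("W", 1, "O")
        w.coords = 2.0 * np.array([-np.cos(np.radians(10)), 0, np.sin(np.radians(10))])
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        score = octahedricity(shell, st)
        assert score.angular_deviation > 1.0
        assert score.angular_deviation == pytest.approx(
            octahedricity_bruteforce(shell, st), abs=1e-9)

    def test_five_coordinate_site_flagged_incomplete(self, oct_site):
        st, _ = oct_site
        st = st.copy()
        st.chain("W").residues.pop()  # drop one water
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        assert shell.coordination_number == 5
        assert not octahedricity(shell, st).complete

    def test_invariant_under_rigid_motion_and_relabeling(self, oct_site, rng):
        st, _ = oct_site
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        base = octahedricity(shell, st).angular_deviation
        moved = rotate_structure(st, random_rotation(rng), rng.normal(size=3) * 10)
        shell2 = coordination_shell(moved, AtomRef("M", 1, "MG"), 2.6)
        assert octahedricity(shell2, moved).angular_deviation == \
            pytest.approx(base, abs=1e-7)
        shuffled = CoordinationShell(shell.metal, list(reversed(shell.ligands)))
        assert octahedricity(shuffled, st).angular_deviation == \
            pytest.approx(base, abs=1e-9)

    def test_score_is_continuous_in_ligand_position(self, oct_site):
        st, _ = oct_site
        st = st.copy()
        shell = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        before = octahedricity(shell, st).angular_deviation
        st.get_atom("W", 1, "O").coords += [0.0, 0.01, 0.0]
        shell2 = coordination_shell(st, AtomRef("M", 1, "MG"), 2.6)
        after = octahedricity(shell2, st).angular_deviation
        assert abs(after - before) <= 0.5

    def test_fewer_than_two_ligands_raise(self, oct_site):
        st, _ = oct_site
        shell = CoordinationShell(AtomRef("M", 1, "MG"), [])
        with pytest.raises(GeometryError):
            octahedricity(shell, st)


class TestDistanceTable:
    def test_designed_two_metal_distances(self, two_metal, two_metal_def):
        st, manifest = two_metal
        site = two_metal_def
        table = site_distance_table(st, site)
        assert table.value("MgA-MgB") == pytest.approx(
            manifest.ground_truth["designed_separation"], abs=1e-9)
        for label in table.labels():
            if label == "MgA-MgB" or label.startswith("ASP986:OD2"):
                continue  # ion-ion row; distal carboxylate oxygen
            if label.endswith("-MgA") or label.endswith("-MgB"):
                assert table.value(label) == pytest.approx(2.0, abs=1e-9)

    def test_his_ca_rows_present_with_scissile_site(self, two_metal, two_metal_def):
        st, _ = two_metal
        site = two_metal_def
        site.scissile = locate_scissile_phosphate(st, "C", pam_position=5)
        table = site_distance_table(st, site)
        assert any(lab.startswith("HIS983:CA-P") for lab in table.labels())
        site.scissile = None

    def test_table_invariant_under_rigid_motion(self, two_metal, two_metal_def, rng):
        st, _ = two_metal
        moved = rotate_structure(st, random_rotation(rng), rng.normal(size=3) * 20)
        t1 = site_distance_table(st, two_metal_def)
        t2 = site_distance_table(moved, two_metal_def)
        for lab in t1.labels():
            assert t2.value(lab) == pytest.approx(t1.value(lab), abs=1e-8)

    def test_distances_symmetric(self, two_metal, two_metal_def):
        st, _ = two_metal
        table = site_distance_table(st, two_metal_def)
        for _, a, b, d in table.rows:
            pa = a.resolve(st).coords
            pb = b.resolve(st).coords
            assert d == pytest.approx(float(np.linalg.norm(pb - pa)), abs=1e-12)


class TestClassifyShells:
    def test_ruvc_like_first_shell(self, two_metal, two_metal_def):
        st, _ = two_metal
        first, second = classify_shells(st, two_metal_def)
        assert {s for _, s in first} == {10, 762, 983, 986}
        assert {s for _, s in second} >= {982, 985}

    def test_hnh_like_second_shell_holds_the_general_base(self, oct_site,
                                                          oct_site_def):
        st, _ = oct_site
        first, second = classify_shells(st, oct_site_def)
        assert {s for _, s in first} == {839, 863}
        assert ("A", 840) in second

    def test_isolated_ion_gives_empty_shells(self):
        st = Structure("iso", [Chain("M", [
            Residue(1, "MG", [Atom("MG", "MG", np.zeros(3))])])])
        from mgforge.metalgeom import MetalSiteDefinition
        site = MetalSiteDefinition("custom", [("A", "MG", ("M", 1))], [])
        first, second = classify_shells(st, site)
        assert first == set() and second == set()
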