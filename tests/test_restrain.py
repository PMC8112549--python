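"""Restraint construction, the harmonic energy (analytic gradient vs finite
differences), monotone minimization, and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgforge.errors import PlacementError, RestraintError
from mgforge.metalgeom import AtomRef, coordination_shell, octahedricity
from mgforge.restrain import (
    AngleRestraint,
    DistanceRestraint,
    RestraintSet,
    build_restraints,
    place_waters,
    refine,
    restraint_energy,
    restraint_gradient,
)
from mgforge.synthfix import (
    make_octahedral_site,
    make_two_metal_site,
    octahedral_site_definition,
    perturb_structure,
    two_metal_site_definition,
)


class TestBuildRestraints:
    def test_one_metal_counts_and_ligand_set(self, oct_site, oct_site_def):
        structure, _ = oct_site
        rset = build_restraints(structure, oct_site_def, "one_metal")
        assert len(rset.distances) == 6
        assert len(rset.angles) == 12
        ligands = {str(r.atom_a) for r in rset.distances}
        assert ligands == {"A/839/OD1", "A/863/OD1", "T/3/OP1", "T/4/OP1",
                           "W/1/O", "W/2/O"}
        assert all(r.target == pytest.approx(2.0) for r in rset.distances)
        assert all(a.target == pytest.approx(90.0) for a in rset.angles)

    def test_two_metal_counts_include_his_to_ion_a(self, two_metal, two_metal_def):
        structure, _ = two_metal
        rset = build_restraints(structure, two_metal_def, "two_metal")
        assert len(rset.distances) == 12
        assert len(rset.angles) == 24
        his = [r for r in rset.distances if str(r.atom_a) == "A/983/ND1"]
        assert len(his) == 1
        # ion A is the His-proximal ion
        assert his[0].atom_b == AtomRef("M", 1, "MG")
        # the bridging pro-Rp oxygen is restrained to both ions
        bridge_targets = {str(r.atom_b) for r in rset.distances
                          if str(r.atom_a) == "C/3/OP1"}
        assert bridge_targets == {"M/1/MG", "M/2/MG"}

    def test_mutated_his_raises_restraint_error(self, two_metal, two_metal_def):
        structure, _ = two_metal
        broken = structure.copy()
        res = broken.get_residue("A", 983)
        res.res_name = "ALA"
        res.atoms = [a for a in res.atoms if a.name not in ("ND1", "CG")]
        with pytest.raises(RestraintError, match="983"):
            build_restraints(broken, two_metal_def, "two_metal")


class TestEnergy:
    def test_satisfied_restraints_have_zero_energy(self, oct_site, oct_site_def):
        structure, _ = oct_site
        rset = build_restraints(structure, oct_site_def, "one_metal")
        total, breakdown = restraint_energy(structure, rset)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert sum(breakdown.values()) == pytest.approx(total, abs=1e-9)

    def test_single_stretched_restraint_closed_form(self, oct_site):
        structure, _ = oct_site
        moved = structure.copy()
        moved.get_atom("W", 1, "O").coords = np.array([-3.0, 0.0, 0.0])
        rset = RestraintSet(distances=[DistanceRestraint(
            AtomRef("W", 1, "O"), AtomRef("M", 1, "MG"),
            target=2.0, force_constant=1.0)], k_rep=0.0 + 1e-12)
        rset.k_rep = 1e-12  # isolate the single distance term
        total, breakdown = restraint_energy(moved, rset)
        assert breakdown["distance"] == pytest.approx(1.0, abs=1e-9)

    def test_energy_invariant_under_rigid_motion(self, two_metal, two_metal_def, rng):
        structure, _ = two_metal
        pert = perturb_structure(structure, 0.2, seed=5)
        rset = build_restraints(pert, two_metal_def, "two_metal")
        e0, _ = restraint_energy(pert, rset)
        t = np.radians(73.0)
        R = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                      [-np.sin(t), 0, np.cos(t)]])
        moved = pert.copy()
        moved.transform(R, np.array([11.0, -4.0, 6.0]))
        e1, _ = restraint_energy(moved, rset)
        assert e1 == pytest.approx(e0, abs=1e-9 * max(e0, 1.0))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), sigma=st.floats(0.05, 0.6))
    def test_analytic_gradient_matches_finite_differences(self, seed, sigma):
        structure, _ = make_octahedral_site(sigma=sigma, seed=seed)
        rset = build_restraints(structure, octahedral_site_definition(), "one_metal")
        grad = restraint_gradient(structure, rset)
        rng = np.random.default_rng(seed)
        flat_refs = [(c.chain_id, r.seq_num, a.name)
                     for c, r, a in structure.iter_atoms()]
        mobile = {str(m) for m in rset.mobile}
        h = 1e-6
        for _ in range(6):
            i = int(rng.integers(len(flat_refs)))
            cid, seq, name = flat_refs[i]
            if f"{cid}/{seq}/{name}" not in mobile:
                continue
            axis = int(rng.integers(3))
            for sgn, store in ((1, "plus"), (-1, "minus")):
                trial = structure.copy()
                trial.get_atom(cid, seq, name).coords[axis] += sgn * h
                e, _ = restraint_energy(trial, rset)
                if sgn == 1:
                    e_plus = e
                else:
                    e_minus = e
            fd = (e_plus - e_minus) / (2 * h)
            scale = max(abs(fd), 1.0)
            assert grad[i, axis] == pytest.approx(fd, abs=1e-4 * scale)


class TestRefine:
    def test_start_at_minimum_leaves_coordinates_unchanged(self, two_metal,
                                                           two_metal_def):
        structure, _ = two_metal
        rset = build_restraints(structure, two_metal_def, "two_metal")
        result = refine(structure, rset)
        assert result.n_iterations == 0
        np.testing.assert_allclose(result.structure.coords(), structure.coords(),
                                   atol=1e-9)

    def test_perturbed_octahedron_recovers_target_distances(self):
        structure, _ = make_octahedral_site(sigma=0.5, seed=42)
        rset = build_restraints(structure, octahedral_site_definition(), "one_metal")
        result = refine(structure, rset)
        assert result.converged
        assert max(result.residuals.values()) < 0.05
        dists = [2.0 + r for r in result.residuals.values()]
        assert np.mean(dists) == pytest.approx(2.0, abs=0.01)

    def test_energy_trajectory_monotone_non_increasing(self):
        structure, _ = make_octahedral_site(sigma=0.5, seed=3)
        rset = build_restraints(structure, octahedral_site_definition(), "one_metal")
        result = refine(structure, rset)
        traj = result.energy_trajectory
        assert len(traj) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(traj, traj[1:]))

    def test_only_mobile_atoms_move(self):
        structure, _ = make_octahedral_site(sigma=0.4, seed=9)
        rset = build_restraints(structure, octahedral_site_definition(),
                                "one_metal", mobile_radius=3.0)
        mobile = {str(m) for m in rset.mobile}
        result = refine(structure, rset)
        for c, r, a in structure.iter_atoms():
            key = f"{c.chain_id}/{r.seq_num}/{a.name}"
            after = result.structure.get_atom(c.chain_id, r.seq_num, a.name).coords
            if key not in mobile:
                np.testing.assert_allclose(after, a.coords, atol=1e-12)

    def test_two_metal_spacing_emerges_without_ion_ion_restraint(
            self, two_metal, two_metal_def):
        structure, manifest = two_metal
        rset = build_restraints(structure, two_metal_def, "two_metal")
        pair_atoms = {frozenset((str(r.atom_a), str(r.atom_b)))
                      for r in rset.distances}
        assert frozenset(("M/1/MG", "M/2/MG")) not in pair_atoms
        pert = perturb_structure(structure, 0.3, seed=11,
                                 center=np.array([1.65, 0, 0]), radius=8.0)
        result = refine(pert, build_restraints(pert, two_metal_def, "two_metal"))
        d = np.linalg.norm(result.structure.get_atom("M", 1, "MG").coords -
                           result.structure.get_atom("M", 2, "MG").coords)
        assert 3.0 < d < 4.0

    def test_parameter_recovery_rate_over_seeds(self):
        """>= 95/100 seeded perturbations recover distances and near-perfect
        octahedral geometry."""
        hits = 0
        for seed in range(100):
            structure, _ = make_octahedral_site(sigma=0.5, seed=seed)
            rset = build_restraints(structure, octahedral_site_definition(),
                                    "one_metal")
            result = refine(structure, rset)
            if max(result.residuals.values()) >= 0.05:
                continue
            shell = coordination_shell(result.structure, AtomRef("M", 1, "MG"), 2.6)
            if shell.coordination_number != 6:
                continue
            if octahedricity(shell, result.structure).angular_deviation < 5.0:
                hits += 1
        assert hits >= 95


class TestPlaceWaters:
    def test_four_coordinate_ion_gets_two_waters(self, oct_site, oct_site_def):
        structure, _ = oct_site
        dry = structure.copy()
        dry.chains = [c for c in dry.chains if c.chain_id != "W"]
        wet = place_waters(dry, oct_site_def)
        assert wet.n_atoms == dry.n_atoms + 2
        for res in wet.chain("W").residues:
            d = np.linalg.norm(res.atom("O").coords -
                               wet.get_atom("M", 1, "MG").coords)
            assert d == pytest.approx(2.0, abs=1e-6)

    def test_placed_waters_complete_a_clean_octahedron(self, oct_site, oct_site_def):
        structure, _ = oct_site
        dry = structure.copy()
        dry.chains = [c for c in dry.chains if c.chain_id != "W"]
        wet = place_waters(dry, oct_site_def)
        shell = coordination_shell(wet, AtomRef("M", 1, "MG"), 2.6)
        assert shell.coordination_number == 6
        assert octahedricity(shell, wet).angular_deviation < 1e-5

    def test_saturated_ion_raises_placement_error(self, oct_site, oct_site_def):
        structure, _ = oct_site
        with pytest.raises(PlacementError):
            place_waters(structure, oct_site_def)


def test_restraint_value_validation():
    a, b = AtomRef("A", 1, "X"), AtomRef("A", 2, "Y")
    with pytest.raises(ValueError):
        DistanceRestraint(a, b, target=-1.0)
    with pytest.raises(ValueError):
        AngleRestraint(a, b, AtomRef("A", 3, "Z"), target=200.0)
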