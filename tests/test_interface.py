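"""Hydrogen bonds, salt bridges, SASA and interaction energy."""

import numpy as np
import pytest

import mechbond as mb
from mechbond.interface import _sphere_points
from mechbond.params import COULOMB_K, VDW_RADII

from helpers import (
    brute_force_hbonds,
    random_interface_structure,
    simple_pair_structure,
)


class TestDetectHBonds:
    def test_inside_both_cutoffs_is_one_event(self):
        s, a, b = simple_pair_structure(2.9, 10.0)
        events = mb.detect_hbonds(s.coords, a, b)
        assert len(events) == 1
        e = events[0]
        assert e.donor == ("A", 1, "N") and e.acceptor == ("B", 1, "O")
        assert e.da_distance == pytest.approx(2.9, abs=1e-9)
        assert e.dha_deviation == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize(
        "distance,deviation,n",
        [(3.6, 10.0, 0), (3.4, 31.0, 0), (3.4, 29.0, 1), (2.0, 0.0, 1)],
    )
    def test_cutoff_boundaries(self, distance, deviation, n):
        s, a, b = simple_pair_structure(distance, deviation)
        assert len(mb.detect_hbonds(s.coords, a, b)) == n

    def test_angle_convention_is_deviation_from_linearity(self):
        # a perfectly linear D-H-A arrangement has deviation 0, angle 180
        s, a, b = simple_pair_structure(3.0, 0.0)
        [e] = mb.detect_hbonds(s.coords, a, b)
        assert e.dha_deviation == pytest.approx(0.0, abs=1e-9)

    def test_hydrogen_free_structure_raises(self):
        atoms = [
            mb.Atom(1, "N", "N", 1, "RES", "A", [0, 0, 0]),
            mb.Atom(2, "O", "O", 1, "RES", "B", [0, 2.9, 0]),
        ]
        s = mb.Structure(atoms)
        with pytest.raises(mb.MissingHydrogenError):
            mb.detect_hbonds(
                s.coords,
                mb.Selection(s, (0,), "A"),
                mb.Selection(s, (1,), "B"),
            )

    def test_overlapping_selections_rejected(self, two_bond_trajectory):
        _, s, _ = two_bond_trajectory
        sel = mb.select(s, "A", s.chains["A"])
        with pytest.raises(mb.SelectionError, match="overlap"):
            mb.detect_hbonds(s.coords, sel, sel)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        s = random_interface_structure(rng, n_residues=15)
        sel_a = mb.select(s, "A", s.chains["A"])
        sel_b = mb.select(s, "B", s.chains["B"])
        for _ in range(5):
            frame = s.coords + rng.normal(0, 1.0, size=s.coords.shape)
            got = {
                (e.donor, e.hydrogen, e.acceptor)
                for e in mb.detect_hbonds(frame, sel_a, sel_b)
            }
            assert got == brute_force_hbonds(frame, sel_a, sel_b)


class TestSaltBridges:
    def _structure(self, resname, oname, basename, basatom, dist):
        atoms = [
            mb.Atom(1, oname, "O", 10, resname, "A", [0.0, 0.0, 0.0]),
            mb.Atom(2, basatom, "N", 20, basename, "B", [dist, 0.0, 0.0]),
        ]
        s = mb.Structure(atoms)
        return s, mb.Selection(s, (0,), "A"), mb.Selection(s, (1,), "B")

    def test_glu_lys_contact(self):
        s, a, b = self._structure("GLU", "OE1", "LYS", "NZ", 3.5)
        contacts = mb.detect_salt_bridges(s.coords, a, b)
        assert contacts == [(("A", 10), ("B", 20), pytest.approx(3.5))]

    def test_serine_oxygen_is_not_acidic(self):
        s, a, b = self._structure("SER", "OG", "LYS", "NZ", 3.5)
        assert mb.detect_salt_bridges(s.coords, a, b) == []

    def test_beyond_cutoff(self):
        s, a, b = self._structure("GLU", "OE1", "LYS", "NZ", 4.2)
        assert mb.detect_salt_bridges(s.coords, a, b) == []

    def test_multiple_atom_contacts_report_one_pair(self):
        atoms = [
            mb.Atom(1, "OD1", "O", 10, "ASP", "A", [0.0, 0.0, 0.0]),
            mb.Atom(2, "OD2", "O", 10, "ASP", "A", [1.0, 0.0, 0.0]),
            mb.Atom(3, "NH1", "N", 20, "ARG", "B", [2.0, 2.0, 0.0]),
        ]
        s = mb.Structure(atoms)
        contacts = mb.detect_salt_bridges(
            s.coords, mb.Selection(s, (0, 1), "A"), mb.Selection(s, (2,), "B")
        )
        assert len(contacts) == 1
        # minimum O-N distance is reported
        assert contacts[0][2] == pytest.approx(np.hypot(1.0, 2.0))


class TestOccupancyAndCounts:
    def _toggled_trajectory(self, present_frames, total=100):
        s, a, b = simple_pair_structure(2.9, 10.0)
        frames = np.repeat(s.coords[None], total, axis=0)
        for k in range(total):
            if k not in present_frames:
                frames[k, 2, 1] = 5.0  # move the acceptor out of range
        return mb.Trajectory(s, frames), a, b

    def test_thirty_of_hundred_frames(self):
        traj, a, b = self._toggled_trajectory(set(range(30)))
        table = mb.occupancy(traj, a, b)
        assert table.rows[0].occupancy == pytest.approx(0.30)

    def test_adding_absent_frames_decreases_occupancy(self):
        t1, a, b = self._toggled_trajectory(set(range(30)), total=50)
        t2, a2, b2 = self._toggled_trajectory(set(range(30)), total=100)
        o1 = mb.occupancy(t1, a, b).rows[0].occupancy
        o2 = mb.occupancy(t2, a2, b2).rows[0].occupancy
        assert o2 < o1

    def test_count_series_counts_planted_bonds(self, two_bond_trajectory):
        cfg, s, _ = two_bond_trajectory
        always = mb.GeneratorConfig(
            n_residues_per_chain=3, n_frames=20,
            bond_specs=[
                mb.BondSpec(("A", 1, "N", "H"), ("B", 1, "O"), "steady", 1.0),
                mb.BondSpec(("A", 2, "N", "H"), ("B", 2, "O"), "steady", 1.0),
            ],
        )
        st = mb.generate_complex(always)
        t = mb.generate_trajectory(st, always, 0.0)
        sel_a = mb.select(st, "A", st.chains["A"])
        sel_b = mb.select(st, "B", st.chains["B"])
        assert mb.hbond_count_series(t, sel_a, sel_b).tolist() == [2] * 20

    def test_mean_count_equals_sum_of_occupancies(self, two_bond_trajectory):
        cfg, s, traj = two_bond_trajectory
        sel_a = mb.select(s, "A", s.chains["A"])
        sel_b = mb.select(s, "B", s.chains["B"])
        n_hb = mb.hbond_count_series(traj, sel_a, sel_b)
        expected = sum(
            mb.occupancy_curve(spec, 50.0) for spec in cfg.bond_specs
        )
        sigma = np.sqrt(
            sum(
                mb.occupancy_curve(sp, 50.0) * (1 - mb.occupancy_curve(sp, 50.0))
                for sp in cfg.bond_specs
            )
            / len(traj)
        )
        assert abs(n_hb.mean() - expected) <= 3 * sigma


class TestSasa:
    def _single_atom(self, element="C"):
        atoms = [mb.Atom(1, element, element, 1, "RES", "A", [0.0, 0.0, 0.0])]
        s = mb.Structure(atoms)
        return s, mb.Selection(s, (0,), "atom")

    def test_isolated_atom_matches_analytic_sphere(self):
        s, sel = self._single_atom("C")
        r = VDW_RADII["C"] + 1.4
        analytic = 4 * np.pi * r * r
        assert mb.sasa(s.coords, sel) == pytest.approx(analytic, rel=0.01)
        assert analytic == pytest.approx(120.76, abs=0.01)

    def test_fully_enclosed_atom_has_zero_area(self):
        pts = _sphere_points(30) * 2.0
        atoms = [mb.Atom(1, "C", "C", 1, "RES", "A", [0.0, 0.0, 0.0])]
        atoms += [
            mb.Atom(i + 2, "C", "C", i + 2, "RES", "A", p)
            for i, p in enumerate(pts)
        ]
        s = mb.Structure(atoms)
        only_center = mb.Selection(s, tuple(range(len(atoms))), "all")
        area_center = 0.0
        # accessible fraction of the central atom: recompute via the public
        # API by differencing the shell-only and full SASA
        shell = mb.Selection(s, tuple(range(1, len(atoms))), "shell")
        area_center = mb.sasa(s.coords, only_center) - mb.sasa(s.coords, shell)
        r = VDW_RADII["C"] + 1.4
        assert area_center <= 0.02 * 4 * np.pi * r * r

    def test_two_atom_system_matches_dense_quadrature(self):
        atoms = [
            mb.Atom(1, "C", "C", 1, "RES", "A", [0.0, 0.0, 0.0]),
            mb.Atom(2, "O", "O", 2, "RES", "A", [1.8, 0.4, -0.2]),
        ]
        s = mb.Structure(atoms)
        sel = mb.Selection(s, (0, 1), "pair")
        coarse = mb.sasa(s.coords, sel, n_sphere_points=960)
        dense = mb.sasa(s.coords, sel, n_sphere_points=10000)
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_matches_biotite_reference(self):
        """Independent cross-check against biotite's Shrake-Rupley."""
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 8, size=(12, 3))
        atoms = [
            mb.Atom(i + 1, "C", "C", i + 1, "RES", "A", c)
            for i, c in enumerate(coords)
        ]
        s = mb.Structure(atoms)
        mine = mb.sasa(
            s.coords, mb.Selection(s, tuple(range(12)), "all"),
            n_sphere_points=2000,
        )
        arr = biotite_struct.AtomArray(12)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 12)
        ref = float(
            np.sum(
                biotite_struct.sasa(
                    arr, probe_radius=1.4, point_number=2000,
                    vdw_radii="Single",
                )
            )
        )
        # vdw tables differ slightly (1.70 vs biotite's single-atom 1.70 C)
        assert mine == pytest.approx(ref, rel=0.03)

    def test_unknown_element_is_reported(self):
        s, sel = self._single_atom("XX")
        with pytest.raises(mb.ParameterError, match="XX"):
            mb.sasa(s.coords, sel)


class TestBuriedSasa:
    def _two_chain(self, separation):
        atoms = [
            mb.Atom(1, "C", "C", 1, "RES", "A", [0.0, 0.0, 0.0]),
            mb.Atom(2, "C", "C", 1, "RES", "B", [separation, 0.0, 0.0]),
        ]
        s = mb.Structure(atoms)
        return s, mb.Selection(s, (0,), "A"), mb.Selection(s, (1,), "B")

    def test_separated_chains_bury_nothing(self):
        s, a, b = self._two_chain(100.0)
        assert mb.buried_sasa(s.coords, a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_partners(self):
        s, a, b = self._two_chain(4.0)
        assert mb.buried_sasa(s.coords, a, b) == mb.buried_sasa(s.coords, b, a)

    def test_touching_spheres_match_spherical_cap_formula(self):
        # two equal solvent-extended spheres of radius R at distance d bury
        # two caps of height h = R - d/2, area 2*pi*R*h each
        d = 4.0
        R = VDW_RADII["C"] + 1.4
        s, a, b = self._two_chain(d)
        analytic = 2 * 2 * np.pi * R * (R - d / 2)
        assert mb.buried_sasa(s.coords, a, b) == pytest.approx(
            analytic, rel=0.02
        )

    def test_overlapping_selections_rejected(self):
        s, a, b = self._two_chain(4.0)
        both = mb.Selection(s, (0, 1), "both")
        with pytest.raises(mb.SelectionError):
            mb.buried_sasa(s.coords, a, both)


class TestInteractionEnergy:
    def _pair(self, r, qa=1.0, qb=-1.0, eps=0.0, rmin_half=1.0):
        atoms = [
            mb.Atom(1, "X1", "C", 1, "RES", "A", [0.0, 0.0, 0.0],
                    charge=qa, lj_epsilon=eps, lj_rmin_half=rmin_half),
            mb.Atom(2, "X2", "C", 1, "RES", "B", [r, 0.0, 0.0],
                    charge=qb, lj_epsilon=eps, lj_rmin_half=rmin_half),
        ]
        s = mb.Structure(atoms)
        return s, mb.Selection(s, (0,), "A"), mb.Selection(s, (1,), "B")

    def test_unit_charges_at_three_angstrom(self):
        s, a, b = self._pair(3.0)
        e = mb.interaction_energy(s.coords, a, b)
        assert e.electrostatic == pytest.approx(-COULOMB_K / 3.0)
        assert e.electrostatic == pytest.approx(-110.69, abs=0.01)
        assert e.van_der_waals == 0.0
        assert e.total == e.electrostatic + e.van_der_waals

    def test_lj_minimum_is_minus_epsilon(self):
        s, a, b = self._pair(3.0, qa=0.0, qb=0.0, eps=0.25, rmin_half=1.5)
        e = mb.interaction_energy(s.coords, a, b)
        assert e.van_der_waals == pytest.approx(-0.25)
        assert e.electrostatic == 0.0

    def test_outside_cutoff_is_zero(self):
        s, a, b = self._pair(13.0)
        e = mb.interaction_energy(s.coords, a, b)
        assert e.total == 0.0

    def test_continuous_across_cutoff_boundary(self):
        s1, a1, b1 = self._pair(12.0 - 1e-7)
        s2, a2, b2 = self._pair(12.0 + 1e-7)
        lo = mb.interaction_energy(s1.coords, a1, b1)
        hi = mb.interaction_energy(s2.coords, a2, b2)
        assert abs(lo.total - hi.total) < 1e-6

    def test_symmetric_in_selections(self, two_bond_trajectory):
        _, s, traj = two_bond_trajectory
        sel_a = mb.select(s, "A", s.chains["A"])
        sel_b = mb.select(s, "B", s.chains["B"])
        e1 = mb.interaction_energy(traj.frames[0], sel_a, sel_b)
        e2 = mb.interaction_energy(traj.frames[0], sel_b, sel_a)
        assert e1.total == pytest.approx(e2.total, rel=1e-12)

    def test_missing_parameters_are_listed(self):
        atoms = [
            mb.Atom(1, "X1", "C", 1, "RES", "A", [0.0, 0.0, 0.0],
                    charge=1.0, lj_epsilon=0.1, lj_rmin_half=1.0),
            mb.Atom(2, "X2", "C", 5, "RES", "B", [3.0, 0.0, 0.0]),
        ]
        s = mb.Structure(atoms)
        with pytest.raises(mb.ParameterError, match="B:5:X2"):
            mb.interaction_energy(
                s.coords, mb.Selection(s, (0,), "A"), mb.Selection(s, (1,), "B")
            )
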