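"""RMSD, pull distance, DMC, cross-angle and rupture force."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mechbond as mb


def _rigid(frames, seed=0):
    """Apply a random rigid rotation + translation to every frame."""
    rng = np.random.default_rng(seed)
    out = np.empty_like(frames)
    for k in range(len(frames)):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        out[k] = frames[k] @ R.T + t
    return out


@pytest.fixture
def toy_trajectory(rng):
    atoms = [
        mb.Atom(i + 1, "CA", "C", i + 1, "GLY", "A", p)
        for i, p in enumerate(rng.uniform(-5, 5, size=(8, 3)))
    ]
    s = mb.Structure(atoms)
    frames = s.coords[None] + rng.normal(0, 0.5, size=(10, 8, 3))
    frames[0] = s.coords
    return mb.Trajectory(s, frames), s


class TestRmsd:
    def test_identical_frame_is_zero(self, toy_trajectory):
        traj, s = toy_trajectory
        sel = mb.Selection(s, tuple(range(8)), "all")
        assert mb.rmsd_series(traj, 0, sel).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_motion(self, toy_trajectory):
        traj, s = toy_trajectory
        sel = mb.Selection(s, tuple(range(8)), "all")
        base = mb.rmsd_series(traj, 0, sel).values
        moved = mb.Trajectory(s, _rigid(traj.frames))
        rigid = mb.rmsd_series(moved, traj.frames[0], sel).values
        np.testing.assert_allclose(rigid, base, atol=1e-6)

    def test_matches_scipy_superposition_oracle(self, toy_trajectory):
        traj, s = toy_trajectory
        sel = mb.Selection(s, tuple(range(8)), "all")
        mine = mb.rmsd_series(traj, 0, sel).values
        for k in range(len(traj)):
            a = traj.frames[k] - traj.frames[k].mean(axis=0)
            bfr = traj.frames[0] - traj.frames[0].mean(axis=0)
            _, rssd = Rotation.align_vectors(bfr, a)
            assert mine[k] == pytest.approx(rssd / np.sqrt(8), abs=1e-6)

    def test_displaced_atom_closed_form(self):
        # 4 points; one displaced by 2 Å. After centring/rotation the
        # optimal RMSD on this symmetric arrangement is sqrt(d'²/n) with
        # the displacement shared: verified against the scipy oracle.
        pts = np.array(
            [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]]
        )
        moved = pts.copy()
        moved[0, 2] += 2.0
        atoms = [
            mb.Atom(i + 1, "CA", "C", i + 1, "GLY", "A", p)
            for i, p in enumerate(pts)
        ]
        s = mb.Structure(atoms)
        traj = mb.Trajectory(s, np.stack([pts, moved]))
        sel = mb.Selection(s, (0, 1, 2, 3), "all")
        _, rssd = Rotation.align_vectors(
            pts - pts.mean(axis=0), moved - moved.mean(axis=0)
        )
        assert mb.rmsd_series(traj, 0, sel).values[1] == pytest.approx(
            rssd / 2.0, abs=1e-8
        )


class TestPullDistance:
    def _two_atoms(self, p1, p2):
        atoms = [
            mb.Atom(1, "CA", "C", 1, "GLY", "A", p1),
            mb.Atom(2, "CA", "C", 1, "GLY", "B", p2),
        ]
        s = mb.Structure(atoms)
        return mb.Trajectory(s, s.coords[None])

    def test_three_four_five(self):
        traj = self._two_atoms([0, 0, 0], [3, 4, 0])
        series = mb.pull_distance_series(traj, ("B", 1, "CA"), ("A", 1, "CA"))
        assert series.values[0] == pytest.approx(5.0)

    def test_coincident_atoms(self):
        traj = self._two_atoms([1, 1, 1], [1, 1, 1])
        series = mb.pull_distance_series(traj, ("B", 1, "CA"), ("A", 1, "CA"))
        assert series.values[0] == 0.0

    def test_translation_invariant(self):
        t1 = self._two_atoms([0, 0, 0], [3, 4, 0])
        t2 = self._two_atoms([10, -7, 2], [13, -3, 2])
        d1 = mb.pull_distance_series(t1, ("B", 1, "CA"), ("A", 1, "CA")).values
        d2 = mb.pull_distance_series(t2, ("B", 1, "CA"), ("A", 1, "CA")).values
        np.testing.assert_allclose(d1, d2)


class TestDmc:
    def _structure(self, positions, elements=None):
        elements = elements or ["C"] * len(positions)
        atoms = [
            mb.Atom(i + 1, el, el, i + 1, "GLY", "A", p)
            for i, (el, p) in enumerate(zip(elements, positions))
        ]
        return mb.Structure(atoms)

    def test_single_atom_loops(self):
        s = self._structure([[0, 0, 0], [3, 4, 0]])
        l1 = mb.Selection(s, (0,), "l1")
        l2 = mb.Selection(s, (1,), "l2")
        assert mb.dmc(s.coords, l1, l2) == pytest.approx(5.0)

    def test_identical_loops_give_zero(self):
        s = self._structure([[1, 2, 3]])
        l1 = mb.Selection(s, (0,), "l1")
        assert mb.dmc(s.coords, l1, l1) == 0.0

    def test_equal_mass_centroid(self):
        s = self._structure([[0, 0, 0], [2, 0, 0], [1, 5, 0]])
        pair = mb.Selection(s, (0, 1), "pair")
        single = mb.Selection(s, (2,), "single")
        assert mb.dmc(s.coords, pair, single) == pytest.approx(5.0)

    def test_symmetric_and_translation_invariant(self):
        s = self._structure([[0, 0, 0], [2, 0, 0], [1, 5, 0]],
                            ["N", "O", "C"])
        l1 = mb.Selection(s, (0, 1), "l1")
        l2 = mb.Selection(s, (2,), "l2")
        d = mb.dmc(s.coords, l1, l2)
        assert mb.dmc(s.coords, l2, l1) == d
        assert mb.dmc(s.coords + 11.0, l1, l2) == pytest.approx(d, abs=1e-9)

    def test_mass_weighting_shifts_center(self):
        # O (16) vs H (1): the mass centre sits near the oxygen
        s = self._structure([[0, 0, 0], [2, 0, 0], [1, 5, 0]],
                            ["O", "H", "C"])
        l1 = mb.Selection(s, (0, 1), "l1")
        l2 = mb.Selection(s, (2,), "l2")
        weighted = mb.dmc(s.coords, l1, l2, mass_weighted=True)
        centroid = mb.dmc(s.coords, l1, l2, mass_weighted=False)
        assert weighted != pytest.approx(centroid)


class TestCrossAngle:
    def _strands(self, axis_a, axis_b):
        pa = np.outer(np.arange(4, dtype=float), axis_a)
        pb = np.outer(np.arange(4, dtype=float), axis_b) + [0, 0, 20.0]
        atoms = [
            mb.Atom(i + 1, "CA", "C", i + 1, "GLY", "A", p)
            for i, p in enumerate(pa)
        ] + [
            mb.Atom(i + 5, "CA", "C", i + 1, "GLY", "B", p)
            for i, p in enumerate(pb)
        ]
        s = mb.Structure(atoms)
        return s, mb.Selection(s, (0, 1, 2, 3), "A"), mb.Selection(s, (4, 5, 6, 7), "B")

    @pytest.mark.parametrize(
        "axis_b,expected",
        [([0, 1, 0], 90.0), ([1, 0, 0], 0.0), ([1, 1, 0], 45.0)],
    )
    def test_analytic_axes(self, axis_b, expected):
        s, a, b = self._strands([1, 0, 0], axis_b)
        assert mb.cross_angle(s.coords, a, b) == pytest.approx(expected, abs=1e-6)

    def test_folded_to_first_quadrant_and_symmetric(self):
        s, a, b = self._strands([1, 0, 0], [-1, 0.3, 0])
        angle = mb.cross_angle(s.coords, a, b)
        assert 0.0 <= angle <= 90.0
        assert mb.cross_angle(s.coords, b, a) == pytest.approx(angle)

    def test_invariant_under_rigid_motion(self):
        s, a, b = self._strands([1, 0, 0], [1, 2, 0.5])
        base = mb.cross_angle(s.coords, a, b)
        moved = _rigid(s.coords[None], seed=5)[0]
        assert mb.cross_angle(moved, a, b) == pytest.approx(base, abs=1e-6)

    def test_degenerate_strand_raises(self):
        atoms = [
            mb.Atom(i + 1, "CA", "C", i + 1, "GLY", "A", [1.0, 2.0, 3.0])
            for i in range(3)
        ] + [
            mb.Atom(i + 4, "CA", "C", i + 1, "GLY", "B", [float(i), 0, 0])
            for i in range(3)
        ]
        s = mb.Structure(atoms)
        with pytest.raises(mb.SelectionError, match="degenerate"):
            mb.cross_angle(
                s.coords, mb.Selection(s, (0, 1, 2), "A"),
                mb.Selection(s, (3, 4, 5), "B"),
            )


class TestRuptureForce:
    def _trace(self, peak=240.0, n=200, rupture=150, plateau=11, noise=0.0,
               seed=0):
        rng = np.random.default_rng(seed)
        rise = rupture - plateau
        force = np.concatenate([
            np.linspace(0, peak, rise, endpoint=False),
            np.full(plateau, peak),
            np.linspace(peak, 40.0, n - rupture + 1)[1:],
        ])
        if noise:
            force = force + rng.normal(0, noise, n)
        n_hb = np.where(np.arange(n) < rupture, 3, 0)
        return mb.ForceTrace(np.arange(n) * 0.1, force, n_hb)

    def test_planted_peak_recovered_exactly_without_noise(self):
        result = mb.rupture_force(self._trace())
        assert result.force == pytest.approx(240.0)
        assert result.dissociated

    def test_monotone_trace_warns_and_returns_final_value(self):
        t = mb.ForceTrace(np.arange(50) * 0.1, np.linspace(0, 100, 50))
        with pytest.warns(UserWarning, match="never dissociated"):
            result = mb.rupture_force(t)
        assert not result.dissociated
        # the centred window averages the rising edge: slightly below the
        # final raw value, but still the global smoothed maximum
        assert 90.0 <= result.force <= 100.0
        assert result.frame == len(t) - 1

    def test_noisy_trace_within_ten_piconewton(self):
        result = mb.rupture_force(self._trace(noise=10.0, seed=42), window=11)
        assert abs(result.force - 240.0) <= 10.0

    def test_trace_roundtrip(self, tmp_path):
        t = self._trace()
        path = tmp_path / "trace.tsv"
        t.to_tsv(str(path))
        back = mb.ForceTrace.from_tsv(str(path))
        np.testing.assert_allclose(back.force, t.force)
        np.testing.assert_array_equal(back.n_hb, t.n_hb)
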