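"""RMSD/RMSF, radius of gyration, grid volume and RDF peak metrics."""
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cetptunnel.structure import Atom, Structure
from cetptunnel.trajmetrics import (
    CoordinateSet,
    Trajectory,
    kabsch_rmsd,
    molecular_volume,
    radius_of_gyration,
    rdf_first_peak,
    rmsf,
)


def _cset(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(coords))]
    return CoordinateSet(labels, coords)


ASYM4 = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 1.5, 0], [0.3, 0.4, 2.2]])


class TestKabschRMSD:
    def test_identical_sets_zero(self):
        assert kabsch_rmsd(_cset(ASYM4), _cset(ASYM4)) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(ASYM4) + np.array([5.0, -3.0, 8.0])
        assert kabsch_rmsd(_cset(ASYM4), _cset(moved)) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        b = ASYM4 + rng.normal(0, 0.3, ASYM4.shape)
        ab = kabsch_rmsd(_cset(ASYM4), _cset(b))
        ba = kabsch_rmsd(_cset(b), _cset(ASYM4))
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_superposed_never_exceeds_direct(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            b = ASYM4 + rng.normal(0, 0.5, ASYM4.shape)
            assert (kabsch_rmsd(_cset(ASYM4), _cset(b), superpose=True)
                    <= kabsch_rmsd(_cset(ASYM4), _cset(b), superpose=False) + 1e-12)

    def test_matches_exhaustive_rotation_grid(self):
        """Brute-force search over rotations reproduces the optimum."""
        rng = np.random.default_rng(3)
        b = ASYM4 + rng.normal(0, 0.2, ASYM4.shape)
        ours = kabsch_rmsd(_cset(ASYM4), _cset(b))

        ac = ASYM4 - ASYM4.mean(axis=0)
        bc = b - b.mean(axis=0)
        best = math.inf
        center = np.zeros(3)
        width = 180.0
        for _ in range(4):  # coarse-to-fine grid refinement
            axes = [np.linspace(c - width, c + width, 9) for c in center]
            for a1 in axes[0]:
                for a2 in axes[1]:
                    for a3 in axes[2]:
                        r = Rotation.from_euler("zyx", [a1, a2, a3], degrees=True)
                        val = np.sqrt(np.mean(np.sum((ac - r.apply(bc)) ** 2, axis=1)))
                        if val < best:
                            best, center = val, np.array([a1, a2, a3])
            width /= 6.0
        assert ours == pytest.approx(best, abs=1e-3)

    def test_underdetermined_rotation_rejected(self):
        two = _cset([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_rmsd(two, two, superpose=True)


class TestRMSF:
    def _rigid_base(self, n=12, seed=4):
        rng = np.random.default_rng(seed)
        return rng.uniform(-5, 5, size=(n, 3))

    def test_static_trajectory_all_zero(self):
        base = self._rigid_base()
        traj = Trajectory([f"p{i}" for i in range(len(base))],
                          np.repeat(base[None], 4, axis=0))
        assert np.allclose(list(rmsf(traj).values()), 0.0, atol=1e-12)

    def test_oscillating_point_recovers_amplitude(self):
        """One point moving ±d along x in a rigid anchor set → RMSF ≈ d."""
        base = self._rigid_base(n=40)
        d = 0.8
        frames = []
        for k in range(20):
            f = base.copy()
            f[0, 0] += d * (1 if k % 2 == 0 else -1)
            frames.append(f)
        traj = Trajectory([f"p{i}" for i in range(len(base))], np.array(frames))
        values = rmsf(traj)
        assert values["p0"] == pytest.approx(d, rel=0.05)

    def test_rigid_tumbling_superposed_away(self):
        base = self._rigid_base()
        rng = np.random.default_rng(5)
        frames = [Rotation.random(random_state=rng).apply(base) + rng.normal(0, 3, 3)
                  for _ in range(6)]
        traj = Trajectory([f"p{i}" for i in range(len(base))], np.array(frames))
        assert max(rmsf(traj).values()) < 1e-6

    def test_single_frame_rejected(self):
        base = self._rigid_base()
        with pytest.raises(ValueError):
            rmsf(Trajectory([f"p{i}" for i in range(len(base))], base[None]))


class TestRadiusOfGyration:
    def test_two_points(self):
        assert radius_of_gyration(_cset([[0, 0, 0], [2, 0, 0]])) == pytest.approx(1.0)

    def test_equilateral_triangle(self):
        pts = [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]]
        assert radius_of_gyration(_cset(pts)) == pytest.approx(1 / math.sqrt(3), abs=1e-12)

    def test_single_point_zero(self):
        assert radius_of_gyration(_cset([[3, 4, 5]])) == 0.0

    def test_mass_weighting_pulls_center(self):
        c = CoordinateSet(["a", "b"], np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                          masses=np.array([3.0, 1.0]))
        # center at 0.5; rg = sqrt((3*0.25 + 1*2.25)/4) = sqrt(0.75)
        assert radius_of_gyration(c) == pytest.approx(math.sqrt(0.75))


def _sphere_structure(radius=2.0, centers=((0.0, 0.0, 0.0),)):
    return Structure([Atom(i + 1, f"C{i+1}", "C", "ALA", i + 1, "A", np.array(c), radius)
                      for i, c in enumerate(centers)])


class TestMolecularVolume:
    def test_single_sphere(self):
        v = molecular_volume(_sphere_structure())
        assert v == pytest.approx(4 / 3 * math.pi * 8, rel=0.02)

    def test_disjoint_spheres_add(self):
        v = molecular_volume(_sphere_structure(centers=((0, 0, 0), (50, 0, 0))))
        assert v == pytest.approx(2 * 4 / 3 * math.pi * 8, rel=0.02)

    def test_coincident_spheres_union(self):
        v = molecular_volume(_sphere_structure(centers=((0, 0, 0), (0, 0, 0))))
        assert v == pytest.approx(4 / 3 * math.pi * 8, rel=0.02)

    def test_monotone_in_radii(self):
        small = molecular_volume(_sphere_structure(radius=1.9))
        large = molecular_volume(_sphere_structure(radius=2.1))
        assert large >= small

    def test_grid_halving_converges(self):
        # a protein-scale sphere: surface voxels are a small volume fraction
        coarse = molecular_volume(_sphere_structure(radius=4.0), grid=0.25)
        fine = molecular_volume(_sphere_structure(radius=4.0), grid=0.125)
        assert abs(coarse - fine) / fine < 0.01

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError):
            molecular_volume(_sphere_structure(), grid=0.0)


class TestRDFFirstPeak:
    def test_one_dimensional_chain(self):
        pts = np.array([[5.0 * i] for i in range(30)])
        assert rdf_first_peak(pts, bin_width=0.5, max_radius=12.0) == pytest.approx(5.0, abs=0.5)

    def test_no_peak_is_error(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError):
            rdf_first_peak(pts, bin_width=0.5, max_radius=10.0)
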