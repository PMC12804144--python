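"""Shrake-Rupley engine: analytic oracles, grid exactness, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biotite.structure as struc
from epidyn.errors import InputError, LookupAtomError, ParameterError
from epidyn.sasa import (
    SasaParams,
    atom_sasa,
    compute_sasa,
    residue_asa,
    sphere_points,
    two_sphere_analytic,
)
from epidyn.structure_io import parse_pdb

from conftest import PDB_SMALL

CARBON_FULL = 4.0 * np.pi * (1.7 + 1.4) ** 2  # isolated carbon, probe 1.4


class TestSpherePoints:
    def test_unit_norm(self):
        pts = sphere_points(12)
        assert pts.shape == (12, 3)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform_centroid(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 0.01

    def test_deterministic(self):
        np.testing.assert_array_equal(sphere_points(960), sphere_points(960))

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            sphere_points(11)


class TestAtomSasa:
    def test_isolated_carbon_full_sphere(self):
        areas = atom_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert areas[0] == pytest.approx(CARBON_FULL, rel=1e-12)

    def test_engulfed_atom_is_zero(self):
        coords = np.zeros((2, 3))
        areas = atom_sasa(coords, np.array([0.5, 5.0]))
        assert areas[0] == 0.0

    def test_two_carbons_match_analytic_within_1pc(self):
        d = 2.0
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = atom_sasa(coords, np.array([1.7, 1.7]))
        expected = two_sphere_analytic(1.7, 1.7, d)
        assert areas[0] == pytest.approx(expected[0], rel=0.01)
        assert areas[1] == pytest.approx(expected[1], rel=0.01)

    def test_random_two_spheres_match_analytic(self, rng):
        for _ in range(25):
            r1, r2 = rng.uniform(1.2, 2.0, 2)
            d = rng.uniform(0.5, r1 + r2 + 2.5)
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            num = atom_sasa(coords, np.array([r1, r2]))
            ana = two_sphere_analytic(r1, r2, d)
            for got, want in zip(num, ana):
                if want > 1.0:  # relative comparison meaningless near zero
                    assert got == pytest.approx(want, rel=0.01)
                else:
                    assert got == pytest.approx(want, abs=1.0)

    def test_grid_bit_identical_to_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            coords = rng.uniform(-4.0, 4.0, (n, 3))
            radii = rng.uniform(1.2, 2.0, n)
            np.testing.assert_array_equal(
                atom_sasa(coords, radii, use_grid=True),
                atom_sasa(coords, radii, use_grid=False),
            )

    def test_rigid_motion_changes_total_by_under_2pc(self, rng):
        coords = rng.uniform(-3.0, 3.0, (8, 3))
        radii = rng.uniform(1.4, 1.9, 8)
        total = atom_sasa(coords, radii).sum()
        for _ in range(5):
            from scipy.spatial.transform import Rotation

            rot = Rotation.random(rng=np.random.default_rng(int(rng.integers(1 << 31))))
            moved = coords @ rot.as_matrix().T + rng.uniform(-20, 20, 3)
            assert atom_sasa(moved, radii).sum() == pytest.approx(total, rel=0.02)

    def test_probe_radius_monotonicity(self):
        areas = [
            atom_sasa(np.zeros((1, 3)), np.array([1.7]), SasaParams(probe_radius=p))[0]
            for p in (0.0, 0.7, 1.4, 2.0)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_adding_atom_never_increases_areas(self, rng):
        coords = rng.uniform(-2.0, 2.0, (5, 3))
        radii = np.full(5, 1.7)
        before = atom_sasa(coords[:4], radii[:4])
        after = atom_sasa(coords, radii)
        assert np.all(after[:4] <= before + 1e-12)

    def test_convergence_with_point_count(self, rng):
        coords = rng.uniform(-2.0, 2.0, (6, 3))
        radii = np.full(6, 1.6)
        ref = atom_sasa(coords, radii, SasaParams(n_points=16384)).sum()
        errors = [
            abs(atom_sasa(coords, radii, SasaParams(n_points=n)).sum() - ref)
            for n in (60, 240, 960, 3840)
        ]
        assert errors[-1] < errors[0]

    def test_nonfinite_coordinate_rejected(self):
        with pytest.raises(InputError):
            atom_sasa(np.array([[np.nan, 0, 0]]), np.array([1.7]))

    def test_matches_independent_implementation(self, rng):
        # biotite's Shrake-Rupley, fed the same radii, as external oracle
        coords = rng.uniform(-4.0, 4.0, (20, 3)).astype(np.float32)
        radii = rng.uniform(1.4, 1.9, 20)
        arr = struc.AtomArray(20)
        arr.coord = coords
        arr.element = np.full(20, "C", dtype="U2")
        ref = struc.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=radii)
        mine = atom_sasa(
            coords.astype(float), radii, SasaParams(n_points=2000)
        )
        np.testing.assert_allclose(mine, ref, rtol=0.03, atol=0.5)


class TestTwoSphereAnalytic:
    def test_disjoint_full_areas(self):
        a1, a2 = two_sphere_analytic(1.7, 1.5, 10.0)
        assert a1 == pytest.approx(4 * np.pi * 3.1**2)
        assert a2 == pytest.approx(4 * np.pi * 2.9**2)

    def test_coincident_limit_is_half_sphere(self):
        big_r = 1.7 + 1.4
        a1, _ = two_sphere_analytic(1.7, 1.7, 1e-9)
        assert a1 == pytest.approx(2 * np.pi * big_r**2, rel=1e-6)

    def test_overlap_reduces_area(self):
        a1, a2 = two_sphere_analytic(1.7, 1.7, 2.0)
        assert a1 == a2 < CARBON_FULL

    def test_engulfed(self):
        a1, a2 = two_sphere_analytic(0.5, 5.0, 0.5)
        assert a1 == 0.0
        assert a2 == pytest.approx(4 * np.pi * 6.4**2)

    @given(st.floats(0.3, 3.0), st.floats(0.3, 3.0), st.floats(0.05, 12.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_areas_bounded(self, r1, r2, d):
        a1, a2 = two_sphere_analytic(r1, r2, d)
        assert 0.0 <= a1 <= 4 * np.pi * (r1 + 1.4) ** 2 + 1e-9
        assert 0.0 <= a2 <= 4 * np.pi * (r2 + 1.4) ** 2 + 1e-9


class TestResidueAsa:
    def test_residue_sum_equals_atom_sum(self):
        s = parse_pdb(PDB_SMALL)
        result = compute_sasa(s)
        for key, area in result.residue_areas.items():
            atoms = [i for i, a in enumerate(s.atoms) if a.residue_key == key]
            assert area == pytest.approx(result.atom_areas[atoms].sum())

    def test_single_atom_residue(self):
        s = parse_pdb(
            "HETATM    1  C1  MYR C   0       0.000   0.000   0.000  1.00 20.00           C\n"
        )
        result = compute_sasa(s)
        assert residue_asa(s, result, "C", 0) == pytest.approx(CARBON_FULL, rel=1e-12)

    def test_unknown_residue_is_lookup_error(self):
        s = parse_pdb(PDB_SMALL)
        result = compute_sasa(s)
        with pytest.raises(LookupAtomError):
            residue_asa(s, result, "A", 99)

    def test_exposed_toy_complex_gly1_above_threshold(self, toy_pair):
        exposed, asa_e, _, _ = toy_pair
        result = compute_sasa(exposed)
        assert residue_asa(exposed, result, "C", 1) == pytest.approx(asa_e)
        assert asa_e > 50.0
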