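import numpy as np
import pytest

from mechunfold.geometry import (ContactAreaSeries, RegionSelection, contact_area,
                                 contact_area_series, max_tilt, sasa,
                                 sphere_points, tilt_angles)
from mechunfold.io import StructureModel
from mechunfold.synthetic import (helix_pair, helix_pair_frames, sphere_pair,
                                  tilted_rod)

R_TOY = 0.15  # nm toy radius used with probe 0.14 throughout
PROBE = 0.14
TOY_RADII = {"C": R_TOY}


def two_sphere_contact_closed_form(d, R):
    """Buried-area closed form for two equal spheres of extended radius R at
    centre distance d < 2R: CA = pi*R*(2R - d)."""
    return np.pi * R * (2 * R - d)


class TestSasa:
    def test_isolated_sphere_matches_analytic_within_1pct(self, single_atom_model):
        area = sasa(single_atom_model, probe=PROBE, n_points=960, radii=TOY_RADII)
        exact = 4 * np.pi * (R_TOY + PROBE) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_convergence_with_point_count(self, single_atom_model):
        exact = 4 * np.pi * (R_TOY + PROBE) ** 2
        errors = [abs(sasa(single_atom_model, probe=PROBE, n_points=n,
                           radii=TOY_RADII) - exact)
                  for n in (64, 256, 960)]
        assert errors[-1] <= errors[0]

    def test_separated_pair_is_twice_single(self, single_atom_model):
        pair = sphere_pair(separation=5.0)
        single = sasa(single_atom_model, probe=PROBE, radii=TOY_RADII)
        assert sasa(pair, probe=PROBE, radii=TOY_RADII) == pytest.approx(2 * single)

    def test_overlapping_pair_matches_spherical_cap_closed_form(self):
        # union SASA of two equal spheres: 2 * 2*pi*R*(R + d/2)
        d = 0.29
        R = R_TOY + PROBE
        pair = sphere_pair(separation=d)
        expected = 2 * 2 * np.pi * R * (R + d / 2)
        got = sasa(pair, probe=PROBE, n_points=960, radii=TOY_RADII)
        assert abs(got - expected) / expected < 0.01

    def test_unknown_element_lists_atom(self):
        model = StructureModel(names=["XX"], elements=["Xx"], resids=np.array([1]),
                               resnames=["UNK"], chains=["A"],
                               coords=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="XX"):
            sasa(model)

    def test_point_set_deterministic_and_unit(self):
        pts = sphere_points(960)
        np.testing.assert_array_equal(pts, sphere_points(960))
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_matches_mdtraj_oracle_on_helix_pair(self):
        mdtraj = pytest.importorskip("mdtraj")
        model = helix_pair(n_res=8, separation=0.4, rise=0.2)
        top = mdtraj.Topology()
        chain = top.add_chain()
        carbon = mdtraj.element.carbon
        for i in range(model.n_atoms):
            res = top.add_residue("ALA", chain)
            top.add_atom("CA", carbon, res)
        traj = mdtraj.Trajectory(model.coords[None, :, :], top)
        # mdtraj uses the same Bondi radius for carbon (0.17 nm)
        oracle = float(mdtraj.shrake_rupley(
            traj, probe_radius=PROBE, n_sphere_points=960).sum())
        ours = sasa(model, probe=PROBE, n_points=960)
        assert abs(ours - oracle) / oracle < 0.03


class TestContactArea:
    def test_zero_beyond_interaction_range(self):
        pair = sphere_pair(separation=2.0)
        a = RegionSelection("a", [("A", 1, 1)])
        b = RegionSelection("b", [("B", 1, 1)])
        assert abs(contact_area(pair, a, b, radii=TOY_RADII)) <= 1e-6

    def test_symmetric_in_regions(self):
        pair = sphere_pair(separation=0.4)
        a = RegionSelection("a", [("A", 1, 1)])
        b = RegionSelection("b", [("B", 1, 1)])
        assert contact_area(pair, a, b, radii=TOY_RADII) == contact_area(
            pair, b, a, radii=TOY_RADII)

    @pytest.mark.parametrize("d", [0.20, 0.29, 0.45])
    def test_two_sphere_closed_form_within_2pct(self, d):
        pair = sphere_pair(separation=d)
        a = RegionSelection("a", [("A", 1, 1)])
        b = RegionSelection("b", [("B", 1, 1)])
        expected = two_sphere_contact_closed_form(d, R_TOY + PROBE)
        got = contact_area(pair, a, b, n_points=960, radii=TOY_RADII)
        assert abs(got - expected) / expected < 0.02

    def test_overlapping_selections_rejected(self):
        pair = sphere_pair(separation=0.4)
        a = RegionSelection("a", [("A", 1, 1)])
        with pytest.raises(ValueError, match="overlap"):
            contact_area(pair, a, a)

    def test_series_constant_for_rigid_frames(self):
        frames = helix_pair_frames(3, dy_per_frame=0.0, n_res=6)
        a = RegionSelection("A", [("A", 1, 6)])
        b = RegionSelection("B", [("B", 1, 6)])
        series = contact_area_series(frames, a, b, [0.0, 1.0, 2.0], n_points=240)
        assert np.ptp(series.ca) < 1e-9

    def test_series_monotone_decay_to_zero_as_b_translates(self):
        frames = helix_pair_frames(6, dy_per_frame=0.35, n_res=6)
        a = RegionSelection("A", [("A", 1, 6)])
        b = RegionSelection("B", [("B", 1, 6)])
        series = contact_area_series(frames, a, b, np.arange(6.0), n_points=240)
        assert series.ca[0] > 0.1
        assert np.all(np.diff(series.ca) <= 1e-9)
        assert series.ca[-1] <= 1e-6

    def test_empty_frame_list_rejected(self):
        a = RegionSelection("A", [("A", 1, 6)])
        with pytest.raises(ValueError, match="empty"):
            contact_area_series([], a, a, [])

    def test_trim_drops_terminal_residues(self):
        model = helix_pair(n_res=6)
        trimmed = RegionSelection("A", [("A", 1, 6)], trim=2)
        assert len(trimmed.resolve(model)) == 2
        with pytest.raises(ValueError, match="trim"):
            RegionSelection("A", [("A", 1, 4)], trim=2).resolve(model)

    def test_selection_string_syntax(self):
        sel = RegionSelection.from_string("A:10-50,B:3-40", label="iface", trim=2)
        assert sel.ranges == [("A", 10, 50), ("B", 3, 40)]
        assert sel.trimmed_ranges() == [("A", 12, 48), ("B", 5, 38)]


class TestTilt:
    @pytest.mark.parametrize("angle,expected", [(0.0, 0.0), (90.0, 90.0),
                                                (180.0, 180.0), (30.0, 30.0),
                                                (87.0, 87.0)])
    def test_rod_angle_recovered(self, angle, expected):
        rod = tilted_rod(angle, n_res=10)
        series = tilt_angles([rod], ("A", 1), ("A", 10), ("A", 10))
        assert series.alpha1[0] == pytest.approx(expected, abs=1e-6)
        assert max_tilt(series) == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_rigid_translation(self):
        rod = tilted_rod(40.0)
        shifted = StructureModel(rod.names, rod.elements, rod.resids, rod.resnames,
                                 rod.chains, rod.coords + np.array([3.0, -2.0, 5.0]))
        s1 = tilt_angles([rod], ("A", 1), ("A", 10), ("A", 10))
        s2 = tilt_angles([shifted], ("A", 1), ("A", 10), ("A", 10))
        np.testing.assert_allclose(s1.alpha1, s2.alpha1, atol=1e-9)

    def test_invariant_under_axis_scaling(self):
        rod = tilted_rod(55.0)
        s1 = tilt_angles([rod], ("A", 1), ("A", 10), ("A", 10), axis=(1, 0, 0))
        s2 = tilt_angles([rod], ("A", 1), ("A", 10), ("A", 10), axis=(7.5, 0, 0))
        np.testing.assert_allclose(s1.alpha1, s2.alpha1, atol=1e-9)

    def test_missing_ca_names_frame_and_residue(self):
        rod = tilted_rod(10.0, n_res=5)
        with pytest.raises(ValueError, match="A:99"):
            tilt_angles([rod], ("A", 1), ("A", 99), ("A", 5))

    def test_max_tilt_takes_higher_of_both_angles(self):
        from mechunfold.geometry import TiltSeries
        series = TiltSeries("t", alpha1=[10.0, 12.0], alpha2=[20.0, 5.0])
        assert max_tilt(series) == 20.0
        with pytest.raises(ValueError, match="empty"):
            max_tilt(TiltSeries("t", alpha1=[], alpha2=[]))
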