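import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_topology, make_trajectory
from gatescan import domain_geometry as dg
from gatescan import structure_io as sio
from gatescan import synthetic_channel as sc
from gatescan.errors import AlignmentError


def _all_selection(n):
    return sio.Selection("all", np.arange(n), spec="all")


class TestRgSeries:
    def test_square_of_unit_points(self):
        coords = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        traj = make_trajectory(coords[None])
        rg = dg.rg_series(traj, _all_selection(4))
        assert rg.rg[0] == pytest.approx(np.sqrt(2.0))

    def test_coincident_atoms_give_zero(self):
        traj = make_trajectory(np.zeros((3, 5, 3)))
        assert np.all(dg.rg_series(traj, _all_selection(5)).rg == 0)

    def test_uniform_dilation_doubles_rg(self):
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((7, 3))
        traj = make_trajectory(np.stack([coords, 2.0 * coords]))
        rg = dg.rg_series(traj, _all_selection(7))
        assert rg.rg[1] == pytest.approx(2.0 * rg.rg[0])


class TestTwistAngle:
    def _bundle_frame(self, tangential, radial):
        spec = sc.ChannelSpec(helix_residues=35, residue_start=658, n_frames=1,
                              per_residue_sigma=0.0,
                              helix_tilt_tangential_deg=tangential,
                              helix_tilt_radial_deg=radial)
        return sc.build_reference(spec)

    def _s6_selection(self, frame, chain="A"):
        return sio.resolve_selection(frame.topology,
                                     f"chain {chain}, residues 658-692, atoms CA")

    @pytest.mark.parametrize("tangential", [0.0, 10.0, 30.0, 60.0])
    def test_tangential_tilt_recovered(self, tangential):
        frame = self._bundle_frame(tangential, 0.0)
        tw = dg.twist_angle(frame, self._s6_selection(frame), "A")
        assert tw.twist_angle == pytest.approx(tangential, abs=0.5)

    @pytest.mark.parametrize("radial", [10.0, 30.0])
    def test_pure_radial_tilt_projects_to_zero(self, radial):
        frame = self._bundle_frame(0.0, radial)
        tw = dg.twist_angle(frame, self._s6_selection(frame), "A")
        assert tw.twist_angle == pytest.approx(0.0, abs=0.5)

    def test_radial_tilt_does_not_bias_tangential_recovery(self):
        with_radial = self._bundle_frame(25.0, 8.0)
        without = self._bundle_frame(25.0, 0.0)
        a1 = dg.twist_angle(with_radial, self._s6_selection(with_radial), "A").twist_angle
        a2 = dg.twist_angle(without, self._s6_selection(without), "A").twist_angle
        assert abs(a1 - a2) < 0.5

    def test_invariant_under_rotation_about_z(self):
        frame = self._bundle_frame(22.0, 0.0)
        sel = self._s6_selection(frame)
        a1 = dg.twist_angle(frame, sel, "A").twist_angle
        rot = Rotation.from_euler("z", 53.0, degrees=True)
        rotated = sio.StructureFrame(frame.topology, rot.apply(frame.coordinates))
        a2 = dg.twist_angle(rotated, sel, "A").twist_angle
        assert a1 == pytest.approx(a2, abs=1e-6)

    def test_invariant_under_atom_order_reversal(self):
        frame = self._bundle_frame(22.0, 0.0)
        sel = self._s6_selection(frame)
        ca = frame.coordinates[sel.atom_indices]
        rev = sio.StructureFrame(make_topology(len(ca), atom_name="CA"), ca[::-1])
        fwd = sio.StructureFrame(make_topology(len(ca), atom_name="CA"), ca)
        all_sel = _all_selection(len(ca))
        a1 = dg.twist_angle(fwd, all_sel).twist_angle
        a2 = dg.twist_angle(rev, all_sel).twist_angle
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_centroid_on_axis_flagged_undefined(self):
        # a helix centred on the z axis has no radial direction
        coords = np.column_stack([np.cos(np.arange(20)), np.sin(np.arange(20)),
                                  0.5 * np.arange(20.0)])
        coords -= coords.mean(axis=0)
        frame = sio.StructureFrame(make_topology(20, atom_name="CA"), coords)
        tw = dg.twist_angle(frame, _all_selection(20))
        assert tw.undefined

    def test_twist_series_recovers_generator_tilts(self):
        spec = sc.ChannelSpec(helix_residues=35, residue_start=658, n_frames=30,
                              per_residue_sigma=0.2, seed=8,
                              helix_tilt_tangential_deg=30.7)
        traj, manifest = sc.simulate_trajectory(spec)
        angles, chains = dg.twist_series(traj, (658, 692))
        assert len(chains) == 4
        assert angles.mean() == pytest.approx(manifest["tilt_tangential_deg"], abs=0.5)


class TestDistanceMatrix:
    def _line_traj(self, positions_per_frame):
        frames = []
        for pos in positions_per_frame:
            coords = np.zeros((len(pos), 3))
            coords[:, 0] = pos
            frames.append(coords)
        return make_trajectory(np.stack(frames), atom_name="CA", resname="ALA")

    def test_static_line_distances(self):
        dm = dg.distance_matrix(self._line_traj([[0.0, 2.0, 4.0]]), "A")
        assert dm.matrix[0, 2] == pytest.approx(4.0)
        assert dm.matrix[0, 1] == pytest.approx(2.0)

    def test_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(13)
        traj = make_trajectory(rng.standard_normal((5, 6, 3)), atom_name="CA")
        dm = dg.distance_matrix(traj, "A")
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        np.testing.assert_allclose(np.diag(dm.matrix), 0.0)

    def test_two_frame_average(self):
        dm = dg.distance_matrix(self._line_traj([[0.0, 3.0], [0.0, 5.0]]), "A")
        assert dm.matrix[0, 1] == pytest.approx(4.0)

    def test_residue_without_ca_dropped_with_warning(self):
        top = sio.Topology(["CA", "CB", "CA"], ["C"] * 3, [1, 2, 3],
                           ["ALA"] * 3, ["A"] * 3)
        traj = sio.Trajectory(top, np.zeros((2, 3, 3)))
        with pytest.warns(UserWarning, match="without"):
            dm = dg.distance_matrix(traj, "A")
        assert list(dm.residue_numbers) == [1, 3]


class TestCompareStates:
    def _dm(self, matrix, label=""):
        n = len(matrix)
        return dg.DistanceMatrix(np.arange(1, n + 1), np.asarray(matrix, float),
                                 state_label=label)

    def test_identical_states_give_zero_delta_and_flagged_correlation(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        sc_ = dg.compare_states(self._dm(m), self._dm(m))
        np.testing.assert_allclose(sc_.delta, 0.0)
        assert np.isnan(sc_.correlation).all()

    def test_proportional_rows_fully_correlated(self):
        base = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [0.5, 1.0, 1.5]])
        sc_ = dg.compare_states(self._dm(base), self._dm(np.zeros((3, 3))))
        assert sc_.correlation[0, 1] == pytest.approx(1.0)

    def test_negated_rows_anticorrelated(self):
        delta = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0], [0.4, 0.1, -0.9]])
        sc_ = dg.compare_states(self._dm(delta), self._dm(np.zeros((3, 3))))
        assert sc_.correlation[0, 1] == pytest.approx(-1.0)

    def test_exact_antisymmetry_under_state_swap(self):
        rng = np.random.default_rng(14)
        a = rng.standard_normal((4, 4))
        b = rng.standard_normal((4, 4))
        fwd = dg.compare_states(self._dm(a), self._dm(b)).delta
        rev = dg.compare_states(self._dm(b), self._dm(a)).delta
        assert np.array_equal(fwd, -rev)

    def test_residue_mismatch_raises(self):
        d1 = self._dm(np.zeros((3, 3)))
        d2 = dg.DistanceMatrix(np.array([7, 8, 9]), np.zeros((3, 3)))
        with pytest.raises(AlignmentError):
            dg.compare_states(d1, d2)


class TestCysPairDistance:
    def _cys_frame(self, sg_distance):
        names = ["CA", "SG", "CA", "SG"]
        top = sio.Topology(names, ["C", "S", "C", "S"], [386, 386, 390, 390],
                           ["CYS"] * 4, ["A"] * 4)
        coords = np.zeros((4, 3))
        coords[1] = [0.0, 0.0, 0.0]
        coords[3] = [sg_distance, 0.0, 0.0]
        return sio.StructureFrame(top, coords)

    @pytest.mark.parametrize("d", [2.03, 2.53, 5.8])
    def test_distance_measured_per_chain(self, d):
        out = dg.cys_pair_sg_distances(self._cys_frame(d))
        assert out["A"] == pytest.approx(d)

    def test_chain_without_sg_omitted(self):
        top = sio.Topology(["CA"], ["C"], [386], ["CYS"], ["B"])
        frame = sio.StructureFrame(top, np.zeros((1, 3)))
        assert dg.cys_pair_sg_distances(frame) == {}
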