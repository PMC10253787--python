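import warnings

import numpy as np
import pytest

from gatescan import structure_io as sio
from gatescan import synthetic_channel as sc
from gatescan.errors import (
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    PartialReadError,
    TopologyError,
)

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00"
    "           C\nEND\n"
)


@pytest.fixture(scope="module")
def small_spec():
    return sc.ChannelSpec(helix_residues=10, residue_start=658, n_frames=10,
                          per_residue_sigma=0.2, seed=5)


@pytest.fixture(scope="module")
def small_traj(small_spec):
    return sc.simulate_trajectory(small_spec)[0]


class TestReadStructure:
    def test_minimal_single_atom_pdb(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        frame = sio.read_structure(p)
        assert frame.n_atoms == 1
        assert frame.topology.atom_name[0] == "CA"
        assert frame.topology.chain_id[0] == "A"
        np.testing.assert_allclose(frame.coordinates[0], [1.0, 2.0, 3.0])

    def test_write_read_roundtrip_preserves_coordinates(self, tmp_path, small_spec):
        ref = sc.build_reference(small_spec)
        sio.write_structure(ref, tmp_path / "ref.pdb")
        back = sio.read_structure(tmp_path / "ref.pdb")
        # PDB fixed-width records carry 3 decimals
        assert np.abs(back.coordinates - ref.coordinates).max() < 1e-3
        assert np.array_equal(back.topology.atom_name, ref.topology.atom_name)
        assert np.array_equal(back.topology.residue_number, ref.topology.residue_number)
        assert np.array_equal(back.topology.chain_id, ref.topology.chain_id)

    def test_multi_model_pdb_selects_requested_model(self, tmp_path, small_traj):
        import MDAnalysis as mda

        from gatescan.structure_io import _to_universe

        u = _to_universe(small_traj.topology, small_traj.coordinates[:4])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(tmp_path / "multi.pdb"), multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        frame3 = sio.read_structure(tmp_path / "multi.pdb", model=3)
        assert np.abs(frame3.coordinates - small_traj.coordinates[2]).max() < 1e-3
        frame1 = sio.read_structure(tmp_path / "multi.pdb")
        assert np.abs(frame1.coordinates - small_traj.coordinates[0]).max() < 1e-3

    def test_mmcif_roundtrip_via_gemmi(self, tmp_path, small_spec):
        import gemmi

        ref = sc.build_reference(small_spec)
        sio.write_structure(ref, tmp_path / "ref.pdb")
        st = gemmi.read_structure(str(tmp_path / "ref.pdb"))
        st.setup_entities()
        st.make_mmcif_document().write_file(str(tmp_path / "ref.cif"))
        back = sio.read_structure(tmp_path / "ref.cif")
        assert np.abs(back.coordinates - ref.coordinates).max() < 1e-3
        assert np.array_equal(back.topology.residue_number, ref.topology.residue_number)

    def test_unparsable_mmcif_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not cif\n###\n")
        with pytest.raises(FormatError):
            sio.read_structure(bad)

    def test_empty_model_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises((EmptyStructureError, FormatError)):
            sio.read_structure(p)

    def test_model_out_of_range(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.raises(FormatError):
            sio.read_structure(p, model=5)


class TestTrajectoryIO:
    def test_roundtrip_preserves_frames_order_and_stride(self, tmp_path, small_traj):
        sio.write_trajectory(small_traj, tmp_path / "top.pdb", tmp_path / "t.dcd")
        back = sio.read_trajectory(tmp_path / "top.pdb", tmp_path / "t.dcd")
        assert back.n_frames == small_traj.n_frames
        assert np.abs(back.coordinates - small_traj.coordinates).max() < 1e-3
        assert np.array_equal(back.topology.atom_name, small_traj.topology.atom_name)
        assert back.stride_ps == pytest.approx(small_traj.stride_ps, rel=1e-5)

    def test_frame0_roundtrip_within_format_precision(self, tmp_path, small_traj):
        sio.write_trajectory(small_traj, tmp_path / "top.pdb", tmp_path / "t.dcd")
        back = sio.read_trajectory(tmp_path / "top.pdb", tmp_path / "t.dcd")
        assert np.abs(back.coordinates[0] - small_traj.coordinates[0]).max() < 1e-3

    def test_atom_count_mismatch_raises_topology_error(self, tmp_path, small_traj):
        sio.write_trajectory(small_traj, tmp_path / "top.pdb", tmp_path / "t.dcd")
        (tmp_path / "wrong.pdb").write_text(MINIMAL_PDB)
        with pytest.raises(TopologyError):
            sio.read_trajectory(tmp_path / "wrong.pdb", tmp_path / "t.dcd")

    def test_truncated_trajectory_reports_recovered_frames(self, tmp_path, small_traj):
        sio.write_trajectory(small_traj, tmp_path / "top.pdb", tmp_path / "t.dcd")
        data = (tmp_path / "t.dcd").read_bytes()
        (tmp_path / "cut.dcd").write_bytes(data[: int(len(data) * 0.6)])
        with pytest.raises(PartialReadError) as exc_info:
            sio.read_trajectory(tmp_path / "top.pdb", tmp_path / "cut.dcd")
        assert 0 < exc_info.value.n_frames_recovered < small_traj.n_frames

    def test_slice_arithmetic(self):
        top = sio.Topology(["CA"], ["C"], [1], ["ALA"], ["A"])
        coords = np.zeros((4000, 1, 3))
        coords[:, 0, 0] = np.arange(4000)
        traj = sio.Trajectory(top, coords, stride_ps=1.0)
        half = traj.slice(2000, None, 2)
        assert half.n_frames == 1000
        assert half.coordinates[0, 0, 0] == 2000
        assert half.stride_ps == 2.0


class TestSelections:
    def test_counting_single_chain(self, small_spec):
        ref = sc.build_reference(small_spec)
        sel = sio.resolve_selection(ref.topology, "chain A, residues 658-660, atoms CA")
        assert len(sel) == 3

    def test_default_bundle_backbone_counts(self):
        spec = sc.ChannelSpec(n_frames=1, per_residue_sigma=0.0)
        ref = sc.build_reference(spec)
        sel = sio.resolve_selection(ref.topology, "residues 432-713, backbone")
        assert len(sel) == 4 * 282 * 4

    def test_resolution_is_deterministic_and_idempotent(self, small_spec):
        ref = sc.build_reference(small_spec)
        s1 = sio.resolve_selection(ref.topology, "residues 658-667, backbone")
        s2 = sio.resolve_selection(ref.topology, "residues 658-667, backbone")
        assert np.array_equal(s1.atom_indices, s2.atom_indices)

    def test_en_dash_range_accepted(self, small_spec):
        ref = sc.build_reference(small_spec)
        s1 = sio.resolve_selection(ref.topology, "residues 658–660, atoms CA")
        s2 = sio.resolve_selection(ref.topology, "residues 658-660, atoms CA")
        assert np.array_equal(s1.atom_indices, s2.atom_indices)

    def test_empty_selection_raises_with_spec_named(self, small_spec):
        ref = sc.build_reference(small_spec)
        with pytest.raises(EmptySelectionError, match="residues 1-5"):
            sio.resolve_selection(ref.topology, "residues 1-5")

    def test_unknown_atom_name_warns_not_errors(self, small_spec):
        ref = sc.build_reference(small_spec)
        with pytest.warns(UserWarning, match="ZZ9"):
            sel = sio.resolve_selection(ref.topology, "atoms CA ZZ9")
        assert len(sel) == 4 * 10


class TestVdw:
    def test_bondi_carbon(self):
        top = sio.Topology(["C1"], ["C"], [1], ["LIG"], ["A"])
        assert sio.assign_vdw(top)[0] == pytest.approx(1.70)

    def test_unknown_element_gets_default(self):
        table = sio.VdwTable(default_radius=1.23)
        top = sio.Topology(["XX1"], ["Xx"], [1], ["LIG"], ["A"])
        assert sio.assign_vdw(top, table)[0] == pytest.approx(1.23)

    def test_all_hydrogen_structure(self):
        top = sio.Topology(["H1", "H2"], ["H", "H"], [1, 1], ["LIG", "LIG"], ["A", "A"])
        np.testing.assert_allclose(sio.assign_vdw(top), [1.20, 1.20])

    def test_hole_simple_set_differs_from_bondi(self):
        assert sio.VdwTable.hole_simple().lookup("C") == pytest.approx(1.85)

    def test_element_inference_from_atom_names(self):
        top = sio.Topology(["CA", "OW", "SG", "1HB"], ["", "", "", ""],
                           [1, 1, 1, 1], ["ALA"] * 4, ["A"] * 4)
        sio.infer_elements(top)
        assert list(top.element) == ["C", "O", "S", "H"]
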