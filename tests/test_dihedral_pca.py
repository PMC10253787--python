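import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatescan import dihedral_pca as dp
from gatescan import structure_io as sio
from gatescan import synthetic_channel as sc


def _traj_from_backbone(bb, n_frames=1):
    """Trajectory from an (n_res, 4, 3) backbone array (N, CA, C, O)."""
    n_res = bb.shape[0]
    names, elements, resnums = [], [], []
    for r in range(n_res):
        for name, el in zip(("N", "CA", "C", "O"), "NCCO"):
            names.append(name)
            elements.append(el)
            resnums.append(r + 1)
    top = sio.Topology(names, elements, resnums, ["ALA"] * 4 * n_res,
                       ["A"] * 4 * n_res)
    coords = np.repeat(bb.reshape(1, -1, 3), n_frames, axis=0)
    return sio.Trajectory(top, coords)


class TestExtractDihedrals:
    def test_ideal_helix_recovers_canonical_angles(self):
        traj = _traj_from_backbone(sc.ideal_helix_backbone(10), n_frames=2)
        series = dp.extract_dihedrals(traj)
        phi = [a for a, lab in zip(series.angles[0], series.labels) if lab[2] == "phi"]
        psi = [a for a, lab in zip(series.angles[0], series.labels) if lab[2] == "psi"]
        np.testing.assert_allclose(phi, -57.0, atol=1.0)
        np.testing.assert_allclose(psi, -47.0, atol=1.0)

    def test_all_trans_backbone_gives_180(self):
        traj = _traj_from_backbone(sc.ideal_helix_backbone(6, phi=180.0, psi=180.0))
        series = dp.extract_dihedrals(traj)
        assert np.all(np.isclose(np.abs(series.angles), 180.0, atol=1e-6))

    def test_two_residue_chain_has_one_phi_and_one_psi(self):
        traj = _traj_from_backbone(sc.ideal_helix_backbone(2))
        series = dp.extract_dihedrals(traj)
        kinds = sorted(lab[2] for lab in series.labels)
        assert kinds == ["phi", "psi"]
        # no phi for residue 1, no psi for the last residue
        assert ("A", 1, "phi") not in series.labels
        assert ("A", 2, "psi") not in series.labels

    def test_chain_break_skips_spanning_dihedrals(self):
        bb = sc.ideal_helix_backbone(6)
        bb[3:] += np.array([20.0, 0.0, 0.0])  # break between residues 3 and 4
        traj = _traj_from_backbone(bb)
        with pytest.warns(UserWarning, match="break"):
            series = dp.extract_dihedrals(traj)
        assert ("A", 4, "phi") not in series.labels
        assert ("A", 3, "psi") not in series.labels


class TestDpca:
    def test_frozen_trajectory_has_zero_eigenvalues(self):
        series = dp.DihedralSeries(np.full((20, 6), -57.0),
                                   [("A", i, "phi") for i in range(6)])
        result = dp.dpca(series)
        np.testing.assert_allclose(result.eigenvalues, 0.0, atol=1e-12)
        np.testing.assert_allclose(result.projections, 0.0, atol=1e-8)

    def test_single_oscillating_dihedral_captured_by_two_components(self):
        n = 400
        t = np.linspace(0, 8 * np.pi, n)
        angles = np.full((n, 5), -57.0)
        angles[:, 2] = -57.0 + 40.0 * np.sin(t)
        series = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(5)])
        result = dp.dpca(series, n_components=2)
        # the sin/cos pair of the moving dihedral carries all variance
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(result.eigenvalues[2:] < 1e-12)

    def test_matches_brute_force_covariance_on_tiny_input(self):
        rng = np.random.default_rng(21)
        angles = rng.uniform(-180, 180, (5, 3))
        series = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(3)])
        result = dp.dpca(series, n_components=6)
        rad = np.radians(angles)
        X = np.concatenate([np.sin(rad), np.cos(rad)], axis=1)
        Xc = X - X.mean(axis=0)
        brute = np.linalg.eigvalsh(Xc.T @ Xc / 4)[::-1]
        np.testing.assert_allclose(result.eigenvalues, np.clip(brute, 0, None),
                                   atol=1e-10)

    def test_matches_sklearn_pca_cross_check(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(22)
        angles = -57.0 + rng.standard_normal((200, 4)) * 25.0
        series = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(4)])
        result = dp.dpca(series, n_components=3)
        rad = np.radians(series.angles)
        X = np.concatenate([np.sin(rad), np.cos(rad)], axis=1)
        ref = PCA(n_components=3).fit(X)
        np.testing.assert_allclose(result.eigenvalues[:3], ref.explained_variance_,
                                   rtol=1e-10)
        # projections agree up to per-component sign
        for k in range(3):
            dot = np.dot(result.projections[:, k], ref.transform(X)[:, k])
            np.testing.assert_allclose(np.abs(result.projections[:, k]),
                                       np.abs(ref.transform(X)[:, k]), atol=1e-8)
            assert abs(dot) > 0

    def test_planted_variance_ordering_recovered(self):
        angles = sc.planted_dihedral_series(800, 6, {1: 30.0, 4: 10.0}, seed=3)
        series = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(6)])
        result = dp.dpca(series, n_components=4)
        # PC1 must load on dihedral 1 (the larger planted mode): its sin/cos
        # coordinates are columns 1 and 7 of the stacked variables
        lead = np.argmax(np.abs(result.eigenvectors[:, 0]))
        assert lead in (1, 7)
        assert result.eigenvalues[0] > result.eigenvalues[1]

    def test_trace_conservation(self):
        rng = np.random.default_rng(23)
        angles = rng.uniform(-180, 180, (50, 8))
        series = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(8)])
        result = dp.dpca(series)
        rad = np.radians(angles)
        X = np.concatenate([np.sin(rad), np.cos(rad)], axis=1)
        total = X.var(axis=0, ddof=1).sum()
        assert result.eigenvalues.sum() == pytest.approx(total, abs=1e-10)

    @given(st.integers(-3, 3))
    @settings(derandomize=True, max_examples=7)
    def test_wrap_invariance_under_full_turn_shifts(self, turns):
        rng = np.random.default_rng(24)
        angles = rng.uniform(-180, 180, (30, 4))
        series1 = dp.DihedralSeries(angles, [("A", i, "phi") for i in range(4)])
        shifted = angles + 360.0 * turns
        series2 = dp.DihedralSeries(((shifted + 180) % 360) - 180,
                                    [("A", i, "phi") for i in range(4)])
        r1 = dp.dpca(series1)
        r2 = dp.dpca(series2)
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)


class TestFreeEnergySurface:
    def test_single_occupied_bin_is_zero_rest_undefined(self):
        proj = np.zeros((10, 2))
        fes = dp.free_energy_surface(proj, bins=5)
        occupied = np.isfinite(fes.free_energy)
        assert occupied.sum() == 1
        assert fes.free_energy[occupied][0] == 0.0

    def test_count_ratio_e_gives_kbt(self):
        n = 1000
        n2 = int(round(n / np.e))
        proj = np.concatenate([np.tile([[0.25, 0.25]], (n, 1)),
                               np.tile([[0.75, 0.75]], (n2, 1))])
        fes = dp.free_energy_surface(proj, bins=2, temperature=303.0)
        vals = np.sort(fes.free_energy[np.isfinite(fes.free_energy)])
        kbt = dp.KB_KCAL_PER_MOL_K * 303.0
        assert kbt == pytest.approx(0.602, abs=0.002)
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(kbt, rel=1e-2)

    def test_uniform_occupancy_is_flat_zero(self):
        x, y = np.meshgrid(np.arange(4), np.arange(4))
        proj = np.column_stack([x.ravel(), y.ravel()]).astype(float)
        fes = dp.free_energy_surface(proj, bins=4)
        np.testing.assert_allclose(fes.free_energy, 0.0, atol=1e-12)

    def test_minimum_over_occupied_bins_is_zero(self):
        rng = np.random.default_rng(25)
        proj = rng.standard_normal((500, 2))
        fes = dp.free_energy_surface(proj, bins=20)
        finite = fes.free_energy[np.isfinite(fes.free_energy)]
        assert finite.min() == 0.0
        assert np.all(finite >= 0.0)
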