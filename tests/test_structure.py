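"""Structure parsing, BW numbering, collective variables and motion analyses."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conformscape import structure as st
from conformscape.errors import (BWResolutionError, DegenerateInputError,
                                 EmptySelectionError, FeaturizationError,
                                 ParseError)
from conformscape.structure import (DEFAULT_BW_MAP, ContactProfile, Trajectory,
                                    build_bw_map, compute_cv, contact_fraction,
                                    dccm, dihedral_angle, kabsch_rotation,
                                    pca_modes, read_structure, rmsf)

from conftest import random_rigid_motion


class TestReadStructure:
    def test_single_atom_identity_parse(self):
        line = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
                "  1.00  0.00           C")
        s = read_structure(line + "\nEND\n")
        res_ids, coords = s.ca_table()
        assert res_ids.tolist() == [1]
        assert np.allclose(coords[0], [1.0, 2.0, 3.0])

    def test_toy_bundle_round_trip(self, toy_bundle):
        s = read_structure(toy_bundle.pdb_text)
        assert s.n_atoms == toy_bundle.n_atoms
        res_ids, _ = s.ca_table("A")
        assert len(res_ids) == toy_bundle.n_residues
        assert s.ligand_coords().shape == (1, 3)

    def test_malformed_coordinate_names_line(self):
        bad = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000\n"
               "ATOM      2  CA  ALA A   2       x.xxx   2.000   3.000\n")
        with pytest.raises(ParseError, match="line 2"):
            read_structure(bad)

    def test_no_atoms_rejected(self):
        with pytest.raises(ParseError):
            read_structure("REMARK nothing here\n")

    def test_empty_ca_selection(self, toy_bundle):
        s = read_structure(toy_bundle.pdb_text)
        with pytest.raises(EmptySelectionError):
            s.ca_table("Z")

    def test_longest_protein_chain(self, toy_bundle):
        s = read_structure(toy_bundle.pdb_text)
        assert s.longest_protein_chain() == "A"


class TestBWMap:
    def test_resolution_arithmetic_from_anchors(self):
        # offsets from the x.50 anchors (6.50=271 ⇒ 6.25=246, 6.24=245,
        # 6.35=256; 7.50=315 ⇒ 7.39=304) reproduce the printed labels
        assert DEFAULT_BW_MAP.resolve("6.25") == 246
        assert DEFAULT_BW_MAP.resolve("6.24") == 245
        assert DEFAULT_BW_MAP.resolve("6.35") == 256
        assert DEFAULT_BW_MAP.resolve("7.39") == 304

    def test_anchor_resolves_to_itself(self):
        assert DEFAULT_BW_MAP.resolve("3.50") == 142

    def test_cv_codes_resolve_to_expected_residues(self):
        expected = {"2.40": 80, "5.63": 236, "6.25": 246,
                    "8.54": 329, "7.56": 321, "7.54": 319, "7.47": 312}
        for code, residue in expected.items():
            assert DEFAULT_BW_MAP.resolve(code) == residue

    def test_missing_anchor_and_out_of_range(self):
        bw = build_bw_map({"6": 271}, {"6": (245, 285)})
        with pytest.raises(BWResolutionError):
            bw.resolve("3.50")
        with pytest.raises(BWResolutionError):
            bw.resolve("6.99")

    def test_anchor_outside_range_rejected(self):
        with pytest.raises(BWResolutionError):
            build_bw_map({"6": 300}, {"6": (245, 285)})


class TestComputeCV:
    FRAME = {80: (0.0, 0.0, 0.0), 236: (3.0, 4.0, 0.0), 246: (0.0, 0.0, 5.0),
             329: (0.0, 0.0, 1.0), 321: (1.0, 0.0, 1.0),
             319: (1.0, 1.0, 1.0), 312: (0.0, 1.0, 1.0)}

    def test_distance_sum_three_four_five(self):
        d, _ = compute_cv(self.FRAME)
        assert d == pytest.approx(10.0)

    def test_planar_cis_trans_dihedrals(self):
        # the frame's four dihedral points trace a planar U-turn: cis = 0
        _, chi = compute_cv(self.FRAME)
        assert chi == pytest.approx(0.0, abs=1e-9)
        trans = dict(self.FRAME)
        trans[312] = (2.0, -1.0, 1.0)
        _, chi = compute_cv(trans)
        assert chi == pytest.approx(180.0)

    def test_missing_residue_names_bw_code(self):
        frame = dict(self.FRAME)
        del frame[246]
        with pytest.raises(FeaturizationError, match="6.25"):
            compute_cv(frame)

    def test_collinear_dihedral_rejected(self):
        frame = dict(self.FRAME)
        frame[321] = (0.0, 0.0, 2.0)
        frame[319] = (0.0, 0.0, 3.0)
        frame[312] = (0.0, 0.0, 4.0)
        with pytest.raises(DegenerateInputError):
            compute_cv(frame)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        ref = compute_cv(self.FRAME)
        for _ in range(20):
            Q, t = random_rigid_motion(rng)
            moved = {r: Q @ np.asarray(p) + t for r, p in self.FRAME.items()}
            d, chi = compute_cv(moved)
            assert d == pytest.approx(ref[0], abs=1e-9)
            circ = abs(chi - ref[1])
            assert min(circ, 360.0 - circ) < 1e-9

    def test_dihedral_wraps_into_0_360(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.standard_normal((4, 3)) * 5
            try:
                chi = dihedral_angle(*pts)
            except DegenerateInputError:
                continue
            assert 0.0 <= chi < 360.0


class TestRMSF:
    def test_static_trajectory_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 8, 3)), (5, 1, 1))
        traj = Trajectory(coords=coords, res_ids=np.arange(8))
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        traj = Trajectory(coords=np.zeros((1, 4, 3)), res_ids=np.arange(4))
        with pytest.raises(DegenerateInputError):
            rmsf(traj)

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        # one jittered residue among many fixed anchors; no net rotation
        rng = np.random.default_rng(13)
        sigma = 0.08
        base = rng.uniform(-10, 10, size=(40, 3))
        coords = np.tile(base, (10_000, 1, 1))
        coords[:, 0, :] += sigma * rng.standard_normal((10_000, 3))
        traj = Trajectory(coords=coords, res_ids=np.arange(40))
        # no net rotation by construction, so the closed form is exact
        # without superposition (fitting would absorb a little of the jitter)
        vals = rmsf(traj, superpose=False)
        assert vals.iloc[0] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_duplicated_residues_identical(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(20, 6, 3))
        coords[:, 5, :] = coords[:, 2, :]
        traj = Trajectory(coords=coords, res_ids=np.arange(6))
        vals = rmsf(traj, superpose=False)
        assert vals.iloc[5] == pytest.approx(vals.iloc[2], abs=1e-12)


class TestPCA:
    def test_single_direction_is_pc1(self):
        t = np.linspace(-1, 1, 30)
        coords = np.zeros((30, 5, 3))
        coords[:, 2, 0] = t
        traj = Trajectory(coords=coords + 7.0, res_ids=np.arange(5))
        _, eigvals, per_res = pca_modes(traj, 2, superpose=False)
        assert eigvals[0] > 0
        assert eigvals[1] == pytest.approx(0.0, abs=1e-20)
        assert np.argmax(per_res[0]) == 2

    def test_orthogonal_motions_eigenvalue_ratio(self):
        rng = np.random.default_rng(2)
        n = 4000
        a = 2.0 * rng.standard_normal(n)
        b = 1.0 * rng.standard_normal(n)
        coords = np.zeros((n, 4, 3))
        coords[:, 0, 0] = a
        coords[:, 1, 1] = b
        traj = Trajectory(coords=coords, res_ids=np.arange(4))
        _, eigvals, _ = pca_modes(traj, 2, superpose=False)
        assert eigvals[0] / eigvals[1] == pytest.approx(4.0, rel=0.15)

    def test_matches_dense_covariance_oracle(self):
        rng = np.random.default_rng(17)
        coords = rng.normal(size=(5, 6, 3))
        traj = Trajectory(coords=coords, res_ids=np.arange(6))
        _, eigvals, _ = pca_modes(traj, 4, superpose=False)
        flat = coords.reshape(5, -1)
        flat = flat - flat.mean(axis=0)
        oracle = np.sort(np.linalg.eigvalsh(flat.T @ flat / 4))[::-1]
        assert np.allclose(eigvals, oracle[:4], atol=1e-10)

    def test_rank_error(self):
        traj = Trajectory(coords=np.random.default_rng(0).normal(size=(3, 4, 3)),
                          res_ids=np.arange(4))
        with pytest.raises(DegenerateInputError):
            pca_modes(traj, 5)

    def test_total_variance_consistent_with_rmsf(self):
        rng = np.random.default_rng(23)
        coords = rng.normal(size=(50, 7, 3))
        traj = Trajectory(coords=coords, res_ids=np.arange(7))
        vals = rmsf(traj, superpose=False)
        _, eigvals, _ = pca_modes(traj, 21, superpose=False)
        # sum RMSF² uses 1/F normalization, eigenvalues use 1/(F-1)
        assert (vals ** 2).sum() == pytest.approx(eigvals.sum() * 49 / 50, rel=1e-10)


class TestDCCM:
    def test_diagonal_and_anticorrelated_pair(self):
        rng = np.random.default_rng(4)
        motion = rng.standard_normal((100, 3))
        coords = rng.normal(size=(100, 5, 3)) * 0.01
        coords[:, 1, :] += motion
        coords[:, 3, :] -= motion  # exact negation of residue 1's displacement
        traj = Trajectory(coords=coords, res_ids=np.arange(5))
        m = dccm(traj, superpose=False)
        assert np.allclose(np.diag(m.values), 1.0)
        big = np.zeros((100, 2, 3))
        big[:, 0, :] = motion
        big[:, 1, :] = -motion
        pure = dccm(Trajectory(coords=big, res_ids=np.arange(2)), superpose=False)
        assert pure.values[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_interval_not_clamped(self):
        rng = np.random.default_rng(9)
        traj = Trajectory(coords=rng.normal(size=(60, 8, 3)), res_ids=np.arange(8))
        m = dccm(traj)
        assert np.allclose(m.values, m.values.T, atol=1e-12)
        assert (m.values <= 1 + 1e-12).all() and (m.values >= -1 - 1e-12).all()

    def test_independent_displacements_near_zero(self):
        rng = np.random.default_rng(31)
        coords = rng.standard_normal((10_000, 2, 3)) * 0.1
        coords[:, 0, :] += np.array([5.0, 0, 0])
        m = dccm(Trajectory(coords=coords, res_ids=np.arange(2)), superpose=False)
        assert abs(m.values[0, 1]) < 0.1

    def test_zero_variance_marked_missing(self):
        coords = np.random.default_rng(1).normal(size=(20, 3, 3))
        coords[:, 2, :] = 1.0
        m = dccm(Trajectory(coords=coords, res_ids=np.arange(3)), superpose=False)
        assert np.isnan(m.values[2, 0]) and np.isnan(m.values[0, 2])

    def test_mask_affects_display_only(self):
        rng = np.random.default_rng(6)
        traj = Trajectory(coords=rng.normal(size=(30, 4, 3)), res_ids=np.arange(4))
        m = dccm(traj, mask_threshold=0.3)
        shown = m.masked()
        small = np.abs(m.values) < 0.3
        assert np.isnan(shown[small]).all()
        assert not np.isnan(m.values).any()


class TestKabsch:
    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(8)
        P = rng.normal(size=(12, 3))
        P -= P.mean(axis=0)
        Q = rng.normal(size=(12, 3))
        Q -= Q.mean(axis=0)
        R = kabsch_rotation(P, Q)
        rot, _ = Rotation.align_vectors(Q, P)
        assert np.allclose(R, rot.as_matrix().T, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestContacts:
    def _traj(self):
        coords = np.zeros((10, 3, 3))
        coords[:, 0, :] = [0, 0, 0]
        coords[:, 1, :] = [20, 0, 0]
        coords[:, 2, :] = [40, 0, 0]
        return Trajectory(coords=coords, res_ids=np.array([101, 102, 103]))

    def test_always_close_and_always_far(self):
        ligand = np.tile(np.array([[3.0, 0, 0]]), (10, 1, 1))
        prof = contact_fraction(self._traj(), ligand)
        assert prof.fractions.loc[101] == 1.0
        assert prof.fractions.loc[103] == 0.0
        assert prof.selected.tolist() == [101]

    def test_exact_six_of_ten_frames_selected(self):
        ligand = np.full((10, 1, 3), 100.0)
        ligand[:6, 0, :] = [0, 0, 3.9]
        prof = contact_fraction(self._traj(), ligand)
        assert prof.fractions.loc[101] == pytest.approx(0.6)
        assert 101 in prof.selected

    def test_frame_mismatch(self):
        with pytest.raises(DegenerateInputError):
            contact_fraction(self._traj(), np.zeros((7, 1, 3)))
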