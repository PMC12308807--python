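"""Featurization and file I/O: distances, torsions, sin/cos, text formats."""

import math

import numpy as np
import pytest
from MDAnalysis.lib.distances import calc_dihedrals

from ptsne import (
    ConformationSet,
    dihedral_angle,
    distance_features,
    heavy_atom_indices,
    make_toy_conformations,
    read_matrix,
    read_xyz,
    sincos_features,
    write_matrix,
    write_xyz,
)


class TestReadMatrix:
    def test_plain_read(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2\n3 4\n5 6\n")
        np.testing.assert_array_equal(read_matrix(p), [[1, 2], [3, 4], [5, 6]])

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("# header\n1 2\n# middle\n3 4\n")
        assert read_matrix(p).shape == (2, 2)

    def test_column_selection_reorders(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2 3\n4 5 6\n")
        np.testing.assert_array_equal(
            read_matrix(p, columns=[2, 0]), [[3, 1], [6, 4]]
        )

    def test_ragged_row_reports_line_number(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2\n3 4 5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_matrix(p)

    def test_non_numeric_token_reports_line_number(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2\n3 oops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_matrix(p)

    def test_empty_selection_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2\n")
        with pytest.raises(ValueError, match="empty"):
            read_matrix(p, columns=[])

    def test_round_trip_through_writer(self, tmp_path, rng):
        X = rng.normal(size=(4, 3))
        p = tmp_path / "m.tsv"
        write_matrix(p, X, header=["a", "b", "c"])
        np.testing.assert_allclose(read_matrix(p), X, atol=1e-9)


class TestXYZ:
    def test_single_frame(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("3\ncomment\nC 0 0 0\nO 1 0 0\nH 0 1 0\n")
        conf = read_xyz(p)
        assert conf.n_frames == 1 and conf.n_atoms == 3
        assert conf.atom_labels == ["C", "O", "H"]

    def test_two_frame_round_trip(self, tmp_path, rng):
        conf = ConformationSet(rng.normal(size=(2, 4, 3)), ["C", "H", "N", "O"])
        p = tmp_path / "b.xyz"
        write_xyz(p, conf)
        back = read_xyz(p)
        np.testing.assert_allclose(back.coords, conf.coords, atol=1e-9)
        assert back.atom_labels == conf.atom_labels

    def test_malformed_count_line_names_line(self, tmp_path):
        p = tmp_path / "c.xyz"
        p.write_text("two\ncomment\nC 0 0 0\n")
        with pytest.raises(ValueError, match="line 1"):
            read_xyz(p)

    def test_inconsistent_atom_count_names_frame(self, tmp_path):
        p = tmp_path / "d.xyz"
        p.write_text("2\n\nC 0 0 0\nH 1 0 0\n3\n\nC 0 0 0\nH 1 0 0\nH 0 1 0\n")
        with pytest.raises(ValueError, match="frame 1"):
            read_xyz(p)


class TestDistanceFeatures:
    def test_ten_heavy_atoms_give_45_features(self):
        conf, _ = make_toy_conformations(3, 20, random_state=0)
        sel = heavy_atom_indices(conf)
        assert len(sel) == 10
        assert distance_features(conf, sel).shape == (3, 45)

    def test_two_atoms_unit_distance(self):
        conf = ConformationSet(np.array([[[0, 0, 0], [1, 0, 0]]], float))
        np.testing.assert_allclose(distance_features(conf, [0, 1]), [[1.0]])

    def test_matches_brute_force_pair_loop(self, rng):
        conf = ConformationSet(rng.normal(size=(2, 4, 3)))
        feats = distance_features(conf, [0, 1, 2, 3])
        for f in range(2):
            expected = [
                math.dist(conf.coords[f, i], conf.coords[f, j])
                for i in range(4)
                for j in range(i + 1, 4)
            ]
            np.testing.assert_allclose(feats[f], expected, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        conf, _ = make_toy_conformations(4, 8, random_state=1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = ConformationSet(conf.coords @ q.T + np.array([5.0, -2.0, 9.0]),
                                conf.atom_labels)
        np.testing.assert_allclose(
            distance_features(conf), distance_features(moved), atol=1e-9
        )

    def test_duplicate_selection_rejected(self):
        conf = ConformationSet(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="duplicate"):
            distance_features(conf, [0, 0])


class TestDihedral:
    @staticmethod
    def _four_atoms(phi_deg):
        """Planar-to-torsion geometry: b-c along x, 120-degree bond angles."""
        phi = math.radians(phi_deg)
        coords = np.array([[
            [-0.5, math.sqrt(3) / 2, 0.0],
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [1.5, math.sqrt(3) / 2 * math.cos(phi), math.sqrt(3) / 2 * math.sin(phi)],
        ]])
        return ConformationSet(coords)

    def test_planar_cis_is_zero(self):
        assert dihedral_angle(self._four_atoms(0.0), (0, 1, 2, 3))[0] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_planar_trans_is_180(self):
        assert dihedral_angle(self._four_atoms(180.0), (0, 1, 2, 3))[
            0
        ] == pytest.approx(180.0, abs=1e-9)

    def test_gauche_pm60_matches_independent_implementation(self):
        for phi in (60.0, -60.0):
            conf = self._four_atoms(phi)
            mine = dihedral_angle(conf, (0, 1, 2, 3))[0]
            assert abs(mine) == pytest.approx(60.0, abs=1e-9)
            other = math.degrees(
                calc_dihedrals(*(conf.coords[0, i][None] for i in range(4)))[0]
            )
            assert mine == pytest.approx(other, abs=1e-6)

    def test_random_torsions_match_mdanalysis(self):
        conf, _ = make_toy_conformations(5, 9, random_state=4)
        for q in [(0, 1, 2, 3), (2, 3, 4, 5), (5, 6, 7, 8)]:
            mine = dihedral_angle(conf, q)
            other = np.degrees(
                calc_dihedrals(*(np.ascontiguousarray(conf.coords[:, i]) for i in q))
            )
            np.testing.assert_allclose(mine, other, atol=1e-6)

    def test_collinear_geometry_flagged_nan(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0, 1, 2, 3]  # all on the x axis
        conf = ConformationSet(coords)
        assert np.isnan(dihedral_angle(conf, (0, 1, 2, 3))[0])

    def test_duplicate_indices_rejected(self):
        conf = ConformationSet(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError, match="distinct"):
            dihedral_angle(conf, (0, 1, 1, 2))


class TestSinCos:
    def test_six_angles_give_12_features(self, rng):
        A = rng.uniform(-180, 180, size=(7, 6))
        assert sincos_features(A).shape == (7, 12)

    def test_zero_angle_maps_to_sin0_cos1(self):
        np.testing.assert_allclose(sincos_features([[0.0]]), [[0.0, 1.0]])

    def test_rows_on_unit_circle(self, rng):
        A = rng.uniform(-180, 180, size=(20, 3))
        F = sincos_features(A)
        s, c = F[:, 0::2], F[:, 1::2]
        np.testing.assert_allclose(s**2 + c**2, 1.0, atol=1e-12)

    def test_radian_input_flag(self):
        F = sincos_features([[math.pi / 2]], degrees=False)
        np.testing.assert_allclose(F, [[1.0, 0.0]], atol=1e-12)
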