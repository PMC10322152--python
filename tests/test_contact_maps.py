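import numpy as np
import pytest

from statecoev import contact_maps as cm, synthetic
from statecoev.coevolution import CoevolutionMap
from statecoev.contact_maps import (ResidueDistanceMatrix, SoftContactMap,
                                    ca_rmsd, map_similarity, optimize_t,
                                    pca_project, soft_contact_map)
from statecoev.errors import DataError, FrameMismatchError, InsufficientDataError


def _dm(d, state="unknown", sid="s"):
    return ResidueDistanceMatrix(distances=d, structure_id=sid, state=state)


class TestSoftContactMap:
    @pytest.mark.parametrize("r,expected", [
        (4.0, 0.5),
        (0.0, 1.0 / (1.0 + np.exp(-8.0))),
        (8.0, 1.0 / (1.0 + np.exp(8.0))),
    ])
    def test_sigmoid_closed_form(self, r, expected):
        d = np.array([[0.0, r], [r, 0.0]])
        m = soft_contact_map(_dm(d))
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_r(self):
        r = np.linspace(0.0, 20.0, 200)
        vals = 1.0 / (1.0 + np.exp(2.0 * r - 8.0))
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(DataError):
            _dm(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_state_label_carried(self):
        m = soft_contact_map(_dm(np.zeros((3, 3)), state="occluded"))
        assert m.state == "occluded"


class TestMapSimilarity:
    def _random_setup(self, rng, L=50):
        s = rng.standard_normal((L, L))
        C = CoevolutionMap(scores=s + s.T)
        mx = SoftContactMap(values=(lambda v: (v + v.T) / 2)(rng.uniform(0, 1, (L, L))))
        my = SoftContactMap(values=(lambda v: (v + v.T) / 2)(rng.uniform(0, 1, (L, L))))
        return C, mx, my

    def test_self_similarity_is_squared_norm(self, rng):
        C, mx, _ = self._random_setup(rng, L=10)
        d = map_similarity(C, mx, mx)
        assert d == pytest.approx(np.sum((C.scores * mx.values) ** 2))

    def test_zero_map_gives_zero(self, rng):
        C, mx, _ = self._random_setup(rng, L=8)
        my = SoftContactMap(values=np.zeros((8, 8)))
        assert map_similarity(C, mx, my) == 0.0

    def test_matches_brute_force_triple_loop(self, rng):
        C, mx, my = self._random_setup(rng, L=50)
        expected = 0.0
        for i in range(50):
            for j in range(50):
                expected += (C.scores[i, j] * mx.values[i, j]
                             * C.scores[i, j] * my.values[i, j])
        assert map_similarity(C, mx, my) == pytest.approx(expected, rel=1e-9)

    def test_symmetric(self, rng):
        C, mx, my = self._random_setup(rng, L=20)
        assert map_similarity(C, mx, my) == pytest.approx(
            map_similarity(C, my, mx))

    def test_frame_mismatch(self, rng):
        C, mx, _ = self._random_setup(rng, L=8)
        my = SoftContactMap(values=np.zeros((9, 9)))
        with pytest.raises(FrameMismatchError):
            map_similarity(C, mx, my)


class TestOptimizeT:
    def test_identical_ensembles_flat_objective(self, rng):
        L = 30
        s = np.abs(rng.standard_normal((L, L)))
        C = CoevolutionMap(scores=s + s.T)
        v = rng.uniform(0, 1, (L, L))
        base = SoftContactMap(values=(v + v.T) / 2)
        maps = []
        for state in ("a", "b"):
            for k in range(2):
                maps.append(SoftContactMap(values=base.values, state=state,
                                           structure_id=f"{state}{k}"))
        with pytest.warns(UserWarning, match="flat"):
            _t, curve = optimize_t(maps, C, t_grid=[5, 10, 15])
        assert curve["degenerate"]

    def test_single_t_returned_unchanged(self, classifier_world):
        world, maps, _dms, cmap = classifier_world
        t, curve = optimize_t(maps, cmap, t_grid=[25])
        assert t == 25 and set(curve) == {25, "degenerate"}

    def test_state_with_one_map_rejected(self, classifier_world):
        _w, maps, _d, cmap = classifier_world
        broken = maps[:6]  # 5 of state 1, 1 of state 2
        with pytest.raises(InsufficientDataError):
            optimize_t(broken, cmap, t_grid=[10])

    def test_embedding_reproducible(self, classifier_world):
        _w, maps, _d, cmap = classifier_world
        t1, c1 = optimize_t(maps, cmap, t_grid=[20, 30], seed=0)
        t2, c2 = optimize_t(maps, cmap, t_grid=[20, 30], seed=0)
        assert t1 == t2 and c1 == c2

    def test_objective_invariant_under_id_relabeling(self, classifier_world):
        _w, maps, _d, cmap = classifier_world
        relabeled = [SoftContactMap(values=m.values, state=m.state,
                                    structure_id=f"x{k}")
                     for k, m in enumerate(maps)]
        _t1, c1 = optimize_t(maps, cmap, t_grid=[20, 40])
        _t2, c2 = optimize_t(relabeled, cmap, t_grid=[20, 40])
        assert c1 == c2


class TestCaRmsd:
    def test_identical_structures(self, rng):
        a = rng.standard_normal((10, 3))
        assert ca_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, rng):
        from scipy.spatial.transform import Rotation
        a = rng.standard_normal((10, 3))
        R = Rotation.from_euler("xyz", [np.pi / 2, 0.3, -1.0]).as_matrix()
        b = a @ R.T + np.array([4.0, -2.0, 7.0])
        assert ca_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        from scipy.spatial.transform import Rotation
        a = rng.standard_normal((4, 3))
        b = rng.standard_normal((4, 3))
        got = ca_rmsd(a, b)
        # independent superposition via scipy's quaternion-based solver
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _rot, rssd = Rotation.align_vectors(ac, bc)
        assert got == pytest.approx(rssd / np.sqrt(4), abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            ca_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_pairing_applied(self, rng):
        a = rng.standard_normal((6, 3))
        b = a[::-1]
        pairing = [(i, 5 - i) for i in range(6)]
        assert ca_rmsd(a, b, pairing) == pytest.approx(0.0, abs=1e-9)


class TestBlosumDistance:
    def test_self_distance_zero(self):
        assert cm.blosum_distance("ACDEFGHIK", "ACDEFGHIK") == pytest.approx(0.0)

    def test_diverged_positive(self):
        assert cm.blosum_distance("AAAAAA", "WWWWWW") > 0.5

    def test_no_overlap_rejected(self):
        with pytest.raises(InsufficientDataError):
            cm.blosum_distance("AC---", "--DEF")

    def test_frame_mismatch(self):
        with pytest.raises(FrameMismatchError):
            cm.blosum_distance("ACDEF", "ACDE")


class TestPCA:
    def test_collinear_points_one_component(self, rng):
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer(rng.standard_normal(20), direction)
        res = pca_project(X, n_components=2)
        assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-18)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((15, 6))
        res = pca_project(X, n_components=None)
        assert np.allclose(res.reconstruct(), X, atol=1e-9)

    def test_deterministic_sign_convention(self, rng):
        X = rng.standard_normal((12, 5))
        r1 = pca_project(X)
        r2 = pca_project(X)
        assert np.allclose(r1.coordinates, r2.coordinates)


PDB_FIXTURE = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   1       1.958  -0.800  -1.200  1.00  0.00           C
ATOM      5  N   GLY A   2       5.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       6.458   0.000   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       7.000   1.400   0.000  1.00  0.00           C
ATOM      8  N   SER A   3      12.000   0.000   0.000  1.00  0.00           N
ATOM      9  CA  SER A   3      13.458   0.000   0.000  1.00  0.00           C
ATOM     10  OG  SER A   3      13.958   1.200   0.700  1.00  0.00           O
END
"""


class TestStructureReading:
    def test_min_heavy_atom_distances(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_FIXTURE)
        dm = cm.read_structure_distances(p, state="occluded")
        assert dm.length == 3
        assert dm.state == "occluded"
        # residues 1-2: closest heavy atoms are C(2.0,1.4,0) and N(5,0,0)
        expected = np.linalg.norm(np.array([2.0, 1.4, 0.0]) - np.array([5.0, 0.0, 0.0]))
        assert dm.distances[0, 1] == pytest.approx(expected, abs=1e-6)
        assert dm.distances[0, 1] == dm.distances[1, 0]

    def test_cache_round_trip(self, tmp_path, rng):
        d = rng.uniform(1, 20, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = ResidueDistanceMatrix(distances=d, structure_id="x",
                                   state="inward_open",
                                   column_map={0: 3, 1: 4})
        cm.save_distance_matrix(dm, tmp_path / "x")
        again = cm.load_distance_matrix(tmp_path / "x")
        assert np.allclose(again.distances, dm.distances, atol=1e-5)
        assert again.state == dm.state
        assert again.column_map == dm.column_map


class TestColumnMapping:
    def test_maps_through_alignment_row(self):
        # structure sequence aligns to the ungapped row; row positions carry
        # the MSA column indices.
        row = "AC-DEF-GH"
        mapping = cm.map_structure_to_columns("ACDEFGH", row)
        assert mapping == {0: 0, 1: 1, 2: 3, 3: 4, 4: 5, 5: 7, 6: 8}

    def test_kept_columns_filter(self):
        row = "ACDEF"
        mapping = cm.map_structure_to_columns("ACDEF", row,
                                              kept_columns=np.array([0, 2, 4]))
        assert mapping == {0: 0, 2: 2, 4: 4}
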