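"""Kabsch superposition, RMSD matrices and greedy neighbor-count clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amylens.cluster import (
    ClusterResult, RMSDMatrix, daura_cluster, kabsch_superpose, rmsd_matrix,
    superpose_conformation, top_families,
)
from conftest import motif_ensemble, random_rotation


def brute_force_rmsd(P, Q, coarse=24, refine_levels=4):
    """Rotation-grid search oracle for the minimal RMSD of centered sets."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def rot(a, b, c):
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return Rz1 @ Ry @ Rz2

    def rmsd_at(a, b, c):
        d = P @ rot(a, b, c).T - Q
        return np.sqrt((d ** 2).sum() / len(P))

    grid = np.linspace(0, 2 * np.pi, coarse, endpoint=False)
    bgrid = np.linspace(0, np.pi, coarse // 2 + 1)
    best = min(
        ((rmsd_at(a, b, c), (a, b, c))
         for a in grid for b in bgrid for c in grid),
        key=lambda t: t[0],
    )
    val, (a, b, c) = best
    step = 2 * np.pi / coarse
    for _ in range(refine_levels):
        cand = [(rmsd_at(a + da, b + db, c + dc), (a + da, b + db, c + dc))
                for da in np.linspace(-step, step, 5)
                for db in np.linspace(-step, step, 5)
                for dc in np.linspace(-step, step, 5)]
        val, (a, b, c) = min(cand, key=lambda t: t[0])
        step /= 4
    return val


def naive_daura(D, cutoff):
    """Independent reference implementation of the greedy clustering."""
    n = D.shape[0]
    remaining = set(range(n))
    families = []
    while remaining:
        best_i, best_neigh = None, None
        for i in sorted(remaining):
            neigh = {j for j in remaining if D[i, j] < cutoff}
            if best_neigh is None or len(neigh) > len(best_neigh):
                best_i, best_neigh = i, neigh
        families.append((best_i, sorted(best_neigh)))
        remaining -= best_neigh
    return families


class TestKabsch:
    def test_self_superposition_is_identity(self, helix_coil_conf):
        R, t, rmsd = superpose_conformation(helix_coil_conf, helix_coil_conf)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self, helix_coil_conf):
        rng = np.random.default_rng(17)
        Q = random_rotation(rng)
        moved = helix_coil_conf.transformed(Q, rng.normal(scale=15.0, size=3))
        _, _, rmsd = superpose_conformation(moved, helix_coil_conf)
        assert rmsd < 1e-6

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        # near-planar set that would tempt a reflection
        P = rng.normal(size=(6, 3)) * np.array([1.0, 1.0, 0.05])
        Q = -P  # inversion: only a proper rotation may be returned
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rotation_grid_oracle_on_4_points(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(4, 3)) * 3.0
        Q = rng.normal(size=(4, 3)) * 3.0
        _, _, rmsd = kabsch_superpose(P, Q)
        oracle = brute_force_rmsd(P, Q)
        assert rmsd <= oracle + 1e-6
        assert abs(rmsd - oracle) < 1e-3

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestRMSDMatrix:
    def test_identical_conformers_zero_matrix(self, human_seq):
        ens, _ = motif_ensemble("helix-coil", human_seq, 1, seed=5)
        from amylens.model_io import Ensemble
        rep = Ensemble(human_seq, [ens[0]] * 4)
        m = rmsd_matrix(rep)
        assert m.values.max() < 1e-9

    def test_two_conformers_one_independent_value(self, human_seq):
        ens, _ = motif_ensemble("helix-coil", human_seq, 2, seed=5, sigma=3.0)
        m = rmsd_matrix(ens)
        assert m.values.shape == (2, 2)
        assert m.values[0, 1] == m.values[1, 0] > 0
        assert m.values[0, 0] == m.values[1, 1] == 0

    def test_jittered_helices_stay_within_cutoff(self, human_seq):
        """20 sigma=2 deg copies of the helix motif are mutually closer
        than the 3.0 A family cutoff over the helix residues."""
        ens, _ = motif_ensemble("helix-coil", human_seq, 20, seed=13, sigma=2.0)
        m = rmsd_matrix(ens, residue_selection=range(8, 18))
        assert m.values.max() < 3.0

    def test_matches_pairwise_kabsch(self, human_seq):
        ens, _ = motif_ensemble("beta-hairpin", human_seq, 5, seed=2, sigma=3.0)
        m = rmsd_matrix(ens)
        for i, j in itertools.combinations(range(5), 2):
            _, _, r = superpose_conformation(ens[i], ens[j])
            assert m.values[i, j] == pytest.approx(r, abs=1e-8)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RMSDMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            RMSDMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestDauraCluster:
    def _matrix(self, D):
        D = np.asarray(D, dtype=float)
        return RMSDMatrix((D + D.T) / 2)

    def test_all_close_one_family(self):
        n = 7
        D = np.full((n, n), 1.0)
        np.fill_diagonal(D, 0.0)
        res = daura_cluster(self._matrix(D), cutoff=3.0)
        assert len(res.families) == 1
        assert sorted(res.families[0].members) == list(range(n))

    def test_all_far_singletons(self):
        n = 6
        D = np.full((n, n), 9.0)
        np.fill_diagonal(D, 0.0)
        res = daura_cluster(self._matrix(D), cutoff=3.0)
        assert len(res.families) == n
        assert all(f.size == 1 for f in res.families)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_independent_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.uniform(0, 6, size=(40, 40))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        res = daura_cluster(RMSDMatrix(D), cutoff=3.0)
        oracle = naive_daura(D, 3.0)
        assert len(res.families) == len(oracle)
        for fam, (cent, members) in zip(res.families, oracle):
            assert fam.centroid == cent
            assert sorted(fam.members) == members

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_partition_and_dominance_properties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        D = rng.uniform(0, 5, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        res = daura_cluster(RMSDMatrix(D), cutoff=2.5)
        members = sorted(m for f in res.families for m in f.members)
        assert members == list(range(n))  # exact partition
        sizes = [f.size for f in res.families]
        assert sizes == sorted(sizes, reverse=True)  # greedy dominance
        for f in res.families:
            assert all(D[f.centroid, m] < 2.5 or m == f.centroid
                       for m in f.members)

    def test_deterministic_tie_break_lowest_index(self):
        # two disjoint pairs: both centroids have 2 neighbors; index 0 first
        D = np.full((4, 4), 9.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 1.0
        res = daura_cluster(RMSDMatrix(D), cutoff=2.0)
        assert res.families[0].centroid == 0
        assert res.families[1].centroid == 2


class TestTopFamilies:
    def _result(self, sizes, n):
        fams = []
        start = 0
        from amylens.cluster import Family
        for s in sizes:
            fams.append(Family(list(range(start, start + s)), start))
            start += s
        return ClusterResult(fams, 3.0, n)

    def test_min_fraction_and_max_k(self):
        res = self._result((50, 30, 15, 4, 1), 100)
        assert len(top_families(res, min_fraction=0.01)) == 5
        assert len(top_families(res, min_fraction=0.05)) == 3
        assert [f.size for f in top_families(res, max_k=2)] == [50, 30]

    def test_single_family_dominates(self):
        res = self._result((100,), 100)
        assert len(top_families(res)) == 1
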