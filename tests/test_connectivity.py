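"""Connectivity statistics: worked examples, oracles, and error paths."""

import warnings

import numpy as np
import pytest

from dmfconn.connectivity import (ConnectivityMap, SubjectExcluded,
                                  VoxelDataset, censor_frames, cohen_d_map,
                                  dice, fc_matrix, fisher_z,
                                  global_connectivity, grid_adjacency,
                                  group_tmap, occurrence_map,
                                  permutation_cluster_correct, residualize,
                                  seed_map)


def _toy_voxels(data, spacing_um=100.0):
    data = np.asarray(data, dtype=float)
    coords = np.zeros((data.shape[0], 3))
    coords[:, 0] = spacing_um * np.arange(data.shape[0])
    return VoxelDataset(data=data, coords=coords)


def _orthobasis(t, k, seed):
    """k orthonormal zero-mean timeseries (exact correlations by design)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((t, k))
    X -= X.mean(axis=0)
    return np.linalg.qr(X)[0].T


class TestFCMatrix:
    def test_affine_copy_fully_correlated(self):
        rng = np.random.default_rng(0)
        y1 = rng.standard_normal(100)
        fc = fc_matrix(np.vstack([y1, 2 * y1 + 1]))
        assert fc.R[0, 1] == pytest.approx(1.0)

    def test_sign_flip_anticorrelated(self):
        rng = np.random.default_rng(1)
        y1 = rng.standard_normal(100)
        fc = fc_matrix(np.vstack([y1, -y1]))
        assert fc.R[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            fc = fc_matrix(rng.standard_normal((2, 1000)))
            hits += abs(fc.R[0, 1]) < 0.1
        assert hits >= 49

    def test_constant_row_flagged(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            fc = fc_matrix(ts)
        assert np.isnan(fc.R[0, 1])
        assert fc.R[0, 0] == 1.0

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(3)
        fc = fc_matrix(rng.standard_normal((5, 60)))
        np.testing.assert_allclose(fc.R, fc.R.T)
        np.testing.assert_allclose(np.diag(fc.R), 1.0)


class TestFisherZ:
    @pytest.mark.parametrize("r,z", [(0.0, 0.0), (0.5, 0.549306)])
    def test_values(self, r, z):
        assert fisher_z(r) == pytest.approx(z, abs=1e-6)

    def test_odd_symmetry(self):
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3))

    def test_clipping_keeps_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(4)
        ts = rng.standard_normal((4, 80))
        scaled = ts * np.array([[2.0], [0.5], [3.0], [1.0]]) + 7.0
        np.testing.assert_allclose(fc_matrix(ts).Z, fc_matrix(scaled).Z,
                                   atol=1e-10)


class TestGlobalConnectivity:
    def test_three_voxel_worked_example(self):
        # construct r12 = 0.8, r13 = 0, r23 = 0 exactly via orthonormal basis
        basis = _orthobasis(200, 3, 5)
        v1 = basis[0]
        v2 = 0.8 * basis[0] + np.sqrt(1 - 0.64) * basis[1]
        v3 = basis[2]
        gc = global_connectivity(_toy_voxels([v1, v2, v3]))
        expected = (np.arctanh(0.8) + 0.0) / 2
        assert gc.values[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.549306, abs=1e-6)

    def test_exclusion_radius_drops_near_voxel(self):
        basis = _orthobasis(200, 3, 6)
        v1 = basis[0]
        v2 = 0.8 * basis[0] + 0.6 * basis[1]
        v3 = basis[2]
        ds = _toy_voxels([v1, v2, v3], spacing_um=500.0)
        gc = global_connectivity(ds, exclusion_radius_um=600.0)
        # v2 at 500 um is excluded for v1; only v3 (1000 um) remains
        assert gc.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n_vox = 40
        data = rng.standard_normal((n_vox, 120))
        coords = rng.uniform(0, 2000, size=(n_vox, 3))
        ds = VoxelDataset(data=data, coords=coords)
        for radius in (0.0, 600.0):
            gc = global_connectivity(ds, exclusion_radius_um=radius)
            for i in range(n_vox):
                zs = []
                for j in range(n_vox):
                    if i == j:
                        continue
                    if radius > 0 and np.linalg.norm(
                            coords[i] - coords[j]) <= radius:
                        continue
                    r = np.corrcoef(data[i], data[j])[0, 1]
                    zs.append(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))
                assert gc.values[i] == pytest.approx(np.mean(zs), abs=1e-10)

    def test_identical_voxels_exercise_clipping(self):
        sig = np.sin(np.linspace(0, 8, 50))
        ds = _toy_voxels([sig, sig, sig])
        gc = global_connectivity(ds)
        assert np.all(np.isfinite(gc.values))
        assert gc.values[0] > 8  # atanh near the clip bound

    def test_all_excluded_raises(self):
        rng = np.random.default_rng(8)
        ds = _toy_voxels(rng.standard_normal((3, 50)), spacing_um=10.0)
        with pytest.raises(ValueError):
            global_connectivity(ds, exclusion_radius_um=1e6)


class TestSeedMap:
    def test_seed_voxel_clipped_and_orthogonal_near_zero(self):
        basis = _orthobasis(400, 2, 9)
        ds = _toy_voxels([basis[0], basis[1]])
        sm = seed_map(ds, [0])
        assert sm.values[0] > 8            # self-correlation, clipped z
        assert abs(sm.values[1]) < 1e-9    # orthogonal by construction

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        ds = _toy_voxels(rng.standard_normal((4, 100)))
        a = seed_map(ds, [0, 1]).values
        b = seed_map(ds, [0, 1]).values
        np.testing.assert_array_equal(a, b)

    def test_empty_seed_rejected(self):
        ds = _toy_voxels(np.random.default_rng(0).standard_normal((3, 50)))
        with pytest.raises(ValueError):
            seed_map(ds, [])


class TestGroupContrasts:
    def test_cohen_d_worked_example(self):
        d = cohen_d_map(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]))
        assert d.values[0] == pytest.approx(-2.828427, abs=1e-6)

    def test_cohen_d_null_and_antisymmetry(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((5, 7))
        d_ab = cohen_d_map(A, A.copy()).values
        np.testing.assert_allclose(d_ab, 0.0, atol=1e-12)
        B = rng.standard_normal((5, 7))
        np.testing.assert_allclose(cohen_d_map(A, B).values,
                                   -cohen_d_map(B, A).values)

    def test_tmap_worked_example(self):
        t = group_tmap(np.array([[1.0], [2.0], [3.0]]),
                       np.array([[4.0], [5.0], [6.0]]))
        assert t.values[0] == pytest.approx(-3.674235, abs=1e-6)

    def test_tmap_identical_groups_and_sign_flip(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((4, 6))
        np.testing.assert_allclose(group_tmap(A, A.copy()).values, 0.0,
                                   atol=1e-12)
        B = rng.standard_normal((4, 6))
        np.testing.assert_allclose(group_tmap(A, B).values,
                                   -group_tmap(B, A).values)

    def test_occurrence_map_counts(self):
        maps = [ConnectivityMap(np.array([0.25])),
                ConnectivityMap(np.array([0.19])),
                ConnectivityMap(np.array([0.21]))]
        assert occurrence_map(maps).values[0] == 2
        assert occurrence_map(maps, d_threshold=0.5).values[0] == 0
        assert occurrence_map([ConnectivityMap(np.array([0.3]))] * 7
                              ).values[0] == 7

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            group_tmap(np.ones((1, 3)), np.ones((4, 3)))


class TestPermutationClusterCorrection:
    def test_planted_cluster_detected_isolated_voxel_not(self):
        shape = (6, 6, 1)
        n_vox = 36
        adj = grid_adjacency(shape)
        rng = np.random.default_rng(13)
        effect = np.zeros(n_vox)
        # 3x3 planted block (indices of x in 0..2, y in 0..2)
        block = [x * 6 + y for x in range(3) for y in range(3)]
        effect[block] = 3.0
        A = rng.standard_normal((8, n_vox)) + effect
        B = rng.standard_normal((8, n_vox))
        tmap = group_tmap(A, B)
        clusters = permutation_cluster_correct(tmap, A, B, adj, n_perm=200,
                                               alpha=0.05, seed=0)
        sig = [c for c in clusters if c.significant]
        assert len(sig) >= 1
        covered = set(np.concatenate([c.voxels for c in sig]))
        # allow a stray planted voxel to fall below the cluster-forming
        # threshold by chance
        assert len(set(block) & covered) >= 7
        small = [c for c in clusters if c.extent == 1]
        assert all(not c.significant for c in small)

    def test_null_familywise_error_controlled(self):
        shape = (4, 3, 1)
        adj = grid_adjacency(shape)
        rng = np.random.default_rng(14)
        n_rep, rejections = 120, 0
        for _ in range(n_rep):
            A = rng.standard_normal((6, 12))
            B = rng.standard_normal((6, 12))
            clusters = permutation_cluster_correct(
                group_tmap(A, B), A, B, adj, n_perm=120, alpha=0.05,
                seed=int(rng.integers(2**31)))
            rejections += any(c.significant for c in clusters)
        rate = rejections / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_requires_enough_permutations(self):
        adj = grid_adjacency((2, 2, 1))
        A, B = np.ones((3, 4)), np.zeros((3, 4))
        with pytest.raises(ValueError):
            permutation_cluster_correct(group_tmap(A, B), A, B, adj, n_perm=10)


class TestDice:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
        ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
        ([1, 1, 1, 1, 0, 0], [1, 1, 0, 0, 1, 1], 0.5),
    ])
    def test_values(self, a, b, expected):
        assert dice(a, b) == pytest.approx(expected)

    def test_empty_masks_warn(self):
        with pytest.warns(UserWarning):
            assert np.isnan(dice([0, 0], [0, 0]))


class TestCensorFrames:
    def test_drops_high_motion_frames(self):
        ts = np.arange(6.0).reshape(2, 3)
        out = censor_frames(ts, np.array([0.1, 0.3, 0.15]),
                            fd_threshold_mm=0.2, min_fraction=0.5)
        np.testing.assert_array_equal(out, ts[:, [0, 2]])

    def test_low_motion_unchanged(self):
        ts = np.arange(6.0).reshape(2, 3)
        out = censor_frames(ts, np.full(3, 0.05))
        np.testing.assert_array_equal(out, ts)

    def test_subject_excluded_when_all_high(self):
        with pytest.raises(SubjectExcluded):
            censor_frames(np.ones((2, 3)), np.full(3, 0.9))


class TestResidualize:
    def _covs(self, n, rng):
        import pandas as pd
        return pd.DataFrame({
            "site": rng.choice(["a", "b", "c"], size=n),
            "age": rng.uniform(6, 13, size=n),
            "iq": rng.normal(100, 15, size=n),
        })

    def test_site_offsets_removed(self):
        import pandas as pd
        rng = np.random.default_rng(15)
        covs = self._covs(30, rng)
        offsets = covs["site"].map({"a": 0.0, "b": 5.0, "c": -3.0}).to_numpy()
        maps = rng.standard_normal((30, 4)) + offsets[:, None]
        res = residualize(maps, covs)
        for s in "abc":
            np.testing.assert_allclose(res[covs["site"] == s].mean(axis=0),
                                       0.0, atol=0.5)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(16)
        covs = self._covs(25, rng)
        maps = rng.standard_normal((25, 3))
        res = residualize(maps, covs)
        for col in ("age", "iq"):
            x = covs[col].to_numpy() - covs[col].mean()
            assert np.all(np.abs(x @ res) < 1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(17)
        covs = self._covs(20, rng)
        maps = rng.standard_normal((20, 3))
        once = residualize(maps, covs)
        np.testing.assert_allclose(residualize(once, covs), once, atol=1e-10)

    def test_collinear_design_named(self):
        import pandas as pd
        rng = np.random.default_rng(18)
        covs = pd.DataFrame({"age": rng.uniform(6, 13, 10)})
        covs["age_copy"] = covs["age"]
        with pytest.raises(ValueError, match="age_copy"):
            residualize(rng.standard_normal((10, 2)), covs)
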