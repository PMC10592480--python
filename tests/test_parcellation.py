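"""Bilateral k-means parcellation, pairing, cluster-count evaluation, consensus."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls
from sklearn.metrics import adjusted_rand_score

from corticostate import parcellation as parc, synthetic_data as sd
from corticostate.spectroscopy import correct_fluorescence, normalize_by_baseline


def planted_blocks(rng, n_blocks=4, pixels_per_block=25, T=400, noise=0.3):
    """Pixels grouped into blocks sharing a latent trace + independent noise."""
    latents = rng.normal(size=(n_blocks, T))
    labels = np.repeat(np.arange(n_blocks), pixels_per_block)
    data = latents[labels] + noise * rng.normal(size=(len(labels), T))
    return data, labels


class TestClusterHemisphere:
    def test_planted_blocks_recovered(self, rng):
        data, labels = planted_blocks(rng)
        out, cents = parc.cluster_hemisphere(data, 4, replicates=10, seed=0)
        assert adjusted_rand_score(labels, out) == pytest.approx(1.0)
        assert cents.centroids.shape == (4, 400)

    def test_permutation_invariance(self, rng):
        data, _ = planted_blocks(rng)
        out1, _ = parc.cluster_hemisphere(data, 4, replicates=5, seed=0)
        perm = rng.permutation(len(data))
        out2, _ = parc.cluster_hemisphere(data[perm], 4, replicates=5, seed=0)
        assert adjusted_rand_score(out1, out2[np.argsort(perm)]) == pytest.approx(1.0)

    def test_k1_single_cluster_mean_centroid(self, rng):
        data, _ = planted_blocks(rng, n_blocks=2, pixels_per_block=10)
        labels, cents = parc.cluster_hemisphere(data, 1, seed=0)
        assert np.all(labels == 0)
        assert np.allclose(cents.centroids[0], data.mean(axis=0), atol=1e-12)

    def test_determinism_under_seed(self, rng):
        data, _ = planted_blocks(rng)
        a, _ = parc.cluster_hemisphere(data, 4, replicates=5, seed=42)
        b, _ = parc.cluster_hemisphere(data, 4, replicates=5, seed=42)
        assert np.array_equal(a, b)


class TestMirrorAndPair:
    def test_symmetric_data_pairs_with_geometric_mirror(self, rng):
        data_left, labels = planted_blocks(rng, n_blocks=3, pixels_per_block=12)
        data_right = data_left.copy()  # perfectly mirror-symmetric
        left_assign, _ = parc.cluster_hemisphere(data_left, 3, replicates=5, seed=0)
        labels_right, pairs, _ = parc.mirror_and_pair(
            left_assign, data_left, data_right, lambda lab: lab, seed=0)
        assert sorted(l for l, _ in pairs) == [0, 1, 2]
        for l, r in pairs:
            cl = data_left[left_assign == l].mean(axis=0)
            cr = data_right[labels_right == r].mean(axis=0)
            assert np.corrcoef(cl, cr)[0, 1] > 0.999

    def test_greedy_matches_exhaustive_assignment(self, rng):
        # pairing solved optimally must equal brute force over all 4! matchings
        cents_l = rng.normal(size=(4, 300))
        cents_r = cents_l + 0.4 * rng.normal(size=(4, 300))
        corr = parc._pairwise_corr(cents_l, cents_r)
        from scipy.optimize import linear_sum_assignment
        ri, ci = linear_sum_assignment(-corr)
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(4)):
            score = sum(corr[i, perm[i]] for i in range(4))
            if score > best_score:
                best_perm, best_score = perm, score
        assert tuple(ci) == best_perm

    def test_pairs_form_bijection(self, active_session, active_config):
        raw, truth = active_session
        fn, gn, rn = normalize_by_baseline(raw)
        dff = correct_fluorescence(fn, gn, rn, truth.true_Pg, truth.true_Pr).dff
        rows, cols = active_config.image_shape
        width = (cols - 2) // 2
        pmap = parc.bilateral_parcellation(dff, active_config.image_shape, 8,
                                           (width, cols - width), replicates=5, seed=0)
        lefts = [l for l, _ in pmap.pairs]
        rights = [r for _, r in pmap.pairs]
        assert len(set(lefts)) == len(set(rights)) == 8
        assert set(lefts + rights) == set(np.unique(pmap.labels)) - {0}


@pytest.fixture(scope="module")
def recovered(active_session, active_config):
    raw, truth = active_session
    fn, gn, rn = normalize_by_baseline(raw)
    dff = correct_fluorescence(fn, gn, rn, truth.true_Pg, truth.true_Pr).dff
    rows, cols = active_config.image_shape
    width = (cols - 2) // 2
    pmap = parc.bilateral_parcellation(dff, active_config.image_shape, 8,
                                       (width, cols - width), replicates=10, seed=1)
    return pmap, truth


class TestPlantedRecovery:
    """End-to-end parcellation against the generator's ground truth."""

    def test_ari_at_least_0p9(self, recovered):
        pmap, truth = recovered
        mask = truth.parcel_labels.ravel() > 0
        ari = adjusted_rand_score(truth.parcel_labels.ravel()[mask],
                                  pmap.labels.ravel()[mask])
        assert ari >= 0.9

    def test_bilateral_pairing_exact(self, recovered):
        # every recovered pair must map onto a planted pair: the dominant truth
        # parcel under the left ROI and under the right ROI are partners
        pmap, truth = recovered
        n = len(truth.bilateral_pairs)
        flat_t = truth.parcel_labels.ravel()
        flat_r = pmap.labels.ravel()
        mask = flat_t > 0
        for l, r in pmap.pairs:
            tl = np.bincount(flat_t[(flat_r == l) & mask]).argmax()
            tr = np.bincount(flat_t[(flat_r == r) & mask]).argmax()
            assert tr == tl + n


class TestEvaluateClusterCount:
    def test_exact_nonnegative_mixture_zero_residual(self, rng):
        H = rng.random((3, 200))
        W = rng.random((20, 3))
        data = W @ H
        out = parc.evaluate_cluster_count(data, [parc.CentroidSet(H)])
        assert out["residual"][0] == pytest.approx(0.0, abs=1e-12)

    def test_residual_nonincreasing_and_matches_oracle(self, rng):
        H = rng.random((4, 150))
        data = rng.random((15, 4)) @ H + 0.05 * rng.normal(size=(15, 150))
        nested = [parc.CentroidSet(H[:k]) for k in (1, 2, 3, 4)]
        out = parc.evaluate_cluster_count(data, nested)
        assert all(a >= b - 1e-9 for a, b in zip(out["residual"], out["residual"][1:]))
        # per-pixel NNLS oracle at k=2
        oracle = sum(scipy_nnls(H[:2].T, row)[1] ** 2 for row in data)
        assert out["residual"][1] == pytest.approx(oracle, rel=1e-9)

    def test_pca_bound_dominates_nnls(self, rng):
        H = rng.random((3, 100))
        data = rng.random((12, 3)) @ H + 0.1 * rng.normal(size=(12, 100))
        out = parc.evaluate_cluster_count(data, [parc.CentroidSet(H)])
        assert out["pca_explained_variance"][0] >= out["explained_variance"][0] - 1e-9

    def test_residual_near_asymptote_at_true_count(self, active_session):
        # elbow detectability: at the true parcel count (16) the NNLS residual
        # is within 5% of its large-N asymptote on pixel-level data
        raw, truth = active_session
        in_parcel = truth.parcel_labels.ravel() > 0
        data = truth.true_F[in_parcel][:, ::6][:, :1500]
        sets = []
        for i, k in enumerate((4, 8, 16, 24)):
            _, cents = parc.cluster_hemisphere(data, k, replicates=3, seed=i)
            sets.append(cents)
        out = parc.evaluate_cluster_count(data, sets)
        resid = dict(zip(out["n"], out["residual"]))
        asymptote = min(out["residual"])
        total = np.sum((data - data.mean(axis=1, keepdims=True)) ** 2)
        assert (resid[16] - asymptote) / total <= 0.05

    def test_degenerate_centroid_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate|constant"):
            parc.evaluate_cluster_count(rng.random((5, 50)),
                                        [parc.CentroidSet(np.ones((2, 50)))])


def _map_from_labels(labels):
    n = len(set(labels.ravel()) - {0})
    half = n // 2
    return parc.ParcellationMap(labels=labels, n_rois=n,
                                pairs=[(i + 1, i + 1 + half) for i in range(half)])


class TestConsensusModeMap:
    def _base_map(self):
        labels = np.array([[1, 1, 2, 3, 3, 4],
                           [1, 1, 2, 3, 3, 4]])
        return _map_from_labels(labels)

    def test_identical_maps_unchanged(self):
        m = self._base_map()
        out = parc.consensus_mode_map([m, m, m])
        assert np.array_equal(out.labels, m.labels)

    def test_majority_wins(self):
        a = self._base_map()
        b_labels = a.labels.copy()
        b_labels[0, 0] = 2  # one disagreeing pixel
        b = _map_from_labels(b_labels)
        out = parc.consensus_mode_map([a, a, b])
        assert np.array_equal(out.labels, a.labels)

    def test_mode_matches_counting_oracle_after_relabeling(self, rng):
        a = self._base_map()
        # c uses permuted label ids for the same partition: canonical
        # relabeling must undo the permutation, so the consensus equals a
        perm = {1: 3, 3: 1, 2: 4, 4: 2}
        c = _map_from_labels(np.vectorize(perm.get)(a.labels))
        out = parc.consensus_mode_map([a, a, c])
        assert np.array_equal(out.labels, a.labels)

    def test_mismatched_roi_counts_rejected(self):
        a = self._base_map()
        small = _map_from_labels(np.array([[1, 1, 1, 2, 2, 2],
                                           [1, 1, 1, 2, 2, 2]]))
        with pytest.raises(ValueError, match="n_rois"):
            parc.consensus_mode_map([a, a, small])


class TestGroupSubregions:
    def _block_corr_map(self, n_per_group, groups_per_hemi):
        n_half = n_per_group * groups_per_hemi
        n = 2 * n_half
        m = np.full((n, n), 0.05)
        for g in range(2 * groups_per_hemi):
            sl = slice(g * n_per_group, (g + 1) * n_per_group)
            m[sl, sl] = 0.9
        np.fill_diagonal(m, 1.0)
        return m

    def _pmap(self, n_half):
        labels = np.arange(1, 2 * n_half + 1).reshape(2, n_half, order="F")
        # build a simple map whose roi_order is 1..2n
        return parc.ParcellationMap(
            labels=labels, n_rois=2 * n_half,
            pairs=[(i + 1, i + 1 + n_half) for i in range(n_half)])

    def test_block_structure_recovered(self):
        m = self._block_corr_map(n_per_group=3, groups_per_hemi=2)
        pmap = self._pmap(6)
        grouping, reduced = parc.group_subregions(m, pmap, per_hemisphere_groups=2, seed=0)
        assert len(set(grouping.values())) == 4
        order = pmap.roi_order()
        for g_block in range(4):
            rois = order[g_block * 3:(g_block + 1) * 3]
            assert len({grouping[r] for r in rois}) == 1

    def test_partition_and_reduced_rows(self):
        m = self._block_corr_map(3, 2)
        pmap = self._pmap(6)
        grouping, reduced = parc.group_subregions(m, pmap, per_hemisphere_groups=2, seed=0)
        assert sorted(grouping.keys()) == pmap.roi_order()
        assert reduced.shape == (4, 12)
        order = pmap.roi_order()
        for gi in range(4):
            members = [order.index(r) for r, g in grouping.items() if g == gi]
            assert np.allclose(reduced[gi], m[members].mean(axis=0), atol=1e-12)

    def test_too_few_rois_rejected(self):
        pmap = self._pmap(3)
        m = np.eye(6)
        with pytest.raises(ValueError, match="fewer ROIs"):
            parc.group_subregions(m, pmap, per_hemisphere_groups=6)
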