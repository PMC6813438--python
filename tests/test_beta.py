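import io as _io

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phyloturn import CommunityTable, PhyloTree
from phyloturn.beta import (
    DistanceMatrix,
    axis_regression,
    bray_curtis,
    depth_distance,
    mantel,
    pcoa,
    weighted_unifrac,
)
from conftest import random_instance


def naive_weighted_unifrac(table, tree, normalized=False):
    """Independent per-branch enumeration via the dendropy tree."""
    props = table.counts / table.counts.sum(axis=1, keepdims=True)
    col = {o: j for j, o in enumerate(table.otu_ids)}
    out = np.zeros((table.n_samples, table.n_samples))
    dtree = tree.dendropy_tree
    for a in range(table.n_samples):
        for b in range(table.n_samples):
            num = 0.0
            den = 0.0
            for node in dtree.postorder_node_iter():
                if node.edge.tail_node is None:
                    continue
                tips = [
                    str(lf.taxon.label) for lf in node.leaf_iter()
                ]
                pa = sum(props[a, col[t]] for t in tips if t in col)
                pb = sum(props[b, col[t]] for t in tips if t in col)
                num += node.edge.length * abs(pa - pb)
                den += node.edge.length * (pa + pb)
            out[a, b] = (num / den if den else 0.0) if normalized else num
    return out


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 0], [0, 0]]))

    def test_tsv_round_trip(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c"], squareform([1.0, 2.0, 3.0]))
        p = tmp_path / "dm.tsv"
        dm.to_tsv(p)
        back = DistanceMatrix.from_tsv(p)
        assert back.ids == dm.ids
        assert np.allclose(back.values, dm.values)


class TestBrayCurtis:
    def test_disjoint_is_one(self):
        t = CommunityTable(["a", "b"], ["x", "y"], np.array([[1, 0], [0, 1]]))
        assert bray_curtis(t).pair("a", "b") == 1.0

    def test_identical_is_zero(self):
        t = CommunityTable(["a", "b"], ["x", "y"], np.array([[2, 3], [2, 3]]))
        assert bray_curtis(t).pair("a", "b") == 0.0

    def test_hand_value(self):
        t = CommunityTable(["a", "b"], ["x", "y"], np.array([[2, 2], [1, 1]]))
        assert bray_curtis(t).pair("a", "b") == pytest.approx(2 / 6)

    def test_empty_sample_errors(self):
        t = CommunityTable(["a", "b"], ["x"], np.array([[0], [1]]))
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(t)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(5, 7))
            counts[:, 0] += 1
            t = CommunityTable([f"s{i}" for i in range(5)], [f"o{j}" for j in range(7)], counts)
            mine = bray_curtis(t).condensed()
            ref = pdist(counts.astype(float), metric="braycurtis")
            assert np.allclose(mine, ref, atol=1e-12)


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, three_tip_tree):
        t = CommunityTable(["a", "b"], ["A", "B", "C"], np.array([[1, 2, 3], [1, 2, 3]]))
        assert weighted_unifrac(t, three_tip_tree).pair("a", "b") == 0.0

    def test_star_tree_two_tips(self):
        tree = PhyloTree.from_newick("(X:1,Y:1);")
        t = CommunityTable(["a", "b"], ["X", "Y"], np.array([[5, 0], [0, 7]]))
        assert weighted_unifrac(t, tree).pair("a", "b") == pytest.approx(2.0)
        assert weighted_unifrac(t, tree, normalized=True).pair("a", "b") == pytest.approx(1.0)

    def test_star_tree_equals_l1(self):
        # on a star tree with unit branches, raw weighted UniFrac is the L1
        # distance of relative abundance vectors
        tree = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 20, size=(3, 4))
        t = CommunityTable(["a", "b", "c"], ["A", "B", "C", "D"], counts)
        wu = weighted_unifrac(t, tree)
        props = counts / counts.sum(axis=1, keepdims=True)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            l1 = np.abs(props[i] - props[j]).sum()
            assert wu.values[i, j] == pytest.approx(l1, abs=1e-12)

    def test_missing_otu_errors(self, three_tip_tree):
        t = CommunityTable(["a"], ["A", "ZZZ"], np.array([[1, 1]]))
        with pytest.raises(KeyError, match="ZZZ"):
            weighted_unifrac(t, three_tip_tree)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_naive_enumeration(self, normalized):
        rng = np.random.default_rng(7)
        for _ in range(5):
            tree, table = random_instance(rng, max_samples=5, max_taxa=8)
            mine = weighted_unifrac(table, tree, normalized=normalized).values
            ref = naive_weighted_unifrac(table, tree, normalized=normalized)
            assert np.allclose(mine, ref, atol=1e-12)

    def test_matches_scikit_bio(self):
        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(11)
        for norm in (False, True):
            tree, table = random_instance(rng, max_samples=5, max_taxa=10)
            sk_tree = TreeNode.read(_io.StringIO(tree.as_newick()))
            ref = beta_diversity(
                "weighted_unifrac",
                table.counts,
                ids=table.sample_ids,
                taxa=table.otu_ids,
                tree=sk_tree,
                normalized=norm,
            ).data
            mine = weighted_unifrac(table, tree, normalized=norm).values
            assert np.allclose(mine, ref, atol=1e-10)


class TestPCoA:
    def test_zero_distances_zero_coordinates(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0

    def test_collinear_points(self):
        dm = DistanceMatrix(["a", "b", "c"], squareform([1.0, 2.0, 1.0]))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 1
        ax = res.coordinates[:, 0]
        assert np.allclose(sorted(ax), [-1, 0, 1], atol=1e-10)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        rec = squareform(pdist(res.coordinates[:, :2]))
        assert np.allclose(rec, d, atol=1e-8)
        # Euclidean input: no meaningfully negative eigenvalue
        assert res.eigenvalues.min() > -1e-10

    def test_matches_scikit_bio_eigenvalues(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(7)]
        mine = pcoa(DistanceMatrix(ids, d))
        ref = sk_pcoa(SkDM(d, ids=ids))
        k = 3
        assert np.allclose(mine.eigenvalues[:k], ref.eigvals.values[:k], atol=1e-8)
        assert np.allclose(
            np.abs(mine.coordinates[:, :k]), np.abs(ref.samples.values[:, :k]), atol=1e-6
        )

    def test_proportion_explained_sums_to_one_for_euclidean(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d))
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_signs(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(5)], d)
        a, b = pcoa(dm), pcoa(dm)
        assert np.array_equal(a.coordinates, b.coordinates)


def brute_force_mantel(m1, m2):
    """Exhaustive Mantel p over all relabelings of the second matrix."""
    import itertools

    n = m1.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

    r_obs = corr(m1[iu], m2[iu])
    count = 0
    perms = list(itertools.permutations(range(n)))
    for p in perms:
        p = np.asarray(p)
        if corr(m1[iu], m2[np.ix_(p, p)][iu]) >= r_obs:
            count += 1
    return r_obs, count / len(perms)


class TestMantel:
    def _random_dm(self, rng, n):
        v = squareform(rng.random(n * (n - 1) // 2))
        return DistanceMatrix([f"s{i}" for i in range(n)], v)

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        dm = self._random_dm(rng, 5)
        res = mantel(dm, dm, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_six_samples_exhaustive_720(self):
        rng = np.random.default_rng(1)
        res = mantel(self._random_dm(rng, 6), self._random_dm(rng, 6), n_permutations=999, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 720

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = self._random_dm(rng, 4), self._random_dm(rng, 4)
            res = mantel(a, b, n_permutations=24, seed=0)
            r_ref, p_ref = brute_force_mantel(a.values, b.values)
            assert res.exhaustive and res.n_permutations == 24
            assert res.r == pytest.approx(r_ref, abs=1e-12)
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_invariant_to_joint_reordering(self):
        rng = np.random.default_rng(3)
        a, b = self._random_dm(rng, 5), self._random_dm(rng, 5)
        ids = list(a.ids)
        rng.shuffle(ids)
        res1 = mantel(a, b, n_permutations=24, seed=0)
        res2 = mantel(a.reorder(ids), b.reorder(ids), n_permutations=24, seed=0)
        assert res1.r == pytest.approx(res2.r, abs=1e-12)

    def test_id_mismatch_errors(self):
        rng = np.random.default_rng(4)
        a = self._random_dm(rng, 4)
        b = DistanceMatrix(["x1", "x2", "x3", "x4"], a.values)
        with pytest.raises(ValueError, match="ids"):
            mantel(a, b)

    def test_monte_carlo_p_formula(self):
        # with n = 7, 50 permutations -> Monte-Carlo branch; p in (0, 1]
        rng = np.random.default_rng(5)
        res = mantel(self._random_dm(rng, 7), self._random_dm(rng, 7), n_permutations=50, seed=9)
        assert not res.exhaustive
        assert 0 < res.p <= 1
        assert res.p * 51 == pytest.approx(round(res.p * 51))


class TestDepthDecay:
    def test_depth_difference_values(self, metadata6):
        dd = depth_distance(metadata6)
        assert dd.pair("ST76", "ST32") == pytest.approx(2860.0)
        assert dd.pair("ST11", "ST11") == 0.0

    def test_missing_sample_errors(self, metadata6):
        with pytest.raises(KeyError):
            depth_distance(metadata6, sample_ids=["ST76", "nope"])

    def test_regression_perfect_fit(self, metadata6):
        from phyloturn.beta import OrdinationResult

        depth = metadata6["depth_m"].to_numpy()
        coords = (2.0 * depth - 5.0)[:, None]
        ordn = OrdinationResult(
            ids=list(metadata6.index),
            eigenvalues=np.array([1.0]),
            coordinates=coords,
            proportion_explained=np.array([1.0]),
        )
        r2, p = axis_regression(ordn, metadata6, axis=0)
        assert r2 == pytest.approx(1.0)

    def test_regression_equals_squared_pearson(self, metadata6):
        from scipy.stats import pearsonr

        from phyloturn.beta import OrdinationResult

        rng = np.random.default_rng(6)
        coords = rng.normal(size=(6, 1))
        ordn = OrdinationResult(
            ids=list(metadata6.index),
            eigenvalues=np.array([1.0]),
            coordinates=coords,
            proportion_explained=np.array([1.0]),
        )
        r2, p = axis_regression(ordn, metadata6, axis=0)
        rho, p_ref = pearsonr(metadata6["depth_m"], coords[:, 0])
        assert r2 == pytest.approx(rho**2, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)
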