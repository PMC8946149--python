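import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from ocstrat import clustering as cl


def blob_matrix(rng, centers, n_per=10, sd=0.1, p=12):
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(n_per, p)))
        labels += [i] * n_per
    values = np.vstack(rows)
    names = [f"f{j}" for j in range(p)]
    m = cl.FeatureMatrix(
        [f"s{i}" for i in range(len(values))],
        names,
        values,
        {n: f"singleton:{n}" for n in names},
    )
    return m, np.array(labels)


def two_blob(rng):
    c1 = rng.normal(0, 1, 12)
    return blob_matrix(rng, [c1, -c1])


class TestBuildMatrix:
    def test_full_blocks_build(self, cohort_features):
        sub = dict(list(cohort_features.items())[:3])
        m = cl.build_feature_matrix(sub)
        assert m.values.shape == (3, 24)
        assert np.all(np.isfinite(m.values))

    def test_missing_block_names_sample(self, cohort_features):
        sub = dict(list(cohort_features.items())[:2])
        sid = list(sub)[0]
        sub[sid] = (sub[sid][0], None)
        with pytest.raises(ValueError, match=sid):
            cl.build_feature_matrix(sub)

    def test_column_count_invariant(self, cohort_features):
        m_all = cl.build_feature_matrix(cohort_features)
        m_two = cl.build_feature_matrix(dict(list(cohort_features.items())[:2]))
        assert m_all.feature_names == m_two.feature_names


class TestNormalization:
    def test_constant_column_maps_to_zero(self, rng):
        m, _ = two_blob(rng)
        m.values[:, 0] = 7.0
        norm = cl.normalize_grouped(m)
        assert np.all(norm.values[:, 0] == 0.0)

    def test_singleton_zscore(self, rng):
        m, _ = two_blob(rng)
        norm = cl.normalize_grouped(m)
        assert norm.values[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert norm.values[:, 1].std() == pytest.approx(1.0)

    def test_pooled_scaling_preserves_block_contrast(self, rng):
        # two grouped features, one uniformly 10x the other: after pooled
        # normalization the larger one must remain larger sample-by-sample
        base = rng.uniform(1, 2, size=20)
        values = np.column_stack([base, 10 * base])
        m = cl.FeatureMatrix(
            [f"s{i}" for i in range(20)],
            ["a", "b"],
            values,
            {"a": "G", "b": "G"},
        )
        norm = cl.normalize_grouped(m)
        assert np.all(norm.values[:, 1] > norm.values[:, 0])


class TestDistance:
    def test_identical_rows_zero(self, rng):
        row = rng.normal(size=10)
        m = cl.FeatureMatrix(
            ["a", "b"],
            [f"f{i}" for i in range(10)],
            np.vstack([row, row]),
            {f"f{i}": f"singleton:{i}" for i in range(10)},
        )
        assert cl.sample_distance(m)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_two(self, rng):
        row = rng.normal(size=10)
        m = cl.FeatureMatrix(
            ["a", "b"],
            [f"f{i}" for i in range(10)],
            np.vstack([row, -row + 2 * row.mean()]),
            {f"f{i}": f"singleton:{i}" for i in range(10)},
        )
        assert cl.sample_distance(m)[0, 1] == pytest.approx(2.0)

    def test_symmetry_and_bounds(self, rng):
        m, _ = two_blob(rng)
        d = cl.sample_distance(m)
        assert np.allclose(d, d.T, atol=1e-12)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_zero_variance_row_error_names_sample(self, rng):
        m, _ = two_blob(rng)
        m.values[3, :] = 5.0
        with pytest.raises(ValueError, match="s3"):
            cl.sample_distance(m)


class TestWardD:
    def test_two_blobs_perfect_split(self, rng):
        m, labels = two_blob(rng)
        res = cl.ward_cluster(cl.sample_distance(m), 2)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_k_equals_n_singletons(self, rng):
        m, _ = two_blob(rng)
        res = cl.ward_cluster(cl.sample_distance(m), 20)
        assert len(set(res.labels)) == 20

    def test_k_above_n_raises(self, rng):
        m, _ = two_blob(rng)
        with pytest.raises(ValueError):
            cl.ward_cluster(cl.sample_distance(m), 21)

    def test_matches_scipy_sqrt_equivalence_oracle(self, rng):
        """ward.D on d is scipy 'ward' run on sqrt(d), heights squared.

        scipy's ward implementation applies the Lance-Williams recursion
        to squared input distances and reports the square root, so feeding
        it sqrt(d) reproduces the classic ward.D merge heights on d.
        """
        d = cl.sample_distance(two_blob(rng)[0])
        Z_mine = cl.ward_linkage(d)
        Z_scipy = linkage(squareform(np.sqrt(d), checks=False), method="ward")
        assert np.allclose(np.sort(Z_mine[:, 2]), np.sort(Z_scipy[:, 2] ** 2), atol=1e-8)
        # cluster sizes along the agglomeration agree
        assert np.array_equal(np.sort(Z_mine[:, 3]), np.sort(Z_scipy[:, 3]))

    def test_row_permutation_invariance(self, rng):
        m, _ = two_blob(rng)
        d = cl.sample_distance(m)
        perm = rng.permutation(d.shape[0])
        labels_a = cl.ward_cluster(d, 4).labels
        labels_b = cl.ward_cluster(d[np.ix_(perm, perm)], 4).labels
        assert adjusted_rand_score(labels_a[perm], labels_b) == 1.0

    def test_archetype_recovery_on_default_cohort(self, default_cohort, cohort_features):
        m = cl.build_feature_matrix(cohort_features)
        res = cl.ward_cluster(cl.sample_distance(cl.normalize_grouped(m)), 7)
        truth = [s.truth["archetype"] for s in default_cohort.samples]
        assert adjusted_rand_score(truth, res.labels) >= 0.90


class TestBootstrap:
    def test_separated_blobs_fully_stable(self, rng):
        m, _ = two_blob(rng)
        m.values *= 100  # effectively infinite separation
        stab = cl.bootstrap_stability(m, 2, B=100, seed=5)
        assert all(p >= 0.99 for p in stab.values())

    def test_pure_noise_unstable(self, rng):
        values = rng.normal(size=(40, 15))
        names = [f"f{i}" for i in range(15)]
        m = cl.FeatureMatrix(
            [f"s{i}" for i in range(40)],
            names,
            values,
            {n: f"singleton:{n}" for n in names},
        )
        stab = cl.bootstrap_stability(m, 5, B=200, seed=5)
        assert np.mean(list(stab.values())) < 0.95

    def test_seed_reproducibility(self, rng):
        m, _ = two_blob(rng)
        a = cl.bootstrap_stability(m, 2, B=100, seed=42)
        b = cl.bootstrap_stability(m, 2, B=100, seed=42)
        assert a == b

    def test_b_below_100_rejected(self, rng):
        m, _ = two_blob(rng)
        with pytest.raises(ValueError):
            cl.bootstrap_stability(m, 2, B=50)


class TestPca:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 8))
        names = [f"f{i}" for i in range(8)]
        m = cl.FeatureMatrix(
            [f"s{i}" for i in range(30)],
            names,
            u @ v,
            {n: f"singleton:{n}" for n in names},
        )
        cum = cl.pca_cumvar(m)
        assert cum[0] >= 1 - 1e-9

    def test_nondecreasing_and_ends_at_one(self, rng):
        m, _ = two_blob(rng)
        cum = cl.pca_cumvar(m)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_spreads_variance(self, rng):
        values = rng.normal(size=(200, 10))
        names = [f"f{i}" for i in range(10)]
        m = cl.FeatureMatrix(
            [f"s{i}" for i in range(200)],
            names,
            values,
            {n: f"singleton:{n}" for n in names},
        )
        cum = cl.pca_cumvar(m)
        increments = np.diff(np.concatenate([[0], cum]))
        assert increments.max() < 3 * increments.min()


def test_newick_export_roundtrips_leaf_set(rng):
    import dendropy

    m, _ = two_blob(rng)
    Z = cl.ward_linkage(cl.sample_distance(m))
    nwk = cl.to_newick(Z, m.sample_ids)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert leaves == set(m.sample_ids)


@given(st.integers(0, 2**32 - 1))
def test_cut_tree_partitions_all_samples(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 12))
    x = rng.normal(size=(n, 5))
    d = 1 - np.corrcoef(x)
    np.fill_diagonal(d, 0)
    Z = cl.ward_linkage(np.clip((d + d.T) / 2, 0, 2))
    for k in range(1, n + 1):
        labels = cl.cut_tree(Z, k)
        assert sorted(set(labels)) == list(range(1, k + 1))
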