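"""SPADE stages: densities, downsampling, pooling, clustering, MST, upsampling."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from scipy.stats import wilcoxon
from sklearn.metrics import adjusted_rand_score

from cytoemd import (
    ClusterAssignment,
    SpadeTree,
    agglomerative_cluster,
    build_tree,
    density_dependent_downsample,
    local_densities,
    node_frequencies,
    pool_and_cap,
    select_target_density,
    upsample,
)
from cytoemd.errors import (
    DegenerateInputError,
    InfeasibleRetentionError,
    ParameterError,
    SchemaError,
)
from cytoemd.spade import SpadeTreeModel, expected_retention, keep_probabilities

from .conftest import kruskal_total, make_cells


class TestLocalDensities:
    def test_coincident_cells_count_each_other(self):
        cm = make_cells(np.zeros((2, 2)))
        est = local_densities(cm, seed=0)
        np.testing.assert_array_equal(est.local_density, [2, 2])

    def test_sparse_grid_radius_below_spacing(self):
        # grid spacing 1; radius_factor 0.5 puts the radius below it
        cm = make_cells(np.arange(10.0))
        est = local_densities(cm, radius_factor=0.5, seed=0)
        np.testing.assert_array_equal(est.local_density, np.ones(10))

    def test_matches_brute_force(self, normal_sample):
        sub = make_cells(normal_sample.values[:500], channels=normal_sample.channels)
        est = local_densities(sub, seed=3)
        D = np.abs(sub.values[:, None, :] - sub.values[None, :, :]).sum(axis=-1)
        brute = (D <= est.radius).sum(axis=1)
        np.testing.assert_array_equal(est.local_density, brute)

    def test_single_cell_degenerate(self):
        with pytest.raises(DegenerateInputError):
            local_densities(make_cells([[1.0, 2.0]]), seed=0)

    def test_outlier_density_is_first_percentile(self, normal_sample):
        est = local_densities(normal_sample, seed=0)
        assert est.outlier_density == np.percentile(est.local_density, 1.0)
        assert est.local_density.min() >= 1


class TestSelectTargetDensity:
    def _est(self, ld, od=0.0):
        from cytoemd.spade import DensityEstimate

        return DensityEstimate(
            local_density=np.asarray(ld, dtype=int), radius=1.0, outlier_density=od
        )

    def test_uniform_densities_closed_form(self):
        # all LD equal: expected retention n*min(1, TD/LD) -> TD = LD*R/n
        est = select_target_density(self._est([10] * 100), retain_count=40)
        assert est.target_density == pytest.approx(4.0)
        assert expected_retention(est, est.target_density) == pytest.approx(40.0)

    def test_boundary_keep_everything(self):
        est = select_target_density(self._est([3, 7, 12, 9]), retain_count=4)
        assert est.target_density >= 12

    def test_mixed_densities_exact_expected_retention(self, rng):
        ld = rng.integers(1, 500, size=3000)
        est = select_target_density(self._est(ld, od=np.percentile(ld, 1)), 1000)
        assert expected_retention(est, est.target_density) == pytest.approx(
            1000.0, abs=1.0
        )

    def test_infeasible_retention(self):
        with pytest.raises(InfeasibleRetentionError):
            select_target_density(self._est([5, 5, 5]), retain_count=4)


class TestDownsample:
    def test_exact_count_every_seed(self, normal_sample):
        est = select_target_density(local_densities(normal_sample, seed=0), 800)
        for seed in range(5):
            out = density_dependent_downsample(normal_sample, est, 800, seed=seed)
            assert out.n_cells == 800

    def test_outliers_never_retained(self, rng):
        # regular grid (uniform local density) plus one distant stray cell;
        # the stray's density falls below the 1st percentile and must vanish
        g = np.arange(20.0)
        dense = np.array([[x, y] for x in g for y in g])
        stray = np.array([[500.0, 500.0]])
        cm = make_cells(np.vstack([dense, stray]))
        est = local_densities(cm, seed=0)
        assert est.local_density[-1] < est.outlier_density
        est = select_target_density(est, 200)
        for seed in range(10):
            out = density_dependent_downsample(cm, est, 200, seed=seed)
            assert not (np.abs(out.values - stray).sum(axis=1) < 1e-9).any()

    def test_density_strata_flattened(self):
        # two strata, LD 10 vs 100; retention ratio ~ 10:1 beyond TD
        from cytoemd.spade import DensityEstimate

        ld = np.array([10] * 2000 + [100] * 2000)
        values = np.arange(4000.0)
        cm = make_cells(values)
        est = select_target_density(
            DensityEstimate(local_density=ld, radius=1.0, outlier_density=1.0), 400
        )
        probs = keep_probabilities(est)
        hits = np.zeros(2, dtype=float)
        n_rep = 60
        for seed in range(n_rep):
            out = density_dependent_downsample(cm, est, 400, seed=seed)
            kept = out.column("FSC").astype(int)
            hits[0] += (kept < 2000).sum()
            hits[1] += (kept >= 2000).sum()
        emp = hits / (n_rep * 2000)
        expect = np.array([probs[0], probs[-1]])
        se = np.sqrt(expect * (1 - expect) / (n_rep * 2000))
        assert np.all(np.abs(emp - expect) <= 3 * se)


class TestPoolAndCap:
    def test_under_cap_unchanged(self, normal_sample):
        half = make_cells(
            normal_sample.values[:100], channels=normal_sample.channels, sample_id="b"
        )
        pooled = pool_and_cap([normal_sample, half], cap=10**6, seed=0)
        assert pooled.n_cells == normal_sample.n_cells + 100
        np.testing.assert_array_equal(pooled.values[: normal_sample.n_cells], normal_sample.values)

    def test_over_cap_exact(self, rng):
        subsets = [
            make_cells(rng.normal(size=(600, 2)), sample_id=f"s{i}") for i in range(4)
        ]
        pooled = pool_and_cap(subsets, cap=1000, seed=1)
        assert pooled.n_cells == 1000

    def test_representation_proportional(self, rng):
        sizes = {"a": 3000, "b": 1000}
        subsets = [
            make_cells(rng.normal(size=(n, 2)), sample_id=s) for s, n in sizes.items()
        ]
        counts = {"a": 0, "b": 0}
        n_rep = 30
        for seed in range(n_rep):
            pooled = pool_and_cap(subsets, cap=1000, seed=seed)
            for s in counts:
                counts[s] += (pooled.source_ids == s).sum()
        # inclusion probability is cap/total for every cell
        for s, n in sizes.items():
            expect = 1000 * n / 4000
            se = np.sqrt(1000 * (n / 4000) * (1 - n / 4000) / n_rep)
            assert abs(counts[s] / n_rep - expect) <= 4 * se

    def test_channel_mismatch(self, normal_sample):
        other = make_cells(np.zeros((5, 2)), channels=("FSC", "SSC"))
        with pytest.raises(SchemaError):
            pool_and_cap([normal_sample, other])


class TestAgglomerativeCluster:
    def test_k_equals_n(self, rng):
        X = rng.normal(size=(20, 3))
        a = agglomerative_cluster(X, k=20)
        assert len(set(a.labels.tolist())) == 20

    def test_k_one(self, rng):
        a = agglomerative_cluster(rng.normal(size=(50, 3)), k=1)
        assert set(a.labels.tolist()) == {0}

    def test_k_out_of_range(self, rng):
        with pytest.raises(ParameterError):
            agglomerative_cluster(rng.normal(size=(5, 2)), k=6)

    def test_two_blobs_recovered(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.2, size=(150, 3)), rng.normal(5, 0.2, size=(150, 3))]
        )
        truth = np.repeat([0, 1], 150)
        a = agglomerative_cluster(X, k=2)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_sizes_more_balanced_than_single_linkage(self, rng):
        """The round-based scheme should not chain the way single linkage does."""

        def cv(sizes):
            return sizes.std() / sizes.mean()

        ours, theirs = [], []
        k = 15
        for _ in range(20):
            centers = rng.normal(size=(5, 3)) * 4
            X = np.vstack(
                [c + rng.normal(size=(80, 3)) * 0.5 for c in centers]
            )
            a = agglomerative_cluster(X, k=k)
            ours.append(cv(np.bincount(a.labels, minlength=k).astype(float)))
            sl = fcluster(linkage(X, method="single"), t=k, criterion="maxclust")
            theirs.append(cv(np.bincount(sl, minlength=k + 1)[1:].astype(float)))
        ours, theirs = np.array(ours), np.array(theirs)
        assert ours.mean() < theirs.mean()
        assert wilcoxon(ours, theirs, alternative="less").pvalue < 0.01

    def test_exact_cluster_count_and_nonempty(self, rng):
        X = rng.normal(size=(700, 4))
        a = agglomerative_cluster(X, k=37)
        counts = np.bincount(a.labels, minlength=37)
        assert (counts > 0).all() and counts.sum() == 700


class TestBuildTree:
    def test_two_nodes_single_edge(self):
        a = ClusterAssignment(
            reference_cells=np.array([[0.0, 0.0], [2.0, 1.0]]),
            labels=np.array([0, 1]),
            n_clusters=2,
        )
        t = build_tree(a)
        assert t.edges.tolist() == [[0, 1]]
        assert t.edge_lengths[0] == pytest.approx(3.0)

    def test_collinear_forced_path(self):
        a = ClusterAssignment(
            reference_cells=np.array([[0.0], [1.0], [5.0]]),
            labels=np.array([0, 1, 2]),
            n_clusters=3,
        )
        t = build_tree(a)
        assert sorted(map(tuple, t.edges.tolist())) == [(0, 1), (1, 2)]
        assert t.total_length() == pytest.approx(5.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_total_length_matches_kruskal(self, trial):
        rng = np.random.default_rng(500 + trial)
        K = int(rng.integers(2, 30))
        med = rng.normal(size=(K, int(rng.integers(2, 8))))
        a = ClusterAssignment(
            reference_cells=med, labels=np.arange(K), n_clusters=K
        )
        t = build_tree(a)
        D = cdist(med, med, metric="cityblock")
        assert t.total_length() == pytest.approx(kruskal_total(D), abs=1e-9)
        assert t.edges.shape == (K - 1, 1 + 1)

    def test_json_round_trip(self, rng):
        med = rng.normal(size=(6, 3))
        a = ClusterAssignment(reference_cells=med, labels=np.arange(6), n_clusters=6)
        t = build_tree(a, channels=["FSC", "SSC", "CD45"])
        back = SpadeTree.from_json(t.to_json())
        np.testing.assert_array_equal(back.edges, t.edges)
        np.testing.assert_allclose(back.node_medians, t.node_medians)
        assert back.channels == t.channels


class TestUpsample:
    def _assignment(self, rng, n=200, k=8):
        ref = rng.normal(size=(n, 3))
        return agglomerative_cluster(ref, k=k)

    def test_reference_cell_maps_to_own_cluster(self, rng):
        a = self._assignment(rng)
        labels = upsample(a.reference_cells, a)
        np.testing.assert_array_equal(labels, a.labels)

    def test_tie_breaks_to_lowest_index(self):
        ref = np.array([[0.0, 0.0], [2.0, 0.0]])
        a = ClusterAssignment(reference_cells=ref, labels=np.array([0, 1]), n_clusters=2)
        labels = upsample(np.array([[1.0, 0.0]]), a)  # equidistant
        assert labels[0] == 0

    def test_matches_brute_force(self, rng):
        a = self._assignment(rng, n=400, k=12)
        query = rng.normal(size=(1000, 3))
        labels = upsample(query, a)
        D = cdist(query, a.reference_cells, metric="cityblock")
        brute = a.labels[np.argmin(D, axis=1)]
        np.testing.assert_array_equal(labels, brute)

    def test_channel_mismatch(self, rng):
        a = self._assignment(rng)
        with pytest.raises(SchemaError):
            upsample(rng.normal(size=(5, 7)), a)


class TestNodeFrequencies:
    def test_indicator(self):
        d = node_frequencies(np.zeros(7, dtype=int), 3, "s", 1)
        np.testing.assert_allclose(d.freq, [1.0, 0.0, 0.0])

    def test_half_half(self):
        d = node_frequencies(np.array([0, 0, 1, 1]), 2)
        np.testing.assert_allclose(d.freq, [0.5, 0.5])

    def test_counting_oracle(self, rng):
        labels = rng.integers(0, 9, size=500)
        d = node_frequencies(labels, 9)
        np.testing.assert_allclose(d.freq * 500, np.bincount(labels, minlength=9))
        assert d.freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            node_frequencies(np.empty(0, dtype=int), 3)


class TestSpadeTreeModel:
    def test_fit_transform_shapes(self, small_template):
        from cytoemd import normalize_fsc, simulate_sample

        samples = [
            normalize_fsc(simulate_sample(small_template, lab, 700, seed=s, sample_id=f"s{s}")[0])
            for s, lab in enumerate(["normal", "normal", "AML"])
        ]
        model = SpadeTreeModel(
            retain_count=300, pool_cap=800, n_clusters=12, random_state=0
        )
        F = model.fit(samples).transform(samples)
        assert F.shape == (3, 12)
        np.testing.assert_allclose(F.sum(axis=1), 1.0, atol=1e-12)
        assert model.tree_.n_nodes == 12
        assert model.pooled_.n_cells == 800
        # sklearn parameter plumbing
        assert model.get_params()["n_clusters"] == 12
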