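import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from nicheomics import clustering
from nicheomics.simulate import SimulationConfig, simulate_profiles
from oracles import density_stats_oracle


def _profiles(points, genes=None, cols=None):
    points = np.asarray(points, dtype=float)
    genes = genes or [f"g{i}" for i in range(points.shape[0])]
    cols = cols or [f"d{j}" for j in range(points.shape[1])]
    return pd.DataFrame(points, index=genes, columns=cols)


@pytest.fixture
def two_groups(rng):
    """Two tight, well-separated 2-D blobs of 50 points each."""
    a = rng.normal([0, 0], 0.05, size=(50, 2))
    b = rng.normal([10, 10], 0.05, size=(50, 2))
    labels = np.array([0] * 50 + [1] * 50)
    return _profiles(np.vstack([a, b])), labels


class TestDensityStats:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(40, 3))
            prof = _profiles(pts)
            stats = clustering.density_stats(prof, d_c=0.8)
            rho_o, delta_o, nearest_o = density_stats_oracle(pts, 0.8)
            assert np.allclose(stats["rho"].values, rho_o)
            assert np.allclose(stats["delta"].values, delta_o)
            genes = list(prof.index)
            for i, nh in enumerate(nearest_o):
                got = stats["nearest_higher"].iloc[i]
                assert got == (genes[nh] if nh is not None else None)

    def test_two_groups_exactly_two_gamma_outliers(self, two_groups):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        gamma = np.sort(stats["gamma"].values)[::-1]
        assert gamma[1] > 10 * gamma[2]

    def test_densest_gene_delta_is_max_distance(self, rng):
        prof = _profiles(rng.normal(size=(30, 4)))
        stats = clustering.density_stats(prof, d_c=1.0)
        top = stats["rho"].idxmax()
        from scipy.spatial.distance import cdist

        d = cdist(prof.loc[[top]], prof)[0]
        assert stats.loc[top, "delta"] == pytest.approx(d.max())

    def test_duplicated_point_deltas(self):
        pts = np.tile([[1.0, 2.0]], (5, 1))
        stats = clustering.density_stats(_profiles(pts), d_c=1.0)
        # one representative keeps delta = max distance (0); rest have delta 0
        assert np.allclose(stats["delta"].values, 0.0)

    def test_rho_permutation_invariant(self, rng):
        pts = rng.normal(size=(25, 3))
        prof = _profiles(pts)
        stats1 = clustering.density_stats(prof, d_c=0.7)
        perm = rng.permutation(25)
        prof2 = prof.iloc[perm]
        stats2 = clustering.density_stats(prof2, d_c=0.7)
        assert np.allclose(stats1["rho"].reindex(prof2.index).values, stats2["rho"].values)

    def test_auto_dc_targets_neighborhood_mass(self, rng):
        prof = _profiles(rng.normal(size=(300, 3)))
        stats = clustering.density_stats(prof, d_c="auto", target_mass=0.02)
        mean_mass = stats["rho"].mean()
        assert mean_mass == pytest.approx(0.02 * 300, rel=0.05)

    def test_rejects_bad_dc(self, rng):
        prof = _profiles(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            clustering.density_stats(prof, d_c=-1.0)


class TestAssignClusters:
    def test_two_groups_recovered_exactly(self, two_groups):
        prof, labels = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        assign = clustering.assign_clusters(stats, k=2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, assign["cluster"].values) == 1.0

    def test_k_equals_n_genes(self, rng):
        prof = _profiles(rng.normal(size=(8, 2)))
        stats = clustering.density_stats(prof, d_c=1.0)
        assign = clustering.assign_clusters(stats, k=8)
        assert assign["cluster"].nunique() == 8

    def test_assignment_order_independent(self, two_groups, rng):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        a1 = clustering.assign_clusters(stats, k=2)
        perm = rng.permutation(len(prof))
        prof2 = prof.iloc[perm]
        stats2 = clustering.density_stats(prof2, d_c=0.5)
        a2 = clustering.assign_clusters(stats2, k=2).reindex(a1.index)
        # same partition (cluster ids may swap)
        pairs = set(zip(a1["cluster"], a2["cluster"]))
        assert len(pairs) == 2

    def test_auto_k_finds_gap(self, two_groups):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        assert clustering.choose_k(stats) == 2

    def test_k_above_distinct_gamma_rejected(self):
        pts = np.tile([[0.0, 0.0]], (4, 1))
        stats = clustering.density_stats(_profiles(pts), d_c=1.0)
        with pytest.raises(ValueError, match="distinct gamma"):
            clustering.assign_clusters(stats, k=3)

    def test_centers_belong_to_own_cluster(self, two_groups):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        assign = clustering.assign_clusters(stats, k=2)
        centers = assign.loc[assign["is_center"]]
        assert centers["cluster"].nunique() == 2


class TestExcludeHalo:
    def test_fully_separated_clusters_no_halo(self, two_groups):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        assign = clustering.assign_clusters(stats, k=2)
        out = clustering.exclude_halo(assign, stats, prof, d_c=0.5)
        assert not out["is_halo"].any()

    def test_midpoint_point_flagged_halo(self, rng):
        a = rng.normal([0, 0], 0.05, size=(40, 2))
        b = rng.normal([4, 0], 0.05, size=(40, 2))
        lone = np.array([[2.0, 0.0]])
        prof = _profiles(np.vstack([a, b, lone]))
        stats = clustering.density_stats(prof, d_c=2.5)
        assign = clustering.assign_clusters(stats, k=2)
        out = clustering.exclude_halo(assign, stats, prof, d_c=2.5)
        assert out["is_halo"].iloc[-1]

    def test_idempotent(self, two_groups):
        prof, _ = two_groups
        stats = clustering.density_stats(prof, d_c=0.5)
        assign = clustering.assign_clusters(stats, k=2)
        once = clustering.exclude_halo(assign, stats, prof, d_c=0.5)
        twice = clustering.exclude_halo(once, stats, prof, d_c=0.5)
        assert once["is_halo"].equals(twice["is_halo"])

    def test_centers_never_halo(self, rng):
        prof = _profiles(rng.normal(size=(60, 2)))
        stats = clustering.density_stats(prof, d_c="auto")
        assign = clustering.assign_clusters(stats, k=3)
        out = clustering.exclude_halo(assign, stats, prof)
        assert not out.loc[out["is_center"], "is_halo"].any()


class TestCompactness:
    def test_identical_members_give_one(self):
        row = np.array([1.0, -1.0, 0.5, -0.5])
        prof = _profiles(np.tile(row, (5, 1)))
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": [True] + [False] * 4, "is_halo": False},
            index=prof.index,
        )
        summary, _ = clustering.compactness(assign, prof)
        assert summary["compactness"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_alternating_members_nan(self):
        v = np.array([1.0, -1.0, 1.0, -1.0])
        prof = _profiles(np.vstack([v, -v, v, -v]))
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": [True] + [False] * 3, "is_halo": False},
            index=prof.index,
        )
        summary, _ = clustering.compactness(assign, prof)
        assert np.isnan(summary["compactness"].iloc[0])

    def test_singleton_cluster_nan(self, rng):
        prof = _profiles(rng.normal(size=(3, 4)))
        assign = pd.DataFrame(
            {"cluster": [0, 1, 1], "is_center": [True, True, False], "is_halo": False},
            index=prof.index,
        )
        summary, _ = clustering.compactness(assign, prof)
        assert np.isnan(summary.loc[summary["cluster"] == 0, "compactness"].iloc[0])

    def test_simulated_archetype_clusters_compact(self):
        cfg = SimulationConfig(n_genes=400, n_clusters=4, noise_gene_fraction=0.0, seed=9)
        prof, truth = simulate_profiles(cfg, noise_sd=0.2)
        assign = pd.DataFrame(
            {
                "cluster": [truth.cluster_of_gene[g] for g in prof.index],
                "is_center": False,
                "is_halo": False,
            },
            index=prof.index,
        )
        summary, _ = clustering.compactness(assign, prof)
        assert (summary["compactness"] > 0.9).all()


class TestClusterConditionShift:
    @staticmethod
    def _de(features, lfc, padj):
        return pd.DataFrame({"feature": features, "log2FC": lfc, "padj": padj})

    def test_uniform_lfc(self):
        de_tables = {"T1": self._de(["a", "b"], [1.0, 1.0], [0.01, 0.01])}
        out = clustering.cluster_condition_shift({0: ["a", "b"]}, de_tables)
        assert out["mean_log2FC"].iloc[0] == pytest.approx(1.0)
        assert out["significant"].iloc[0]

    def test_symmetric_lfc_means_zero(self):
        de_tables = {"T1": self._de(["a", "b"], [1.0, -1.0], [0.5, 0.5])}
        out = clustering.cluster_condition_shift({0: ["a", "b"]}, de_tables)
        assert out["mean_log2FC"].iloc[0] == pytest.approx(0.0)
        assert not out["significant"].iloc[0]

    def test_matches_brute_force_mean(self, rng):
        feats = [f"g{i}" for i in range(30)]
        lfc = rng.normal(size=30)
        padj = rng.uniform(size=30)
        de_tables = {"T1": self._de(feats, lfc, padj)}
        members = feats[5:20]
        out = clustering.cluster_condition_shift({0: members}, de_tables)
        expected = float(np.mean([lfc[i] for i in range(5, 20)]))
        assert out["mean_log2FC"].iloc[0] == pytest.approx(expected)

    def test_empty_intersection_nan(self):
        de_tables = {"T1": self._de(["a"], [1.0], [0.1])}
        out = clustering.cluster_condition_shift({0: ["zzz"]}, de_tables)
        assert np.isnan(out["mean_log2FC"].iloc[0])


class TestAnnotateClusters:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        cluster_genes = [f"g{i}" for i in range(5)]
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": False, "is_halo": False}, index=cluster_genes
        )
        sets = {"S": set(cluster_genes)}
        out = clustering.annotate_clusters(assign, sets, universe)
        # P(all 5 draws hit the 5-gene set) = 1 / C(20, 5)
        expected = 1.0 / comb(20, 5)
        assert out["p"].iloc[0] == pytest.approx(expected)

    def test_empty_overlap_p_near_one(self):
        universe = {f"g{i}" for i in range(40)}
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": False, "is_halo": False},
            index=[f"g{i}" for i in range(3)],
        )
        sets = {"S": {f"g{i}" for i in range(30, 35)}}
        out = clustering.annotate_clusters(assign, sets, universe)
        assert out["p"].iloc[0] > 0.3

    def test_null_sets_uniform_p(self, rng):
        universe = {f"g{i}" for i in range(200)}
        members = [f"g{i}" for i in rng.choice(200, 40, replace=False)]
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": False, "is_halo": False}, index=members
        )
        sets = {
            f"S{j}": {f"g{i}" for i in rng.choice(200, 20, replace=False)}
            for j in range(200)
        }
        out = clustering.annotate_clusters(assign, sets, universe)
        # hypergeometric p under the null is stochastically >= uniform
        assert (out["p"] < 0.05).mean() < 0.1

    def test_disjoint_set_skipped_with_warning(self):
        universe = {"g1", "g2"}
        assign = pd.DataFrame(
            {"cluster": 0, "is_center": False, "is_halo": False}, index=["g1"]
        )
        with pytest.warns(UserWarning, match="disjoint"):
            out = clustering.annotate_clusters(assign, {"S": {"zz"}}, universe)
        assert out.empty
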