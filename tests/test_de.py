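import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicheomics import de
from nicheomics import normalization as nm
from oracles import bh_oracle, quasipoisson_score_oracle


def _nb_counts(rng, mu, alpha, n_samples):
    n_nb = 1.0 / alpha
    return np.column_stack(
        [rng.negative_binomial(n_nb, n_nb / (n_nb + mu)) for _ in range(n_samples)]
    )


def _frame(mat):
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )


def _meta(n_a, n_b):
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n_a + n_b)],
            "stromal_type": "T",
            "condition": ["A"] * n_a + ["B"] * n_b,
            "replicate": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        }
    )


class TestNbWaldTest:
    def test_identical_groups_null_result(self, rng):
        block = _nb_counts(rng, 10 ** rng.uniform(1, 3, 50), 0.05, 4)
        counts = _frame(np.hstack([block, block]))
        meta = _meta(4, 4)
        factors = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, factors, meta, ("A", "B"))
        assert np.allclose(res["log2FC"], 0.0, atol=1e-6)
        assert np.allclose(res["p"].dropna(), 1.0, atol=1e-6)

    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(17)
        mu = 10 ** rng.uniform(1, 3, 1000)
        counts = _frame(_nb_counts(rng, mu, 0.05, 16))
        meta = _meta(8, 8)
        res = de.nb_wald_test(counts, nm.size_factors(counts), meta, ("A", "B"))
        frac = float((res["p"] < 0.05).mean())
        # binomial 99% CI around 0.05 at n=1000
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half < frac < 0.05 + half

    def test_effect_recovery(self):
        rng = np.random.default_rng(23)
        mu0 = np.full(500, 100.0)
        ya = _nb_counts(rng, mu0 * 4, 0.05, 5)
        yb = _nb_counts(rng, mu0, 0.05, 5)
        counts = _frame(np.hstack([ya, yb]))
        meta = _meta(5, 5)
        factors = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, factors, meta, ("A", "B"))
        assert abs(res["log2FC"].mean() - 2.0) < 0.2

    def test_wald_sign_matches_log2fc(self, two_group_counts):
        counts, meta = two_group_counts
        res = de.nb_wald_test(counts, nm.size_factors(counts), meta, ("A", "B"))
        nz = res.loc[res["log2FC"] != 0]
        assert np.all(np.sign(nz["wald_stat"]) == np.sign(nz["log2FC"]))

    def test_zero_group_flagged(self, rng):
        mat = _nb_counts(rng, np.full(5, 50.0), 0.05, 8)
        mat[0, :4] = 0  # group A all zero for gene 0
        counts = _frame(mat)
        meta = _meta(4, 4)
        factors = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, factors, meta, ("A", "B"))
        assert res.loc[res["feature"] == "g0", "flag"].iloc[0] == "zero_group"
        assert np.isfinite(res.loc[res["feature"] == "g0", "log2FC"].iloc[0])

    def test_too_few_replicates_raises(self, rng):
        counts = _frame(_nb_counts(rng, np.full(5, 50.0), 0.05, 3))
        meta = _meta(1, 2)
        with pytest.raises(ValueError, match="replicates"):
            de.nb_wald_test(counts, pd.Series(1.0, index=counts.columns), meta, ("A", "B"))

    def test_call_consistent_with_thresholds(self, two_group_counts):
        counts, meta = two_group_counts
        res = de.nb_wald_test(counts, nm.size_factors(counts), meta, ("A", "B"), q=0.1)
        up = res["call"] == "up"
        assert np.all(res.loc[up, "padj"] < 0.1)
        assert np.all(res.loc[up, "log2FC"] > 0)
        down = res["call"] == "down"
        assert np.all(res.loc[down, "padj"] < 0.1)
        assert np.all(res.loc[down, "log2FC"] < 0)

    def test_matches_quasipoisson_oracle_on_poisson_data(self):
        """Near the Poisson limit, p-values agree with an independent
        quasi-Poisson score-test oracle in aggregate calibration."""
        rng = np.random.default_rng(31)
        g, n = 600, 12
        mu = 10 ** rng.uniform(1.5, 2.5, g)
        y = np.column_stack([rng.poisson(mu) for _ in range(n)])
        counts = _frame(y)
        meta = _meta(6, 6)
        factors = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, factors, meta, ("A", "B"))
        in_a = np.array([True] * 6 + [False] * 6)
        size = np.ones(n)
        oracle_p = np.array(
            [quasipoisson_score_oracle(y[i], in_a, size) for i in range(g)]
        )
        for alpha in (0.01, 0.05, 0.1):
            ours = float((res["p"] < alpha).mean())
            theirs = float((oracle_p < alpha).mean())
            assert abs(ours - theirs) < 0.03


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        padj = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_propagates(self):
        padj = de.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(padj[1])
        assert np.isfinite(padj[0]) and np.isfinite(padj[2])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 40)).tolist()
            assert np.allclose(de.bh_adjust(p), bh_oracle(p))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_dominates_p_and_readjustment_only_inflates(self, p):
        # note: BH is not idempotent on arbitrary adjusted vectors
        # (p=[0.25, 1.0] -> [0.5, 1.0] -> [1.0, 1.0]); the true invariant is
        # that re-adjustment can only inflate, never shrink.
        padj = de.bh_adjust(p)
        assert np.all(padj >= np.asarray(p) - 1e-12)
        assert np.all(padj <= 1.0)
        again = de.bh_adjust(padj)
        assert np.all(again >= padj - 1e-12)

    def test_idempotent_on_flat_adjusted_vector(self):
        padj = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(de.bh_adjust(padj), padj)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestSelectClusterGenes:
    @staticmethod
    def _table(features, padj):
        return pd.DataFrame({"feature": features, "padj": padj})

    def test_union_over_contrasts(self):
        pairwise = {
            ("A", "B"): self._table(["g1", "g2"], [0.01, 0.9]),
            ("A", "C"): self._table(["g1", "g2"], [0.9, 0.04]),
            ("B", "C"): self._table(["g1", "g2"], [0.9, 0.9]),
        }
        assert de.select_cluster_genes(pairwise, ["A", "B", "C"]) == {"g1", "g2"}

    def test_empty_when_nothing_significant(self):
        pairwise = {
            ("A", "B"): self._table(["g1"], [0.9]),
            ("A", "C"): self._table(["g1"], [0.9]),
            ("B", "C"): self._table(["g1"], [0.9]),
        }
        assert de.select_cluster_genes(pairwise, ["A", "B", "C"]) == set()

    def test_missing_contrast_reported(self):
        pairwise = {("A", "B"): self._table(["g1"], [0.01])}
        with pytest.raises(ValueError, match=r"\('A', 'C'\)"):
            de.select_cluster_genes(pairwise, ["A", "B", "C"])

    def test_order_independent(self):
        pairwise = {
            ("B", "A"): self._table(["g1"], [0.01]),
            ("C", "A"): self._table(["g2"], [0.2]),
            ("C", "B"): self._table(["g3"], [0.03]),
        }
        assert de.select_cluster_genes(pairwise, ["A", "B", "C"]) == {"g1", "g3"}


class TestDeregulationOverlap:
    def test_superset_gives_one(self):
        out = de.deregulation_overlap({"a", "b"}, {"early": {"a", "b", "c"}})
        assert out["early"] == 1.0

    def test_disjoint_gives_zero(self):
        out = de.deregulation_overlap({"a"}, {"early": {"b"}})
        assert out["early"] == 0.0

    def test_partial_overlap(self):
        late = {f"g{i}" for i in range(10)}
        early = {f"g{i}" for i in range(4)} | {"x", "y"}
        assert de.deregulation_overlap(late, {"e": early})["e"] == pytest.approx(0.4)

    def test_empty_late_raises(self):
        with pytest.raises(ValueError):
            de.deregulation_overlap(set(), {"e": {"a"}})
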