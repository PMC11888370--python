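"""Enrichment metrics, synthon aggregation, replicate overlap, ML baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from delkit import analysis as an


class TestSamplingDepth:
    def test_ratio(self):
        assert an.sampling_depth(10_000, 1_000) == 10.0
        assert an.sampling_depth(0, 1_000) == 0.0

    def test_linear_in_reads(self):
        assert an.sampling_depth(2 * 12345, 999) == \
            2 * an.sampling_depth(12345, 999)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            an.sampling_depth(10, 0)


class TestNormalizedCount:
    def test_counts_per_million(self):
        assert an.normalized_count(5, 1_000_000) == 5.0
        assert an.normalized_count(0, 10) == 0.0

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=200)
        nsc = an.normalized_count(counts, counts.sum())
        assert nsc.sum() == pytest.approx(1e6)


class TestZScore:
    def test_null_expectation_is_zero(self):
        assert an.zscore(10, 1000, 0.01) == 0.0

    def test_frozen_value(self):
        # (30 - 1000*0.01) / sqrt(1000*0.01*0.99); cross-checked against a
        # binomial Monte-Carlo null in test_zscore_calibrated_against_binomial
        assert an.zscore(30, 1000, 0.01) == pytest.approx(6.357, abs=1e-3)

    def test_strictly_increasing_in_count(self):
        zs = [an.zscore(c, 1000, 0.01) for c in range(0, 40, 5)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_zscore_calibrated_against_binomial(self):
        """Monte-Carlo: under the null the z statistic is ~N(0,1)."""
        rng = np.random.default_rng(42)
        n, p0 = 2000, 0.02
        zs = an.zscore(rng.binomial(n, p0, size=4000), n, p0)
        assert abs(zs.mean()) < 0.05
        assert zs.std() == pytest.approx(1.0, abs=0.05)

    def test_invalid_p0_rejected(self):
        with pytest.raises(ValueError):
            an.zscore(1, 10, 0.0)

    def test_control_z_zero_at_equal_proportions(self):
        assert an.zscore_vs_control(5, 100, 10, 200) == 0.0
        assert an.zscore_vs_control(7, 70, 7, 70) == 0.0


class TestMLERatio:
    def test_equal_proportions_give_ratio_one(self):
        r, lo, hi = an.mle_ratio(10, 1000, 10, 1000)
        assert r == 1.0 and lo < 1.0 < hi

    def test_frozen_example(self):
        r, lo, hi = an.mle_ratio(20, 1000, 2, 1000)
        assert r == pytest.approx(8.2, abs=0.1)
        assert lo > 1.0
        assert lo < r < hi

    def test_reciprocity(self):
        r, _, _ = an.mle_ratio(20, 1000, 2, 1000)
        rinv, _, _ = an.mle_ratio(2, 1000, 20, 1000)
        assert r * rinv == pytest.approx(1.0)

    def test_interval_coverage_parametric_bootstrap(self):
        """CI covers the true rate ratio at >= nominal - 2% over 10^5 draws."""
        rng = np.random.default_rng(7)
        lam_t, lam_c, nt, nc = 0.012, 0.004, 2500, 2500
        true_ratio = lam_t / lam_c
        draws = 100_000
        ct = rng.poisson(lam_t * nt, size=draws)
        cc = rng.poisson(lam_c * nc, size=draws)
        _, lo, hi = an.mle_ratio(ct, nt, cc, nc, alpha=0.05)
        coverage = np.mean((lo <= true_ratio) & (true_ratio <= hi))
        assert coverage >= 0.95 - 0.02

    def test_zero_counts_finite(self):
        r, lo, hi = an.mle_ratio(0, 100, 0, 100)
        assert np.isfinite(r) and lo == 0.0 and np.isinf(hi)


def toy_cube():
    """2x2x2 toy cube with hand-computable counts."""
    rows = []
    counts = iter(range(1, 9))
    for a in ("A1", "A2"):
        for b in ("B1", "B2"):
            for c in ("C1", "C2"):
                n = next(counts)
                rows.append({
                    "compound_id": f"L-{a}-{b}-{c}", "library_id": "L",
                    "bb_1": a, "bb_2": b, "bb_3": c,
                    "t/1_raw_count": 2 * n, "t/1_umi_count": n,
                })
    return pd.DataFrame(rows)


class TestAggregateSynthons:
    def test_disynthon_rows_sum_pairs(self):
        cube = toy_cube()
        di = an.aggregate_synthons(cube, [1, 2])
        assert len(di) == 4
        # A1,B1 fixed -> compounds (A1,B1,C1)=1 and (A1,B1,C2)=2
        row = di.set_index("synthon_id").loc["L-A1-B1"]
        assert row["t/1_umi_count"] == 3 and row["t/1_raw_count"] == 6

    def test_counts_conserved(self):
        cube = toy_cube()
        for fixed in ([1], [2], [3], [1, 2], [2, 3]):
            agg = an.aggregate_synthons(cube, fixed)
            assert agg["t/1_umi_count"].sum() == cube["t/1_umi_count"].sum()

    def test_monosynthon_row_count(self):
        assert len(an.aggregate_synthons(toy_cube(), [2])) == 2

    def test_fixing_all_cycles_rejected(self):
        with pytest.raises(ValueError, match="compound level"):
            an.aggregate_synthons(toy_cube(), [1, 2, 3])

    def test_permutation_equivariance(self):
        cube = toy_cube()
        shuffled = cube.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = an.aggregate_synthons(cube, [1, 2])
        b = an.aggregate_synthons(shuffled, [1, 2])
        assert a.equals(b)


class TestEnrichmentTable:
    def test_metrics_present_and_consistent(self):
        cube = toy_cube()
        cube["n/1_raw_count"] = 2
        cube["n/1_umi_count"] = 1
        table = an.enrichment_table(cube, "t/1", control="n/1")
        assert {"sampling_depth", "nsc", "zscore", "zscore_vs_control",
                "mle_ratio"} <= set(table.columns)
        assert (table["mle_ratio_ci_low"] <= table["mle_ratio"]).all()
        assert (table["mle_ratio"] <= table["mle_ratio_ci_high"]).all()
        assert table["nsc"].sum() == pytest.approx(1e6)

    def test_missing_condition_mentions_available(self):
        with pytest.raises(ValueError, match="conditions present"):
            an.enrichment_table(toy_cube(), "nope")


class TestReplicateOverlap:
    def _table(self, passing, universe):
        return pd.DataFrame({
            "compound_id": sorted(universe),
            "zscore": [10.0 if k in passing else 0.0
                       for k in sorted(universe)]})

    def test_identical_tables_all_in_triple_region(self):
        keys = {f"k{i}" for i in range(20)}
        passing = {f"k{i}" for i in range(5)}
        tables = [self._table(passing, keys)] * 3
        regions = an.replicate_overlap(tables, "zscore", 5.0)
        assert regions[frozenset({0, 1, 2})] == 5
        assert all(v == 0 for k, v in regions.items() if len(k) < 3)

    def test_disjoint_sets_only_singles(self):
        keys = {f"k{i}" for i in range(10)}
        tables = [self._table({"k0"}, keys), self._table({"k1"}, keys)]
        regions = an.replicate_overlap(tables, "zscore", 5.0)
        assert regions[frozenset({0})] == 1
        assert regions[frozenset({1})] == 1
        assert regions[frozenset({0, 1})] == 0

    def test_planted_common_and_unique_passers(self):
        keys = {f"k{i}" for i in range(40)}
        common = {f"k{i}" for i in range(10)}
        tables = [self._table(common | {f"k{10 + 5 * r + j}" for j in range(5)},
                              keys)
                  for r in range(3)]
        regions = an.replicate_overlap(tables, "zscore", 5.0)
        assert regions[frozenset({0, 1, 2})] == 10
        for r in range(3):
            assert regions[frozenset({r})] == 5
        for pair in ({0, 1}, {0, 2}, {1, 2}):
            assert regions[frozenset(pair)] == 0
        # regions partition the union of passers
        union = set.union(*(set(t.loc[t.zscore > 5, "compound_id"])
                            for t in tables))
        assert sum(regions.values()) == len(union)

    def test_mismatched_key_spaces_rejected(self):
        a = self._table(set(), {"x", "y"})
        b = self._table(set(), {"x", "z"})
        with pytest.raises(ValueError, match="key spaces"):
            an.replicate_overlap([a, b], "zscore", 1.0)


class TestBalanceAndEvaluate:
    def test_no_signal_matches_dummy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 16))
        y = (rng.random(300) < 0.3).astype(int)
        res = an.balance_and_evaluate(X, y, folds=5, seed=0)
        assert abs(res.mean_accuracy - 0.5) < 0.15
        assert abs(res.mean_accuracy_dummy - 0.5) < 0.1

    def test_separable_signal_learned(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 8))
        y = (X[:, 3] > 0).astype(int)
        res = an.balance_and_evaluate(X, y, folds=5, seed=1)
        assert res.mean_accuracy > 0.9
        assert res.mean_accuracy_dummy < 0.65

    def test_balancing_equalises_classes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 4))
        y = np.array([0] * 150 + [1] * 50)
        res = an.balance_and_evaluate(X, y, folds=4, seed=2)
        assert res.n_per_class == 50

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            an.balance_and_evaluate(np.zeros((10, 2)), np.zeros(10))
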