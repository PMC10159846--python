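"""Abundance redistribution, aggregation, neutral-model fit and statistics."""

import numpy as np
import pandas as pd
import pytest

from viratlas import ecology, synthetic
from viratlas.taxonomy import upgma


class TestRedistribute:
    def test_no_ambiguous_reads_identity(self):
        totals, conv = ecology.redistribute({"a": 5.0, "b": 2.0}, [])
        assert conv and totals.to_dict() == {"a": 5.0, "b": 2.0}

    def test_proportional_fixed_point(self):
        totals, conv = ecology.redistribute({"a": 30, "b": 10}, [(20, ["a", "b"])])
        assert conv
        assert totals["a"] == pytest.approx(45.0, abs=1e-6)
        assert totals["b"] == pytest.approx(15.0, abs=1e-6)

    def test_all_zero_unique_uniform_split(self):
        totals, _ = ecology.redistribute({"a": 0.0, "b": 0.0}, [(10, ["a", "b"])])
        assert totals["a"] == pytest.approx(5.0)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            ecology.redistribute({"a": 1.0}, [(5, ["a"])])

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conserved(self, seed):
        rng = np.random.default_rng(seed)
        contigs = [f"c{i}" for i in range(6)]
        unique = {c: float(rng.integers(0, 50)) for c in contigs}
        groups = []
        for _ in range(4):
            members = list(rng.choice(contigs, rng.integers(2, 5), replace=False))
            groups.append((float(rng.integers(1, 30)), members))
        totals, _ = ecology.redistribute(unique, groups)
        expected = sum(unique.values()) + sum(c for c, _ in groups)
        assert totals.sum() == pytest.approx(expected, abs=1e-9)


class TestRelAbundance:
    def test_length_normalisation_hand_example(self):
        counts = pd.DataFrame({"a": [100], "b": [100]}, index=["s1"])
        ra = ecology.rel_abundance(counts, {"a": 10000, "b": 5000})
        assert ra.loc["s1", "a"] == pytest.approx(1 / 3)
        assert ra.loc["s1", "b"] == pytest.approx(2 / 3)

    def test_single_contig_and_uniform(self):
        ra = ecology.rel_abundance(pd.DataFrame({"a": [7]}, index=["s"]), {"a": 500})
        assert ra.loc["s", "a"] == 1.0
        ra2 = ecology.rel_abundance(
            pd.DataFrame({"a": [5], "b": [5]}, index=["s"]), {"a": 100, "b": 100})
        assert (ra2.loc["s"] == 0.5).all()

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, (5, 8)),
                              columns=[f"c{i}" for i in range(8)])
        counts.iloc[2] = 0
        ra = ecology.rel_abundance(counts, {f"c{i}": 1000 + i for i in range(8)})
        sums = ra.sum(axis=1)
        assert sums.iloc[2] == 0.0
        assert np.allclose(sums.drop(sums.index[2]), 1.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ecology.rel_abundance(pd.DataFrame({"a": [1]}), {"a": 0})


class TestAggregate:
    def test_hand_sum_and_conservation(self):
        ra = pd.DataFrame({"v1": [0.25], "v2": [0.5], "v3": [0.25]}, index=["s"])
        tax = pd.DataFrame({"family": {"v1": "F1", "v2": "F2", "v3": "F2"}})
        agg = ecology.aggregate(ra, tax, "family")
        assert agg.loc["s", "F1"] == pytest.approx(0.25)
        assert agg.loc["s", "F2"] == pytest.approx(0.75)
        assert agg.sum(axis=1).iloc[0] == pytest.approx(ra.sum(axis=1).iloc[0], abs=1e-12)

    def test_missing_votu_grouped_unassigned(self):
        ra = pd.DataFrame({"v1": [0.4], "v2": [0.6]}, index=["s"])
        agg = ecology.aggregate(ra, pd.DataFrame({"family": {"v1": "F1"}}), "family")
        assert agg.loc["s", "unassigned"] == pytest.approx(0.6)


class TestTaxonStats:
    def test_mra_includes_zeros_prevalence_counts_presence(self):
        ra = pd.DataFrame({"F": [0.1, 0.0]}, index=["s1", "s2"])
        stats = ecology.taxon_stats(ra)
        assert stats.loc["F", "mra"] == pytest.approx(0.05)
        assert stats.loc["F", "prevalence"] == pytest.approx(0.5)

    def test_absent_everywhere(self):
        stats = ecology.taxon_stats(pd.DataFrame({"F": [0.0, 0.0]}))
        assert stats.loc["F", "mra"] == 0.0 and stats.loc["F", "prevalence"] == 0.0


class TestNeutralCommunityModel:
    def test_residual_zero_when_observation_matches_prediction(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.lognormal(0, 1, 50))
        p /= p.sum()
        model = ecology.NeutralCommunityModel(N=10000, n_samples=100)
        obs = model._predict_prevalence(0.2, p)
        model.fit(p, obs)
        assert model.m_ == pytest.approx(0.2, rel=1e-3)
        assert np.nanmax(np.abs(model.residuals_)) < 1e-6

    def test_high_migration_limit_prevalence_one(self):
        model = ecology.NeutralCommunityModel(N=10000)
        model.m_ = 0.999
        p = np.array([0.01, 0.05, 0.2])  # all far above d = 1e-4
        assert np.all(model.predict(p) > 0.999)

    @pytest.mark.parametrize("m_true", [0.05, 0.1, 0.3])
    def test_parameter_recovery_from_sloan_sampling(self, m_true):
        """Module invariant: <= 20% relative error at 300 taxa x 200 samples."""
        votus = [f"v{i}" for i in range(300)]
        tax = pd.DataFrame({"votu": votus, "genus": [f"g{i // 5}" for i in range(300)],
                            "family": "f", "order": "o"}).set_index("votu")
        truth = synthetic.TruthTables(tax, {}, {}, {}, {}, {}, {},
                                      {v: 10000 for v in votus}, {}, {}, None)
        cfg = synthetic.SyntheticConfig(
            seed=4, ambiguous_fraction=0.0,
            ncm=synthetic.NCMParams(N_reads=30000, m=m_true, n_samples=200))
        counts, _ = synthetic.make_count_matrix(truth, cfg)
        ra = counts.div(counts.sum(axis=1), axis=0)
        stats = ecology.taxon_stats(ra)
        model, table = ecology.ncm_fit(stats, N=30000, n_samples=200)
        assert abs(model.m_ - m_true) / m_true <= 0.20
        assert "ncm_residual" in table

    def test_too_few_clades_rejected(self):
        with pytest.raises(ValueError):
            ecology.NeutralCommunityModel(N=100).fit([0.5, 0.5], [1, 1])


class TestUniqueBranchFraction:
    def tree(self):
        D = pd.DataFrame([[0, .2, .6], [.2, 0, .6], [.6, .6, 0]],
                         index=list("ABC"), columns=list("ABC"))
        return upgma(D)

    def test_star_is_all_pendant(self):
        star = upgma(np.full((3, 3), 0.4) - 0.4 * np.eye(3))
        assert ecology.unique_branch_fraction(star, star.tips) == pytest.approx(1.0)

    def test_hand_computed_three_tip_fraction(self):
        # pendants 0.1 + 0.1 + 0.3, internal 0.2
        assert ecology.unique_branch_fraction(self.tree(), list("ABC")) == pytest.approx(5 / 7)

    def test_internal_structure_lowers_fraction(self):
        assert (ecology.unique_branch_fraction(self.tree(), list("ABC"))
                < 1.0)

    def test_single_tip_conventional_one(self):
        with pytest.warns(UserWarning, match="convention"):
            assert ecology.unique_branch_fraction(self.tree(), ["A"]) == 1.0


class TestRankStatistics:
    def test_identical_groups_p_one(self):
        assert ecology.rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_exact_enumeration_small_groups(self):
        assert ecology.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(6), rng.random(9)
        assert ecology.rank_sum_test(a, b) == pytest.approx(ecology.rank_sum_test(b, a))

    def test_tied_large_groups_use_normal_approximation(self):
        a = [1, 1, 2, 3, 3, 4, 5, 5, 6, 7]
        b = [3, 3, 4, 5, 5, 6, 7, 8, 8, 9]
        p = ecology.rank_sum_test(a, b)
        assert 0 < p <= 1

    def test_spearman_monotone_and_reverse(self):
        h = {"g1": 0.1, "g2": 0.2, "g3": 0.3, "g4": 0.4}
        v = {"g1": 0.01, "g2": 0.04, "g3": 0.09, "g4": 0.5}
        rho, _ = ecology.phage_host_correlation(h, v)
        assert rho == pytest.approx(1.0)
        rev = {"g1": 4, "g2": 3, "g3": 2, "g4": 1}
        rho2, _ = ecology.phage_host_correlation(h, rev)
        assert rho2 == pytest.approx(-1.0)

    def test_spearman_with_twenty_percent_noise(self):
        rng = np.random.default_rng(5)
        hosts = {f"g{i}": x for i, x in enumerate(rng.lognormal(0, 1, 30))}
        phage = {g: x * rng.lognormal(0, 0.2) for g, x in hosts.items()}
        rho, p = ecology.phage_host_correlation(hosts, phage)
        assert rho > 0.7
        assert p < 0.01

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = ecology.phage_host_correlation(
                {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 0.1, "b": 0.2, "c": 0.3})
        assert np.isnan(rho)

    def test_fewer_than_three_shared_rejected(self):
        with pytest.raises(ValueError):
            ecology.phage_host_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2})
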