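"""Alteration integration and the Bayesian prevalence model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histomics.prevalence import (
    GeneAlterationMatrix,
    PosteriorFit,
    PrevalenceCounts,
    build_alteration_matrix,
    count_significance_null,
    filter_candidate_mutations,
    fit_prevalence,
    flag_hypermutators,
    flag_significant_genes,
    proportion_ci,
    quadrature_posterior,
    select_comparison_genes,
)


class TestMutationFilters:
    def records(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "chrom", "pos",
                                           "ref", "alt", "altered_reads",
                                           "distinct_reads"])

    def test_targeted_fraction_strictly_above_ten_percent(self):
        recs = self.records([
            ("s1", "G1", "chr1", 1, "A", "T", 10, 100),   # exactly 0.10: dropped
            ("s2", "G1", "chr1", 1, "A", "T", 11, 100),
        ])
        kept = filter_candidate_mutations(recs, assay="targeted")
        assert kept["sample_id"].tolist() == ["s2"]

    def test_wes_needs_five_altered_reads_somewhere(self):
        recs = self.records([
            ("s1", "G1", "chr1", 1, "A", "T", 4, 20),  # 0.2 but never >= 5 reads
            ("s2", "G1", "chr1", 1, "A", "T", 4, 20),
            ("s1", "G2", "chr2", 9, "C", "G", 5, 25),  # anchors the G2 mutation
            ("s2", "G2", "chr2", 9, "C", "G", 3, 15),
        ])
        kept = filter_candidate_mutations(recs, assay="WES")
        assert set(kept["gene"]) == {"G2"}
        assert len(kept) == 2  # the low-read carrier of G2 rides along

    def test_missing_depth_column_rejected(self):
        with pytest.raises(ValueError, match="distinct_reads"):
            filter_candidate_mutations(pd.DataFrame({"altered_reads": [1]}),
                                       assay="WES")


class TestHypermutators:
    def test_threshold_is_strictly_greater_than_500(self):
        counts = pd.Series({"a": 500, "b": 501, "c": 12_666, "d": 891, "e": 54})
        flags = flag_hypermutators(counts)
        assert flags.to_dict() == {"a": False, "b": True, "c": True,
                                   "d": True, "e": False}


def toy_matrix():
    genes = ["TP53", "KRAS", "CDKN2A"]
    data = pd.DataFrame(
        [[1, 0, 1, 0], [0, 0, 1, 1], [1, 1, 0, 0]],
        index=genes, columns=["s1", "s2", "s3", "s4"])
    groups = pd.Series([0, 0, 1, 1], index=data.columns)
    counts = pd.Series([40, 700, 30, 20], index=data.columns)
    return GeneAlterationMatrix(data=data, groups=groups,
                                mutation_counts=counts,
                                hypermutator=flag_hypermutators(counts))


class TestAlterationMatrix:
    def gene_intervals(self):
        return pd.DataFrame({"gene": ["PTEN", "ERBB2"], "chrom": ["chr10", "chr17"],
                             "start": [100, 500], "end": [200, 600]})

    def samples(self):
        return pd.DataFrame({"sample_id": ["s1", "s2"], "group": [0, 1],
                             "mutation_count": [40, 60]})

    def test_structural_only_alteration_counts(self):
        mutations = pd.DataFrame(columns=["sample_id", "gene"])
        deletions = {"s1": [("chr10", 150, 180)]}
        m = build_alteration_matrix(mutations, deletions, None, None,
                                    self.gene_intervals(), self.samples())
        assert m.data.loc["PTEN", "s1"] == 1
        assert m.data.loc["PTEN", "s2"] == 0
        assert m.data.loc["ERBB2"].sum() == 0

    def test_idempotent_under_duplicate_records(self):
        mutations = pd.DataFrame({"sample_id": ["s1", "s1"], "gene": ["PTEN", "PTEN"]})
        deletions = {"s1": [("chr10", 150, 180), ("chr10", 150, 180)]}
        m = build_alteration_matrix(mutations, deletions, None, None,
                                    self.gene_intervals(), self.samples())
        assert m.data.loc["PTEN", "s1"] == 1  # binary, not counted

    def test_unknown_gene_warns_and_skips(self):
        mutations = pd.DataFrame({"sample_id": ["s1"], "gene": ["NOT_A_GENE"]})
        with pytest.warns(UserWarning, match="NOT_A_GENE"):
            m = build_alteration_matrix(mutations, None, None, None,
                                        self.gene_intervals(), self.samples())
        assert m.data.to_numpy().sum() == 0


class TestGeneSelection:
    def test_combined_frequency_inclusive_at_threshold(self):
        m = toy_matrix()  # s2 is a hypermutator -> denominators use 3 samples
        # TP53 2/3, KRAS 2/3, CDKN2A 1/3 after hypermutator exclusion
        assert select_comparison_genes(m, ["TP53", "KRAS", "CDKN2A"],
                                       min_freq=2 / 3) == ["TP53", "KRAS"]

    def test_empty_driver_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_comparison_genes(toy_matrix(), [])


class TestPosterior:
    def test_symmetric_counts_give_zero_lor(self):
        q = quadrature_posterior(PrevalenceCounts(5, 10, 5, 10))
        assert abs(q.lor_mean) <= 1e-6
        f = fit_prevalence(PrevalenceCounts(5, 10, 5, 10), n_draws=20_000, seed=0)
        assert abs(f.lor_mean) <= 0.02

    def test_sampler_matches_quadrature_oracle(self):
        counts = PrevalenceCounts(11, 35, 0, 9)
        q = quadrature_posterior(counts)
        f = fit_prevalence(counts, n_draws=50_000, seed=2)
        assert f.lor_mean == pytest.approx(q.lor_mean, abs=0.05)
        assert f.lor_q05 == pytest.approx(q.lor_q05, abs=0.05)
        assert f.lor_q95 == pytest.approx(q.lor_q95, abs=0.05)

    def test_quadrature_grid_refinement_is_converged(self):
        counts = PrevalenceCounts(7, 20, 3, 15)
        coarse = quadrature_posterior(counts, step=0.02)
        fine = quadrature_posterior(counts, step=0.01)
        assert fine.lor_mean == pytest.approx(coarse.lor_mean, abs=1e-3)

    def test_antisymmetry_under_group_swap(self):
        a = quadrature_posterior(PrevalenceCounts(11, 35, 2, 9))
        b = quadrature_posterior(PrevalenceCounts(2, 9, 11, 35))
        assert a.lor_mean == pytest.approx(-b.lor_mean, abs=0.02)

    def test_positive_lor_means_higher_reference_prevalence(self):
        fit = quadrature_posterior(PrevalenceCounts(30, 40, 5, 40))
        assert fit.lor_mean > 0
        assert fit.theta0_mean > fit.theta1_mean

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            PrevalenceCounts(0, 0, 1, 10)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="2000"):
            fit_prevalence(PrevalenceCounts(1, 10, 1, 10), n_draws=100)


class TestSignificance:
    @pytest.mark.parametrize("q05,q95,expected", [
        (0.51, 3.58, True),    # interval excludes zero
        (-0.38, 1.33, False),  # spans zero
        (0.0, 1.0, False),     # boundary exactly zero: strict exclusion
    ])
    def test_credible_interval_rule(self, q05, q95, expected):
        fit = PosteriorFit(lor_mean=1.0, lor_q05=q05, lor_q95=q95,
                           theta0_mean=0.3, theta1_mean=0.1,
                           n_effective=1000, method="test")
        assert fit.significant is expected

    def test_flagging_collects_significant_genes(self):
        fits = {
            "CDKN2A": PosteriorFit(1.87, 0.51, 3.58, 0.3, 0.05, 1e3, "t"),
            "TP53": PosteriorFit(0.42, -0.38, 1.33, 0.5, 0.4, 1e3, "t"),
        }
        assert flag_significant_genes(fits) == ["CDKN2A"]


class TestMonteCarloNull:
    def test_observed_zero_gives_p_one(self):
        assert count_significance_null(6, 0, reps=100, seed=0) == 1.0

    def test_converges_to_exact_binomial_tail(self):
        # P(X >= 4), X ~ Binomial(6, 0.1) = 0.0012699
        exact = stats.binom.sf(3, 6, 0.1)
        reps = 200_000
        p = count_significance_null(6, 4, alpha=0.1, reps=reps, seed=3)
        mc_sd = np.sqrt(exact * (1 - exact) / reps)
        assert abs(p - exact) <= 3 * mc_sd

    def test_monotone_in_observed(self):
        ps = [count_significance_null(6, k, reps=2_000, seed=9) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestProportionCI:
    def test_clopper_pearson_zero_numerator(self):
        lo, hi = proportion_ci(0, 7, method="beta")
        assert lo == 0.0
        assert hi == pytest.approx(stats.beta.ppf(0.975, 1, 7), abs=1e-9)
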