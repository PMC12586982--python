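"""Genotype-concordance matching: consensus, pairing, null, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histomics.concordance import (
    ConcordanceResult,
    NullSummary,
    PileupPanel,
    all_pair_concordances,
    concordance_null,
    match_samples,
    pair_concordance,
    panel_consensus,
    select_snp_sites,
    site_consensus,
)
from histomics.synthetic import make_pileup_cohort


def make_panel(sample_id, counts):
    counts = np.asarray(counts)
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.arange(1, len(counts) + 1),
                          "variant_class": "single"})
    return PileupPanel(sample_id=sample_id, sites=sites, counts=counts)


class TestSiteSelection:
    def catalog(self, n_sub, n_indel):
        return pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(n_sub + n_indel),
            "variant_class": ["single"] * n_sub + ["insertion"] * n_indel,
        })

    def test_only_substitutions_survive(self):
        panel = select_snp_sites(self.catalog(5, 3), n=5, seed=0)
        assert len(panel) == 5
        assert (panel["variant_class"] == "single").all()

    def test_deterministic_and_unique(self):
        cat = self.catalog(50_000, 0)
        a = select_snp_sites(cat, n=10_000, seed=4)
        b = select_snp_sites(cat, n=10_000, seed=4)
        assert a.equals(b)
        assert len(a) == 10_000 and a["pos"].is_unique

    def test_insufficient_sites_error(self):
        with pytest.raises(ValueError, match="eligible"):
            select_snp_sites(self.catalog(4, 10), n=5, seed=0)


class TestSiteConsensus:
    @pytest.mark.parametrize("counts,expected", [
        ([19, 0, 0, 0], None),        # below 20-read depth floor
        ([20, 0, 0, 0], "A"),         # unanimous at the floor
        ([19, 1, 0, 0], "A"),         # fraction exactly 0.95: evaluable
        ([18, 2, 0, 0], None),        # 0.90 < 0.95
        ([0, 0, 40, 0], "G"),
    ])
    def test_rules(self, counts, expected):
        assert site_consensus(np.array(counts)) == expected

    @given(a=st.integers(0, 60), c=st.integers(0, 60),
           depth=st.integers(20, 40), frac=st.floats(0.9, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stricter_filters_never_add_evaluable_sites(self, a, c, depth, frac):
        counts = np.array([[a, c, 3, 0]])
        panel = make_panel("s", counts)
        _, loose = panel_consensus(panel, min_depth=20, min_fraction=0.95)
        _, tight = panel_consensus(panel, min_depth=depth + 20,
                                   min_fraction=min(1.0, frac + 0.95 - 0.9))
        assert not (tight & ~loose).any()


class TestPairConcordance:
    def test_self_concordance_is_one(self):
        p = make_panel("x", [[30, 0, 0, 0]] * 6)
        r = pair_concordance(p, p)
        assert r.concordance == 1.0 and r.n_evaluated == 6

    def test_hand_counted_half(self):
        a = make_panel("a", [[30, 0, 0, 0]] * 10)
        b_counts = [[30, 0, 0, 0]] * 5 + [[0, 30, 0, 0]] * 5
        r = pair_concordance(a, make_panel("b", b_counts))
        assert r.n_evaluated == 10 and r.n_matched == 5
        assert r.concordance == 0.5

    def test_one_sided_evaluable_sites_excluded(self):
        a = make_panel("a", [[30, 0, 0, 0], [30, 0, 0, 0]])
        b = make_panel("b", [[30, 0, 0, 0], [5, 0, 0, 0]])  # site 2 too shallow in b
        r = pair_concordance(a, b)
        assert r.n_evaluated == 1

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = make_panel("a", rng.integers(0, 40, size=(50, 4)))
        b = make_panel("b", rng.integers(0, 40, size=(50, 4)))
        ra, rb = pair_concordance(a, b), pair_concordance(b, a)
        assert (ra.n_evaluated, ra.n_matched) == (rb.n_evaluated, rb.n_matched)

    def test_matrix_path_equals_pairwise_path(self):
        rng = np.random.default_rng(1)
        panels = [make_panel(f"s{i}", rng.integers(0, 60, size=(40, 4)))
                  for i in range(5)]
        fast = {frozenset((r.sample_a, r.sample_b)): (r.n_evaluated, r.n_matched)
                for r in all_pair_concordances(panels)}
        for i in range(5):
            for j in range(i + 1, 5):
                r = pair_concordance(panels[i], panels[j])
                assert fast[frozenset((r.sample_a, r.sample_b))] \
                    == (r.n_evaluated, r.n_matched)


class TestNull:
    def test_threshold_formula(self):
        s = NullSummary(q1=0.60, q3=0.70, n_pairs=100)
        assert s.threshold == pytest.approx(0.85)

    def test_degenerate_equal_null(self):
        results = [ConcordanceResult(f"a{i}", f"b{i}", 100, 80) for i in range(20)]
        s = concordance_null(results, n_pairs=10, seed=0)
        assert s.iqr == 0.0 and s.threshold == pytest.approx(0.8)

    def test_excluded_pairs_do_not_enter(self):
        high = ConcordanceResult("t", "n", 100, 100)
        low = [ConcordanceResult(f"a{i}", f"b{i}", 100, 60) for i in range(20)]
        s = concordance_null([high] + low, n_pairs=50, seed=0,
                             exclude={frozenset(("t", "n"))})
        assert s.q3 == pytest.approx(0.6)


class TestMatching:
    def sheet(self, ids, tumor_types=None):
        return pd.DataFrame({
            "sample_id": ids,
            "patient_id": [i.split("_")[0] for i in ids],
            "tumor_type": tumor_types or ["carcinoma"] * len(ids),
        })

    def test_true_pair_matched_and_loner_excluded(self):
        results = [
            ConcordanceResult("P1_T", "P1_N", 100, 99),
            ConcordanceResult("P1_T", "P2_T", 100, 60),
            ConcordanceResult("P1_N", "P2_T", 100, 61),
        ]
        null = NullSummary(q1=0.58, q3=0.62, n_pairs=100)  # threshold 0.68
        matches, excl = match_samples(results, null,
                                      self.sheet(["P1_T", "P1_N", "P2_T"]))
        assert len(matches) == 1
        assert {matches.iloc[0]["sample_a"], matches.iloc[0]["sample_b"]} \
            == {"P1_T", "P1_N"}
        assert excl["sample_id"].tolist() == ["P2_T"]
        assert excl["reason"].tolist() == ["no_genotype_match"]

    def test_tumor_type_mismatch_excludes_both(self):
        results = [ConcordanceResult("P1_T", "P9_X", 100, 99)]
        null = NullSummary(q1=0.58, q3=0.62, n_pairs=100)
        matches, excl = match_samples(
            results, null, self.sheet(["P1_T", "P9_X"], ["mucinous", "endometrioid"]))
        assert matches.empty
        assert set(excl["sample_id"]) == {"P1_T", "P9_X"}
        assert set(excl["reason"]) == {"tumor_type_mismatch"}

    def test_genuine_tie_is_ambiguous(self):
        results = [
            ConcordanceResult("P1_T", "P1_N", 100, 99),
            ConcordanceResult("P1_T", "P2_N", 100, 99),  # indistinguishable rival
        ]
        null = NullSummary(q1=0.58, q3=0.62, n_pairs=100)
        matches, excl = match_samples(results, null,
                                      self.sheet(["P1_T", "P1_N", "P2_N"]))
        assert matches.empty
        assert "ambiguous_multiple_matches" in set(excl["reason"])


class TestEndToEnd:
    def test_duplicates_recovered_without_error(self):
        cohort = make_pileup_cohort(n_individuals=12, n_sites=800, depth_mean=50,
                                    error_rate=0.0, n_duplicated=4, seed=5)
        results = all_pair_concordances(cohort.panels)
        true_pairs = {frozenset((t, n)) for t, n in cohort.truth.pair_map.items()}
        by_pair = {frozenset((r.sample_a, r.sample_b)): r.concordance
                   for r in results}
        # with zero sequencing error a duplicated pair is perfectly concordant
        assert all(by_pair[p] == 1.0 for p in true_pairs)

    def test_matching_recovers_all_true_pairs(self, small_pileup_cohort):
        cohort = small_pileup_cohort
        results = all_pair_concordances(cohort.panels)
        true_pairs = {frozenset((t, n)) for t, n in cohort.truth.pair_map.items()}
        null = concordance_null(results, n_pairs=500, seed=1, exclude=true_pairs)
        matches, _ = match_samples(results, null, cohort.sample_sheet)
        recovered = {frozenset((a, b))
                     for a, b in zip(matches["sample_a"], matches["sample_b"])}
        assert recovered >= true_pairs
        assert not recovered - true_pairs  # no false matches
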