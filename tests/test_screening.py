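"""Trait summarization, bonitur scoring and dense ranking."""

import pytest

from pgpbscreen.model import (
    Medium,
    Soil,
    Source,
    StrainRecord,
    TraitMeasurement,
)
from pgpbscreen.reference import (
    REPORTED_BIOMETRIC_CUTOFFS,
    REPORTED_TRAIT_MEANS,
    load_bonitur_scores,
    load_genus_counts,
)
from pgpbscreen.screening import (
    MAX_TOTAL,
    biometric_score,
    biometric_score_fixed,
    bonitur_total,
    genus_distribution,
    rank_strains,
    trait_bin_bounds,
    trait_score,
    trait_summary,
)
from pgpbscreen.stats import MeansGrouping


class TestTraitSummary:
    def make(self):
        strains = [
            StrainRecord(f"s{i}", Source.BS, Soil.SF, Medium.JMV, "Rhizobium")
            for i in range(3)
        ]
        traits = [
            TraitMeasurement("s0", iaa=10.0),
            TraitMeasurement("s1", iaa=20.0, fepo4=5.0),
            TraitMeasurement("s2"),
        ]
        return traits, strains

    def test_counts_means_and_cooccurrence(self):
        traits, strains = self.make()
        s = trait_summary(traits, strains)
        assert s.per_trait.loc["iaa", "n_positive"] == 2
        assert s.per_trait.loc["iaa", "mean"] == pytest.approx(15.0)
        assert s.at_least_one == 2
        assert s.multi_trait == 1
        assert s.co_occurrence[frozenset({"iaa"})] == 1
        assert s.co_occurrence[frozenset({"iaa", "fepo4"})] == 1
        assert s.co_occurrence[frozenset()] == 1

    def test_trait_with_no_positives_reports_absent_mean(self):
        traits, strains = self.make()
        s = trait_summary(traits, strains)
        assert s.per_trait.loc["alpo4", "n_positive"] == 0
        import math
        assert math.isnan(s.per_trait.loc["alpo4", "mean"])


class TestTraitScore:
    def test_not_detected_scores_zero(self):
        assert trait_score(None, 3.85) == 0

    def test_band_mode_reproduces_published_alpo4_cutoffs(self):
        lower, upper = trait_bin_bounds(3.85, "band")
        assert round(lower, 1) == 2.5
        assert round(upper, 1) == 5.2
        assert trait_score(3.0, 3.85) == 2  # inside [2.50, 5.20)
        assert trait_score(17.05, 3.85) == 3  # the printed maximum
        assert trait_score(1.0, 3.85) == 1

    def test_boundaries_resolve_to_the_higher_bin(self):
        lower, upper = trait_bin_bounds(10.0, "band")  # 6.5 / 13.5
        assert trait_score(lower, 10.0) == 2
        assert trait_score(upper, 10.0) == 3

    def test_literal_mode_uses_textual_cutoffs(self):
        assert trait_bin_bounds(10.0, "literal") == (3.5, 7.0)
        assert trait_score(3.0, 10.0, "literal") == 1
        assert trait_score(5.0, 10.0, "literal") == 2
        assert trait_score(8.0, 10.0, "literal") == 3

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            trait_score(-1.0, 3.85)

    def test_monotone_in_the_trait_value(self):
        mean = REPORTED_TRAIT_MEANS["fepo4"]
        scores = [trait_score(v, mean) for v in (0.1, 2.0, 4.2, 6.0, 9.0, 56.0)]
        assert scores == sorted(scores)


class TestBiometricScore:
    def grouping(self):
        return MeansGrouping(
            clusters=[["high"], ["CONTROL", "same"], ["low"]],
            means={"high": 1.0, "CONTROL": 0.5, "same": 0.52, "low": 0.1},
        )

    def test_relative_to_control_cluster(self):
        g = self.grouping()
        assert biometric_score("high", g) == 2
        assert biometric_score("same", g) == 1
        assert biometric_score("low", g) == 0

    def test_absent_strain_raises(self):
        with pytest.raises(KeyError):
            biometric_score("ghost", self.grouping())

    def test_fixed_cutoff_mode_replays_published_bounds(self):
        lo, hi = REPORTED_BIOMETRIC_CUTOFFS[("tomato", "rdw")]
        assert biometric_score_fixed(0.30, lo, hi) == 2  # >= 0.27
        assert biometric_score_fixed(0.25, lo, hi) == 1
        lo, hi = REPORTED_BIOMETRIC_CUTOFFS[("tomato", "sdw")]
        assert biometric_score_fixed(0.70, lo, hi) == 0  # <= 0.79


class TestBoniturTotals:
    def test_published_component_rows_sum_to_printed_totals(self):
        table = load_bonitur_scores()
        comps = ["iaa", "fepo4", "alpo4", "siderophore_index",
                 "tomato_rdw", "tomato_sdw", "lulo_rdw", "lulo_sdw"]
        for _, row in table.iterrows():
            res = bonitur_total(row["strain_id"], [row[c] for c in comps])
            assert res.total == row["printed_total"]
            assert res.biotech_potential

    def test_top_strain_example(self):
        res = bonitur_total("019S", (3, 3, 2, 0, 2, 1, 1, 2))
        assert res.total == 14 and res.biotech_potential

    def test_all_zeros(self):
        res = bonitur_total("x", (0,) * 8)
        assert res.total == 0 and not res.biotech_potential

    def test_component_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonitur_total("x", (4, 0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            bonitur_total("x", (0, 0, 0, 0, 3, 0, 0, 0))

    def test_maximum_achievable_total_is_twenty(self):
        assert MAX_TOTAL == 20
        assert bonitur_total("x", (3, 3, 3, 3, 2, 2, 2, 2)).total == 20


class TestRanking:
    def results(self, totals):
        caps = (3, 3, 3, 3, 2, 2, 2, 2)
        out = []
        for i, t in enumerate(totals):
            scores, left = [], t
            for cap in caps:
                take = min(cap, left)
                scores.append(take)
                left -= take
            assert left == 0
            out.append(bonitur_total(f"s{i}", scores))
        return out

    def test_dense_ranks_share_and_have_no_gaps(self):
        ranked = rank_strains(self.results([14, 12, 12, 11]))
        assert [r.rank for r in ranked] == [1, 2, 2, 3]

    def test_published_ranking_pattern_reproduced(self):
        table = load_bonitur_scores()
        comps = ["iaa", "fepo4", "alpo4", "siderophore_index",
                 "tomato_rdw", "tomato_sdw", "lulo_rdw", "lulo_sdw"]
        results = [bonitur_total(r["strain_id"], [r[c] for c in comps])
                   for _, r in table.iterrows()]
        ranked = {r.strain_id: r.rank for r in rank_strains(results)}
        printed = dict(zip(table["strain_id"], table["printed_rank"]))
        assert ranked == printed

    def test_single_and_all_tied(self):
        assert rank_strains([bonitur_total("a", (1,) * 8)])[0].rank == 1
        ranked = rank_strains(self.results([9, 9, 9]))
        assert {r.rank for r in ranked} == {1}

    def test_rank_non_increasing_in_total(self):
        ranked = rank_strains(self.results([3, 17, 8, 8, 20, 0]))
        totals = [r.total for r in ranked]
        ranks = [r.rank for r in ranked]
        assert totals == sorted(totals, reverse=True)
        assert ranks == sorted(ranks)
        assert max(ranks) == len(set(totals))  # dense: no gaps


class TestGenusDistribution:
    def test_census_percentages(self):
        counts = load_genus_counts()
        strains = []
        i = 0
        for _, row in counts.iterrows():
            for _ in range(row["count"]):
                strains.append(StrainRecord(f"s{i}", Source.BS, Soil.SF,
                                            Medium.JMV, row["genus"]))
                i += 1
        dist = genus_distribution(strains).set_index("genus")
        assert dist.loc["Rhizobium", "count"] == 59
        assert dist.loc["Rhizobium", "percent"] == 58.4
        assert dist["count"].sum() == 101

    def test_empty_collection_gives_empty_table(self):
        assert genus_distribution([]).empty
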