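import numpy as np
import pytest

from ribotradeoff.sequence_io import CodingSequence, GeneSubset
from ribotradeoff.structure import (
    StructureProfile,
    StructureRegion,
    ThresholdRule,
    load_structure_scores,
)
from ribotradeoff.tradeoff_stats import (
    aa_composition_by_region,
    assign_codons,
    codon_usage_by_region,
    genome_tradeoff,
    tradeoff_statistic,
)


def region(start, end, klass, gene_id="g"):
    return StructureRegion(gene_id=gene_id, start_nt=start, end_nt=end, klass=klass)


@pytest.fixture()
def pars_profiles(tmp_path_factory, pars_genome, pars_trimmed):
    path = tmp_path_factory.mktemp("scores") / "scores.tsv"
    pars_genome.scores.to_csv(path, sep="\t", index=False)
    return load_structure_scores(path, pars_trimmed, 51)


class TestAssignCodons:
    def test_full_containment_rule(self):
        cds = CodingSequence(id="g", seq="ACG" * 20)
        # codon 8 spans nt 24..27, crossing the region end at 25
        assigned = assign_codons(cds, [region(0, 25, "high")])
        assert assigned["high"] == list(range(8))
        assert assigned["low"] == []

    def test_matches_span_enumeration(self, rng):
        cds = CodingSequence(id="g", seq="ACG" * 50)
        start, end = sorted(rng.integers(0, 150, 2).tolist())
        assigned = assign_codons(cds, [region(start, end, "low")])
        expected = [
            k for k in range(50) if start <= 3 * k and 3 * k + 3 <= end
        ]
        assert assigned["low"] == expected

    def test_no_regions_empty(self):
        cds = CodingSequence(id="g", seq="ACG" * 10)
        assert assign_codons(cds, []) == {"high": [], "low": []}

    def test_exact_codon_region(self):
        cds = CodingSequence(id="g", seq="ACG" * 10)
        assert assign_codons(cds, [region(0, 3, "high")])["high"] == [0]

    def test_overlapping_same_class_rejected(self):
        cds = CodingSequence(id="g", seq="ACG" * 20)
        with pytest.raises(ValueError, match="overlapping"):
            assign_codons(cds, [region(0, 30, "high"), region(27, 45, "high")])


class TestTradeoffStatistic:
    def test_identical_pools_zero_delta(self):
        res = tradeoff_statistic([1, 2, 3], [1, 2, 3])
        assert res.delta_t == 0.0
        assert res.tradeoff_score == 0.0

    def test_separated_pools_exact_p(self):
        res = tradeoff_statistic([1, 2, 3], [4, 5, 6])
        assert res.delta_t == pytest.approx(3.0)
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements

    def test_sign_conventions_opposite(self, rng):
        high = rng.normal(60, 5, 50)
        low = rng.normal(80, 5, 50)
        res = tradeoff_statistic(high, low)
        assert res.delta_t == pytest.approx(-res.tradeoff_score)
        assert res.delta_t > 0

    def test_antisymmetry_under_swap(self, rng):
        high = rng.integers(50, 100, 30).astype(float)
        low = rng.integers(60, 120, 40).astype(float)
        res = tradeoff_statistic(high, low)
        swapped = tradeoff_statistic(low, high)
        assert res.delta_t == pytest.approx(-swapped.delta_t)
        assert res.p_value == pytest.approx(swapped.p_value)

    def test_quartiles_bracket_median(self, rng):
        res = tradeoff_statistic(rng.normal(0, 1, 100), rng.normal(1, 2, 100))
        q1h, q3h = res.iqr_high
        assert q1h <= res.median_high <= q3h

    def test_empty_pool_gives_na_row(self):
        res = tradeoff_statistic([], [1.0, 2.0], n_regions=(0, 1))
        assert not res.defined
        assert np.isnan(res.p_value)
        assert res.n_codons_low == 2 and res.n_regions_low == 1


class TestGenomeTradeoff:
    def test_planted_positive_delta(self, pars_genome, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        res = genome_tradeoff(pars_trimmed, pars_profiles, ecoli_table, rule)
        assert res.defined and res.delta_t > 0
        assert res.p_value < 1e-10

    def test_gene_order_invariance(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        res1 = genome_tradeoff(pars_trimmed, pars_profiles, ecoli_table, rule)
        res2 = genome_tradeoff(
            list(reversed(pars_trimmed)), list(reversed(pars_profiles)), ecoli_table, rule
        )
        assert res1.delta_t == res2.delta_t
        assert res1.n_codons_high == res2.n_codons_high

    def test_codon_counts_bounded_by_genome(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        res = genome_tradeoff(pars_trimmed, pars_profiles, ecoli_table, rule)
        total = sum(g.n_codons for g in pars_trimmed)
        assert res.n_codons_high + res.n_codons_low <= total

    def test_subset_restricts_pools(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        ids = frozenset(g.id for g in pars_trimmed[:5])
        subset = GeneSubset(name="five", member_ids=ids)
        res_all = genome_tradeoff(pars_trimmed, pars_profiles, ecoli_table, rule)
        res_sub = genome_tradeoff(
            pars_trimmed, pars_profiles, ecoli_table, rule, subset=subset
        )
        assert res_sub.n_codons_high < res_all.n_codons_high

    def test_region_mean_pooling_switch(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        res = genome_tradeoff(
            pars_trimmed, pars_profiles, ecoli_table, rule, pooling="region_means"
        )
        assert res.defined and res.delta_t > 0
        assert res.n_codons_high < 1000  # region means, not codons


class TestUsageTables:
    def make_single_gene(self):
        cds = CodingSequence(id="g", seq="GCTGCTAAA" + "ACG" * 30)
        values = np.concatenate([np.ones(9), -np.ones(90)])
        profile = StructureProfile(
            gene_id="g", kind="pars", values=values, defined=np.ones(99, bool)
        )
        return cds, profile

    def test_direct_counts(self, ecoli_table):
        cds, profile = self.make_single_gene()
        rule = ThresholdRule.pars_default(9)
        high, low = codon_usage_by_region([cds], [profile], rule, ecoli_table)
        assert high.counts == {"GCT": 2, "AAA": 1}
        assert high.fractions["GCT"] == pytest.approx(2 / 3)

    def test_fractions_sum_to_one(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        high, low = codon_usage_by_region(
            pars_trimmed, pars_profiles, rule, ecoli_table
        )
        assert sum(high.fractions.values()) == pytest.approx(1.0)
        assert sum(low.fractions.values()) == pytest.approx(1.0)

    def test_by_aa_ordered_fastest_to_slowest(self, pars_trimmed, pars_profiles, ecoli_table):
        rule = ThresholdRule.pars_default(20)
        high, _ = codon_usage_by_region(pars_trimmed, pars_profiles, rule, ecoli_table)
        for aa, entries in high.by_aa.items():
            times = [ecoli_table[c] for c, _ in entries]
            assert times == sorted(times)

    def test_high_class_prefers_fast_codons(self, pars_trimmed, pars_profiles, ecoli_table):
        """The planted coupling shows up as codon-usage bias by class."""
        rule = ThresholdRule.pars_default(20)
        high, low = codon_usage_by_region(pars_trimmed, pars_profiles, rule, ecoli_table)
        mean_t = lambda tab: sum(
            ecoli_table[c] * f for c, f in tab.fractions.items()
        )
        assert mean_t(high) < mean_t(low)

    def test_aa_fractions_sum_to_one(self, pars_trimmed, pars_profiles):
        rule = ThresholdRule.pars_default(20)
        comp = aa_composition_by_region(pars_trimmed, pars_profiles, rule)
        for klass in ("high", "low"):
            assert sum(comp[klass].values()) == pytest.approx(1.0)

    def test_single_aa_gene(self):
        cds = CodingSequence(id="g", seq="GCA" * 20)
        profile = StructureProfile(
            gene_id="g", kind="pars", values=np.ones(60), defined=np.ones(60, bool)
        )
        comp = aa_composition_by_region([cds], [profile], ThresholdRule.pars_default(20))
        assert comp["high"] == {"A": 1.0}
        assert comp["low"] == {}
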