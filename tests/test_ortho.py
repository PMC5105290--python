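import numpy as np
import pytest

from oracles import naive_classify, naive_copy_number, naive_species_counts
from xylocomp.homology import HomologyPolicy
from xylocomp.ortho import (
    GeneCategory,
    OrthoTable,
    PartitionPolicy,
    SpeciesSetPartition,
    classify_genes,
    copy_number_split,
    og_span,
    summarize_partition,
)

from conftest import make_hit, random_og_table

POLICY = PartitionPolicy()


class TestOgSpan:
    def og(self, *pairs):
        return set(pairs)

    def test_two_species_in_each_set(self, tiny_partition):
        og = self.og(("S0", "a"), ("S1", "b"), ("S3", "c"), ("S4", "d"),
                     ("S6", "e"), ("S7", "f"))
        assert og_span(og, tiny_partition, POLICY) == "three_set"

    def test_set_below_threshold_does_not_count(self, tiny_partition):
        og = self.og(("S0", "a"), ("S1", "b"), ("S3", "c"))
        assert og_span(og, tiny_partition, POLICY) == "one_set"

    def test_single_species_og_is_unshared(self, tiny_partition):
        assert og_span(self.og(("S0", "a")), tiny_partition, POLICY) == "unshared"

    def test_empty_og_rejected(self, tiny_partition):
        with pytest.raises(ValueError):
            og_span(set(), tiny_partition, POLICY)

    def test_raising_threshold_never_adds_three_set_ogs(self, tiny_partition):
        rng = np.random.default_rng(11)
        for _ in range(50):
            table, *_ = random_og_table(rng, tiny_partition)
            n3 = [
                sum(
                    og_span(m, tiny_partition, PartitionPolicy(k)) == "three_set"
                    for m in table.ogs.values()
                )
                for k in (1, 2)
            ]
            assert n3[1] <= n3[0]


class TestClassifyGenes:
    def test_sole_member_in_shared_og_is_universal_single(self, tiny_partition):
        triples = [("OG1", sp, f"g_{sp}") for sp in ("S0", "S1", "S3", "S4", "S6", "S7")]
        table = OrthoTable(triples, species_universe=tiny_partition.universe)
        cats = classify_genes(table, tiny_partition, POLICY, [], [])
        assert all(c is GeneCategory.UNIVERSAL_SINGLE for c in cats.values())

    def test_homology_fallback_order(self, tiny_partition):
        table = OrthoTable([], species_universe=tiny_partition.universe)
        arth = [make_hit("g1", "EXT1", 1e-8)]
        selfh = [make_hit("g1", "g1b", 1e-20, "self"), make_hit("g2", "g2b", 1e-20, "self")]
        cats = classify_genes(
            table, tiny_partition, POLICY, arth, selfh,
            extra_genes={"g1": "S0", "g2": "S0", "g3": "S1"},
        )
        assert cats["g1"] is GeneCategory.ARTHROPOD_HOMOLOG  # both kinds -> arthropod first
        assert cats["g2"] is GeneCategory.SELF_HOMOLOG
        assert cats["g3"] is GeneCategory.UNIQUE

    def test_trivial_self_match_is_not_self_homology(self, tiny_partition):
        table = OrthoTable([], species_universe=tiny_partition.universe)
        selfh = [make_hit("g1", "g1", 1e-30, "self")]
        cats = classify_genes(
            table, tiny_partition, POLICY, [], selfh, extra_genes={"g1": "S0"}
        )
        assert cats["g1"] is GeneCategory.UNIQUE

    def test_insignificant_hits_ignored(self, tiny_partition):
        table = OrthoTable([], species_universe=tiny_partition.universe)
        arth = [make_hit("g1", "EXT1", 1e-5)]  # exactly at threshold: not significant
        cats = classify_genes(
            table, tiny_partition, POLICY, arth, [], extra_genes={"g1": "S0"}
        )
        assert cats["g1"] is GeneCategory.UNIQUE

    def test_agrees_with_naive_oracle_on_random_tables(self, tiny_partition):
        """Optimized classification equals nested-loop recount on 200 tables."""
        rng = np.random.default_rng(20240918)
        set_map = {sp: lab for lab, s in tiny_partition.sets.items() for sp in s}
        for _ in range(200):
            table, extra, arth, selfh, gene_species = random_og_table(rng, tiny_partition)
            cats = classify_genes(table, tiny_partition, POLICY, arth, selfh,
                                  extra_genes=extra)
            naive = naive_classify(
                table.triples(), set_map, POLICY.min_species_per_set,
                [(h.query_id, h.subject_id, h.evalue) for h in arth],
                [(h.query_id, h.subject_id, h.evalue) for h in selfh],
                extra,
            )
            assert {g: c.value for g, c in cats.items()} == naive

    def test_every_gene_gets_exactly_one_category(self, tiny_partition):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table, extra, arth, selfh, gene_species = random_og_table(rng, tiny_partition)
            cats = classify_genes(table, tiny_partition, POLICY, arth, selfh,
                                  extra_genes=extra)
            assert set(cats) == set(gene_species)


class TestSummaries:
    def test_per_species_counts_sum_to_gene_totals(self, tiny_partition):
        rng = np.random.default_rng(6)
        for _ in range(50):
            table, extra, arth, selfh, gene_species = random_og_table(rng, tiny_partition)
            cats = classify_genes(table, tiny_partition, POLICY, arth, selfh,
                                  extra_genes=extra)
            summary, spans = summarize_partition(cats, table, tiny_partition, POLICY,
                                                 extra_genes=extra)
            per_species_truth = {}
            for g, sp in gene_species.items():
                per_species_truth[sp] = per_species_truth.get(sp, 0) + 1
            for sp in summary.index:
                assert summary.loc[sp, "total"] == per_species_truth.get(sp, 0)
            assert spans.sum() == len(table.ogs)
            recount = naive_species_counts(
                {g: c.value for g, c in cats.items()}, gene_species
            )
            for (sp, cat), n in recount.items():
                assert summary.loc[sp, cat] == n

    def test_uncovered_gene_rejected(self, tiny_partition):
        table = OrthoTable([("OG1", "S0", "g1"), ("OG1", "S3", "g2")],
                           species_universe=tiny_partition.universe)
        with pytest.raises(ValueError, match="without a category"):
            summarize_partition({"g1": GeneCategory.TWO_SET}, table, tiny_partition)

    def test_empty_table_gives_zero_summary(self, tiny_partition):
        table = OrthoTable([], species_universe=tiny_partition.universe)
        summary, spans = summarize_partition({}, table, tiny_partition)
        assert summary["total"].sum() == 0
        assert spans.sum() == 0


class TestCopyNumberSplit:
    def shared_og(self, og_id, copies_per_species, tiny_partition):
        triples = []
        for sp in ("S0", "S1", "S3", "S4", "S6", "S7"):
            k = copies_per_species.get(sp, 1)
            triples += [(og_id, sp, f"{og_id}_{sp}_{i}") for i in range(k)]
        return triples

    def test_single_copy_counting(self, tiny_partition):
        triples = []
        for i in range(5):
            triples += self.shared_og(f"OG{i}", {}, tiny_partition)
        table = OrthoTable(triples, species_universe=tiny_partition.universe)
        split = copy_number_split(table, tiny_partition, POLICY)
        assert split.loc["S0", "single_copy"] == 5
        assert split.loc["S0", "multi_copy"] == 0

    def test_multi_copy_counts_genes_not_ogs(self, tiny_partition):
        triples = self.shared_og("OG0", {"S0": 3}, tiny_partition)
        table = OrthoTable(triples, species_universe=tiny_partition.universe)
        split = copy_number_split(table, tiny_partition, POLICY)
        assert split.loc["S0", "multi_copy"] == 3
        assert split.loc["S0", "single_copy"] == 0
        assert split.loc["S1", "single_copy"] == 1

    def test_agrees_with_naive_tally_on_random_tables(self, tiny_partition):
        rng = np.random.default_rng(8)
        set_map = {sp: lab for lab, s in tiny_partition.sets.items() for sp in s}
        for _ in range(50):
            table, *_ = random_og_table(rng, tiny_partition)
            split = copy_number_split(table, tiny_partition, POLICY)
            naive = naive_copy_number(table.triples(), set_map, POLICY.min_species_per_set)
            for sp, (single, multi) in naive.items():
                assert split.loc[sp, "single_copy"] == single
                assert split.loc[sp, "multi_copy"] == multi


def test_gene_in_two_ogs_rejected(tiny_partition):
    with pytest.raises(ValueError, match="belongs to both"):
        OrthoTable([("OG1", "S0", "g1"), ("OG2", "S0", "g1")])


def test_partition_requires_disjoint_sets():
    with pytest.raises(ValueError, match="disjoint"):
        SpeciesSetPartition(sets={
            "setA": frozenset({"S0"}), "setB": frozenset({"S0"}),
            "setC": frozenset({"S1"}),
        })
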