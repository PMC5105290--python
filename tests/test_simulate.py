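import numpy as np
import pandas as pd
import pytest

from xylocomp.ortho import GeneCategory, PartitionPolicy, classify_genes
from xylocomp.simulate import (
    CountSimConfig,
    FamilySimConfig,
    HgtSimConfig,
    default_partition,
    simulate_counts,
    simulate_domain_annotations,
    simulate_gene_families,
    simulate_hgt_genome,
)


class TestGeneFamilySimulator:
    def test_no_events_gives_universal_single_everywhere(self):
        r = simulate_gene_families(FamilySimConfig(n_families=40, dup_rate=0,
                                                   loss_rate=0, seed=1))
        assert len(r.table.genes()) == 40 * 15
        assert all(c is GeneCategory.UNIVERSAL_SINGLE for c in r.truth.values())

    def test_deterministic_under_fixed_seed(self):
        a = simulate_gene_families(FamilySimConfig(n_families=30, dup_rate=0.3,
                                                   loss_rate=0.5, seed=9))
        b = simulate_gene_families(FamilySimConfig(n_families=30, dup_rate=0.3,
                                                   loss_rate=0.5, seed=9))
        assert a.table.triples() == b.table.triples()
        assert a.truth == b.truth

    def test_high_loss_produces_lineage_restricted_families(self):
        r = simulate_gene_families(FamilySimConfig(n_families=400, dup_rate=0.2,
                                                   loss_rate=1.5, seed=3))
        cats = set(r.truth.values())
        assert GeneCategory.SET_RESTRICTED_ORTHOLOG in cats
        assert GeneCategory.TWO_SET in cats

    def test_truth_spans_verified_by_direct_presence_inspection(self):
        r = simulate_gene_families(FamilySimConfig(n_families=200, dup_rate=0.2,
                                                   loss_rate=1.0, seed=7))
        partition = default_partition()
        for og_id, members in r.table.ogs.items():
            counting = sum(
                1 for label in partition.labels
                if len({sp for sp, _ in members
                        if sp in partition.sets[label]}) >= 2
            )
            genes = [g for _, g in members]
            truth_cats = {r.truth[g] for g in genes}
            if counting == 3:
                assert truth_cats <= {GeneCategory.UNIVERSAL_SINGLE,
                                      GeneCategory.UNIVERSAL_MULTI}
            elif counting == 2:
                assert truth_cats == {GeneCategory.TWO_SET}
            elif counting == 1:
                assert truth_cats == {GeneCategory.SET_RESTRICTED_ORTHOLOG}

    def test_closed_loop_consistency_with_classifier(self):
        """Simulator truth equals classifier output given perfect hit files."""
        for lam, mu, seed in [(0.0, 0.0, 1), (0.3, 1.2, 2), (0.5, 2.0, 3)]:
            r = simulate_gene_families(FamilySimConfig(n_families=300, dup_rate=lam,
                                                       loss_rate=mu, seed=seed))
            cats = classify_genes(
                r.table, r.partition, PartitionPolicy(), r.arthropod_hits,
                r.self_hits, extra_genes=r.fallback_genes,
            )
            assert cats == r.truth


class TestHgtSimulator:
    def test_zero_divergence_copies_are_identical(self):
        cfg = HgtSimConfig(host_length=30_000, n_insertions=3, insertion_length=500,
                           divergence=0.0, seed=2)
        r = simulate_hgt_genome(cfg)
        assert (r.truth["identity"] == 100.0).all()
        sources = {s.id: s.seq for s in r.bacterial_db}
        for row in r.truth.itertuples():
            assert r.host.seq[row.start:row.end] == sources[row.source_id]

    def test_realized_identity_close_to_expectation(self):
        cfg = HgtSimConfig(host_length=100_000, n_insertions=10,
                           insertion_length=2000, divergence=0.05, seed=4)
        r = simulate_hgt_genome(cfg)
        assert r.truth["identity"].mean() == pytest.approx(95.0, abs=1.0)

    def test_indels_recorded_in_truth(self):
        cfg = HgtSimConfig(host_length=60_000, n_insertions=5, insertion_length=1000,
                           divergence=0.3, indel_rate=0.01, seed=5)
        r = simulate_hgt_genome(cfg)
        assert (r.truth["indel_events"] >= 1).all()

    def test_junction_evidence_in_every_library_at_both_boundaries(self):
        cfg = HgtSimConfig(host_length=40_000, n_insertions=4, insertion_length=500,
                           n_libraries=3, seed=6)
        r = simulate_hgt_genome(cfg)
        for row in r.truth.itertuples():
            for boundary in (row.start, row.end):
                libs = {ev.library_id for ev in r.junctions if ev.position == boundary}
                assert libs == {"LIB01", "LIB02", "LIB03"}

    def test_deterministic_under_fixed_seed(self):
        cfg = HgtSimConfig(host_length=30_000, n_insertions=3, insertion_length=400, seed=8)
        assert simulate_hgt_genome(cfg).host.seq == simulate_hgt_genome(cfg).host.seq

    def test_insertions_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            HgtSimConfig(host_length=1000, n_insertions=5, insertion_length=300)


class TestDomainSimulator:
    def test_planted_cells_set_exactly(self):
        anns, truth = simulate_domain_annotations(
            ["A", "B"], 5, planted=[("IPR000001", "A", 9)], background_max=2, seed=1
        )
        count = len({a.gene_id for a in anns
                     if a.domain_acc == "IPR000001" and a.species_id == "A"})
        assert count == 9
        assert truth == [("IPR000001", "A", 9)]

    def test_background_bounded(self):
        anns, _ = simulate_domain_annotations(["A", "B"], 10, background_max=2, seed=2)
        counts = pd.DataFrame([(a.domain_acc, a.species_id) for a in anns],
                              columns=["d", "s"]).value_counts()
        assert counts.max() <= 2

    def test_unknown_planted_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            simulate_domain_annotations(["A"], 3, planted=[("IPR000001", "B", 9)])

    def test_planted_count_must_exceed_background(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_domain_annotations(["A"], 3, planted=[("IPR000001", "A", 2)],
                                        background_max=2)

    def test_deterministic_under_fixed_seed(self):
        a, _ = simulate_domain_annotations(["A", "B"], 10, background_max=3, seed=3)
        b, _ = simulate_domain_annotations(["A", "B"], 10, background_max=3, seed=3)
        assert a == b


class TestCountSimulator:
    def test_null_config_labels_nothing(self):
        m, truth = simulate_counts(CountSimConfig(n_genes=50, seed=1))
        assert not any(truth.values())
        assert m.counts.shape == (50, 8)

    def test_zero_dispersion_degenerates_to_poisson(self):
        # moment check over >= 1e4 draws: variance approx mean
        cfg = CountSimConfig(n_genes=2000, n_reps=5, baseline_mean=50,
                             dispersion=0.0, seed=2)
        m, _ = simulate_counts(cfg)
        draws = m.counts.to_numpy().ravel()
        assert draws.mean() == pytest.approx(50, rel=0.02)
        assert draws.var() == pytest.approx(50, rel=0.05)

    def test_nb_variance_exceeds_poisson(self):
        cfg = CountSimConfig(n_genes=2000, n_reps=5, baseline_mean=50,
                             dispersion=0.2, seed=3)
        m, _ = simulate_counts(cfg)
        draws = m.counts.to_numpy().ravel()
        # var = mu + phi*mu^2 = 50 + 500 = 550
        assert draws.var() == pytest.approx(550, rel=0.1)

    def test_true_logfc_shifts_condition_means(self):
        lfc = np.full(500, 2.0)
        m, truth = simulate_counts(
            CountSimConfig(n_genes=500, baseline_mean=100, dispersion=0.05,
                           true_logfc=lfc, seed=4)
        )
        t = m.condition_totals("treatment").mean()
        c = m.condition_totals("control").mean()
        assert np.log2(t / c) == pytest.approx(2.0, abs=0.1)
        assert all(truth.values())

    def test_deterministic_under_fixed_seed(self):
        a, _ = simulate_counts(CountSimConfig(n_genes=20, seed=5))
        b, _ = simulate_counts(CountSimConfig(n_genes=20, seed=5))
        assert a.counts.equals(b.counts)
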