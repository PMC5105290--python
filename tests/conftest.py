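import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from xylocomp.io_formats import HomologyHit
from xylocomp.ortho import OrthoTable, PartitionPolicy, SpeciesSetPartition


@pytest.fixture
def tiny_partition() -> SpeciesSetPartition:
    """Eight species across three sets (3/3/2), for randomized tables."""
    return SpeciesSetPartition(
        sets={
            "setA": frozenset({"S0", "S1", "S2"}),
            "setB": frozenset({"S3", "S4", "S5"}),
            "setC": frozenset({"S6", "S7"}),
        },
    )


def make_hit(query: str, subject: str, evalue: float, subject_db: str = "arthropod",
             bit: float = 100.0) -> HomologyHit:
    return HomologyHit(
        query_id=query, subject_id=subject, pct_identity=90.0, aln_length=100,
        mismatches=10, gap_openings=0, q_start=1, q_end=100, s_start=1,
        s_end=100, evalue=evalue, bit_score=bit, subject_db=subject_db,
    )


def random_og_table(rng: np.random.Generator, partition: SpeciesSetPartition):
    """A random OG table plus random homology fallbacks over the partition.

    Returns (table, extra_genes, arthropod_hits, self_hits, gene_species).
    """
    species = sorted(partition.universe)
    n_ogs = int(rng.integers(1, 51))
    triples = []
    gene_idx = 0
    for og_i in range(n_ogs):
        og_id = f"OG{og_i:03d}"
        any_member = False
        for sp in species:
            if rng.random() < 0.45:
                for _ in range(int(rng.integers(1, 4))):
                    gene_idx += 1
                    triples.append((og_id, sp, f"g{gene_idx:05d}"))
                    any_member = True
        if not any_member:  # OGs are non-empty by construction
            gene_idx += 1
            triples.append((og_id, species[int(rng.integers(len(species)))],
                            f"g{gene_idx:05d}"))
    extra_genes = {}
    for _ in range(int(rng.integers(0, 20))):
        gene_idx += 1
        extra_genes[f"g{gene_idx:05d}"] = species[int(rng.integers(len(species)))]

    all_genes = [g for _, _, g in triples] + list(extra_genes)
    arth_hits, self_hits = [], []
    for g in all_genes:
        if rng.random() < 0.3:
            evalue = 10.0 ** rng.uniform(-12, 0)
            arth_hits.append(make_hit(g, "EXT_" + g, evalue, "arthropod"))
        if rng.random() < 0.3:
            evalue = 10.0 ** rng.uniform(-12, 0)
            subject = g if rng.random() < 0.2 else "PARA_" + g  # sometimes trivial self-match
            self_hits.append(make_hit(g, subject, evalue, "self"))

    table = OrthoTable(triples, species_universe=partition.universe)
    gene_species = dict(table.gene_species)
    gene_species.update(extra_genes)
    return table, extra_genes, arth_hits, self_hits, gene_species
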