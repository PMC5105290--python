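"""Three-set orthologous-group classification.

Fifteen species are partitioned into three sets of five (Coleoptera;
Lepidoptera/Diptera; outgroup insects).  An OG "counts" in a set when it
contains genes from at least ``min_species_per_set`` (default 2) distinct
species of that set; its span is the number of counting sets.  Genes in
three-set OGs are universal orthologs (single- or multi-copy per species),
genes in two- and one-set OGs are lineage-restricted orthologs, and genes
without (counting) orthologs fall back to homology evidence: significant
homology to other arthropod genes, self-only homology within their own
genome, or no significant homology at all (unique).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .homology import HomologyPolicy, is_significant
from .io_formats import HomologyHit


class GeneCategory(enum.Enum):
    """Mutually exclusive, exhaustive conservation categories for a gene."""

    UNIVERSAL_SINGLE = "universal_single"
    UNIVERSAL_MULTI = "universal_multi"
    WIDESPREAD = "widespread"  # derived super-class, never assigned per-gene
    TWO_SET = "two_set"
    SET_RESTRICTED_ORTHOLOG = "set_restricted_ortholog"
    ARTHROPOD_HOMOLOG = "arthropod_homolog"
    SELF_HOMOLOG = "self_homolog"
    UNIQUE = "unique"


#: categories classify_genes can actually assign (WIDESPREAD is derived)
ASSIGNABLE_CATEGORIES = [
    c for c in GeneCategory if c is not GeneCategory.WIDESPREAD
]

SPAN_LABELS = ("three_set", "two_set", "one_set", "unshared")


class OrthoTable:
    """Gene <-> species <-> OG membership with each gene in at most one OG."""

    def __init__(
        self,
        memberships: Iterable[tuple[str, str, str]],
        species_universe: Optional[set[str]] = None,
        gene_lengths: Optional[Mapping[str, int]] = None,
    ) -> None:
        self._triples = sorted(set(memberships))
        gene_og: dict[str, str] = {}
        for og, sp, gene in self._triples:
            if gene in gene_og and gene_og[gene] != og:
                raise ValueError(
                    f"gene {gene!r} belongs to both OG {gene_og[gene]!r} and {og!r}"
                )
            gene_og[gene] = og
        self.gene_og = gene_og
        seen_species = {sp for _, sp, _ in self._triples}
        self.species_universe = set(species_universe) if species_universe else seen_species
        extra = seen_species - self.species_universe
        if extra:
            raise ValueError(f"species {sorted(extra)} not in species universe")
        self.gene_lengths = dict(gene_lengths) if gene_lengths else None
        self.gene_species = {gene: sp for _, sp, gene in self._triples}
        ogs: dict[str, set[tuple[str, str]]] = defaultdict(set)
        for og, sp, gene in self._triples:
            ogs[og].add((sp, gene))
        self.ogs: dict[str, set[tuple[str, str]]] = dict(ogs)

    @classmethod
    def from_triples(cls, triples, **kw) -> "OrthoTable":
        return cls(triples, **kw)

    def triples(self) -> list[tuple[str, str, str]]:
        return list(self._triples)

    def genes(self) -> list[str]:
        return sorted(self.gene_og)

    def __len__(self) -> int:
        return len(self._triples)


@dataclass(frozen=True)
class SpeciesSetPartition:
    """Disjoint species sets whose union is the species universe."""

    sets: Mapping[str, frozenset[str]]
    labels: tuple[str, ...] = ("setA", "setB", "setC")

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.sets):
            raise ValueError("partition labels do not match set keys")
        all_species: list[str] = []
        for label in self.labels:
            all_species.extend(self.sets[label])
        if len(all_species) != len(set(all_species)):
            raise ValueError("species sets are not disjoint")

    @property
    def universe(self) -> set[str]:
        return {sp for s in self.sets.values() for sp in s}

    def set_of(self, species: str) -> Optional[str]:
        for label in self.labels:
            if species in self.sets[label]:
                return label
        return None

    def smallest_set_size(self) -> int:
        return min(len(s) for s in self.sets.values())


@dataclass(frozen=True)
class PartitionPolicy:
    """Membership threshold: a set counts with >= this many distinct species."""

    min_species_per_set: int = 2

    def __post_init__(self) -> None:
        if self.min_species_per_set < 1:
            raise ValueError("min_species_per_set must be >= 1")

    def validate_against(self, partition: SpeciesSetPartition) -> None:
        if self.min_species_per_set > partition.smallest_set_size():
            raise ValueError(
                "min_species_per_set exceeds the smallest species set"
            )


def og_span(
    og: set[tuple[str, str]],
    partition: SpeciesSetPartition,
    policy: PartitionPolicy = PartitionPolicy(),
) -> str:
    """Span label of one OG: three_set / two_set / one_set / unshared.

    A set counts iff the OG contains genes from at least
    ``policy.min_species_per_set`` distinct species of that set.
    """
    if not og:
        raise ValueError("og_span of an empty OG")
    policy.validate_against(partition)
    species_per_set: dict[str, set[str]] = {label: set() for label in partition.labels}
    for sp, _gene in og:
        label = partition.set_of(sp)
        if label is None:
            raise ValueError(f"species {sp!r} not in any partition set")
        species_per_set[label].add(sp)
    counting = sum(
        1 for label in partition.labels
        if len(species_per_set[label]) >= policy.min_species_per_set
    )
    return {3: "three_set", 2: "two_set", 1: "one_set", 0: "unshared"}[counting]


def _has_significant_nonself(
    hits: Sequence[HomologyHit], gene: str, policy: HomologyPolicy
) -> bool:
    return any(
        h.subject_id != gene and is_significant(h, policy) for h in hits
    )


def classify_genes(
    table: OrthoTable,
    partition: SpeciesSetPartition,
    policy: PartitionPolicy,
    arthropod_hits: Sequence[HomologyHit],
    self_hits: Sequence[HomologyHit],
    hpolicy: HomologyPolicy = HomologyPolicy(),
    extra_genes: Optional[Mapping[str, str]] = None,
) -> dict[str, GeneCategory]:
    """Assign every gene exactly one conservation category.

    Genes in three-set OGs are universal_single when their species has one
    gene in the OG, else universal_multi; two- and one-set OGs give two_set
    and set_restricted_ortholog.  Genes with no OG, or in OGs where no set
    reaches the membership threshold, fall through to the homology evidence:
    arthropod_homolog before self_homolog (a gene with both is
    arthropod_homolog), and unique when nothing significant remains.  A
    gene's trivial hit to itself never counts as self homology.

    ``extra_genes`` maps OG-less gene ids to their species so they can be
    classified and summarized; hit queries absent from both the table and
    ``extra_genes`` are ignored.
    """
    policy.validate_against(partition)
    arth_by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in arthropod_hits:
        arth_by_query[h.query_id].append(h)
    self_by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in self_hits:
        self_by_query[h.query_id].append(h)

    categories: dict[str, GeneCategory] = {}

    def fallback(gene: str) -> GeneCategory:
        if _has_significant_nonself(arth_by_query.get(gene, ()), gene, hpolicy):
            return GeneCategory.ARTHROPOD_HOMOLOG
        if _has_significant_nonself(self_by_query.get(gene, ()), gene, hpolicy):
            return GeneCategory.SELF_HOMOLOG
        return GeneCategory.UNIQUE

    for og_id, members in table.ogs.items():
        span = og_span(members, partition, policy)
        per_species_count: dict[str, int] = defaultdict(int)
        for sp, _g in members:
            per_species_count[sp] += 1
        for sp, gene in members:
            if span == "three_set":
                categories[gene] = (
                    GeneCategory.UNIVERSAL_SINGLE
                    if per_species_count[sp] == 1
                    else GeneCategory.UNIVERSAL_MULTI
                )
            elif span == "two_set":
                categories[gene] = GeneCategory.TWO_SET
            elif span == "one_set":
                categories[gene] = GeneCategory.SET_RESTRICTED_ORTHOLOG
            else:  # unshared: below threshold everywhere -> homology fallbacks
                categories[gene] = fallback(gene)

    for gene in (extra_genes or {}):
        if gene not in categories:
            categories[gene] = fallback(gene)
    return categories


def summarize_partition(
    categories: Mapping[str, GeneCategory],
    table: OrthoTable,
    partition: SpeciesSetPartition,
    policy: PartitionPolicy = PartitionPolicy(),
    extra_genes: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-species category counts and OG-level span counts.

    The per-species table has one column per assignable category plus the
    derived ``widespread`` super-class (universal_single + universal_multi:
    genes in OGs spanning all three sets) and a ``total`` column.  Row totals
    equal each species' gene count; span counts sum to the OG count.
    """
    gene_species = dict(table.gene_species)
    if extra_genes:
        gene_species.update(extra_genes)
    uncovered = set(gene_species) - set(categories)
    if uncovered:
        raise ValueError(f"genes without a category: {sorted(uncovered)[:5]}")

    species = sorted(partition.universe)
    counts = pd.DataFrame(
        0, index=species, columns=[c.value for c in ASSIGNABLE_CATEGORIES]
    )
    for gene, cat in categories.items():
        sp = gene_species.get(gene)
        if sp is None:
            raise ValueError(f"gene {gene!r} has no species attribution")
        counts.loc[sp, cat.value] += 1
    counts["widespread"] = (
        counts["universal_single"] + counts["universal_multi"]
    )
    counts["total"] = counts[[c.value for c in ASSIGNABLE_CATEGORIES]].sum(axis=1)

    span_counts = pd.Series(0, index=list(SPAN_LABELS))
    for members in table.ogs.values():
        span_counts[og_span(members, partition, policy)] += 1
    return counts, span_counts


def copy_number_split(
    table: OrthoTable,
    partition: SpeciesSetPartition,
    policy: PartitionPolicy = PartitionPolicy(),
) -> pd.DataFrame:
    """Per-species gene counts of single- vs multi-copy orthologs over
    three-set (shared) OGs.

    For each species and each shared OG containing it, the species' per-OG
    gene count goes to ``single_copy`` if it is 1, otherwise all of it to
    ``multi_copy``; the result counts genes, not OGs.
    """
    species = sorted(partition.universe)
    out = pd.DataFrame(0, index=species, columns=["single_copy", "multi_copy"])
    for members in table.ogs.values():
        if og_span(members, partition, policy) != "three_set":
            continue
        per_species: dict[str, int] = defaultdict(int)
        for sp, _g in members:
            per_species[sp] += 1
        for sp, k in per_species.items():
            if k == 1:
                out.loc[sp, "single_copy"] += 1
            else:
                out.loc[sp, "multi_copy"] += k
    return out
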