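"""Cross-species domain-count comparative analysis.

Gene families (InterPro-style domain accessions) are counted per species at
the gene level -- a gene with repeated matches to the same domain counts
once.  A family is flagged as a potential expansion when its maximum count
in any single species is strictly greater than a threshold (default 5), the
flagged genes are partitioned by orthology status (single-copy ortholog,
multi-copy ortholog, or homology only), and a focal species' count can be
compared with the mean of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import FormatError
from .ortho import OrthoTable, PartitionPolicy, SpeciesSetPartition


@dataclass(frozen=True)
class DomainAnnotation:
    """One gene <-> domain accession assignment for one species."""

    gene_id: str
    species_id: str
    domain_acc: str
    domain_name: str = ""


@dataclass(frozen=True)
class ExpansionPolicy:
    """Flag a domain when some species' gene count exceeds this (strict >)."""

    min_max_count: int = 5

    def __post_init__(self) -> None:
        if self.min_max_count < 1:
            raise ValueError("min_max_count must be >= 1")


class DomainCountMatrix:
    """Domain accession x species gene-count table with fixed species order."""

    def __init__(self, counts: pd.DataFrame, species: Sequence[str]) -> None:
        self.species = list(species)
        self.counts = counts.reindex(columns=self.species, fill_value=0).astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("negative domain counts")

    def count(self, domain_acc: str, species_id: str) -> int:
        if domain_acc not in self.counts.index:
            return 0
        return int(self.counts.loc[domain_acc, species_id])

    def __eq__(self, other) -> bool:
        return isinstance(other, DomainCountMatrix) and self.counts.sort_index().equals(
            other.counts.sort_index().reindex(columns=self.counts.columns)
        )


def build_count_matrix(
    annotations: Sequence[DomainAnnotation], species: Sequence[str]
) -> DomainCountMatrix:
    """Count genes per (domain, species), deduplicating repeat matches.

    Absent cells are 0; an annotation for a species outside ``species`` is an
    error.
    """
    known = set(species)
    for ann in annotations:
        if ann.species_id not in known:
            raise ValueError(
                f"annotation species {ann.species_id!r} not in the species list"
            )
    pairs = {(a.domain_acc, a.species_id, a.gene_id) for a in annotations}
    if pairs:
        df = pd.DataFrame(list(pairs), columns=["domain_acc", "species_id", "gene_id"])
        counts = (
            df.groupby(["domain_acc", "species_id"])["gene_id"]
            .nunique()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(columns=list(species), dtype=int)
    return DomainCountMatrix(counts, species)


def flag_expansions(
    matrix: DomainCountMatrix, policy: ExpansionPolicy = ExpansionPolicy()
) -> list[tuple[str, tuple[str, ...], int]]:
    """Domains whose maximum per-species count is strictly > the threshold.

    Returns (domain_acc, arg-max species -- all of them on ties, max count),
    invariant under species reordering.
    """
    out: list[tuple[str, tuple[str, ...], int]] = []
    for domain_acc, row in matrix.counts.iterrows():
        max_count = int(row.max()) if len(row) else 0
        if max_count > policy.min_max_count:
            argmax = tuple(sorted(sp for sp in matrix.species if row[sp] == max_count))
            out.append((str(domain_acc), argmax, max_count))
    return sorted(out)


def orthology_status_partition(
    domain_acc: str,
    annotations: Sequence[DomainAnnotation],
    table: OrthoTable,
    partition: Optional[SpeciesSetPartition] = None,
    policy: PartitionPolicy = PartitionPolicy(),
) -> pd.DataFrame:
    """Partition each species' domain-matched genes by orthology status.

    Every gene lands in exactly one of: ``single_copy`` (sole gene of its
    species in its OG), ``multi_copy`` (its OG holds >1 gene of that
    species), or ``homology_only`` (matched the domain but is in no OG); the
    three bins sum to the species' domain count.
    """
    matched = {
        (a.species_id, a.gene_id) for a in annotations if a.domain_acc == domain_acc
    }
    og_species_count: dict[tuple[str, str], int] = {}
    for og_id, members in table.ogs.items():
        for sp, _g in members:
            og_species_count[(og_id, sp)] = og_species_count.get((og_id, sp), 0) + 1
    species = sorted({sp for sp, _ in matched})
    out = pd.DataFrame(
        0, index=species, columns=["single_copy", "multi_copy", "homology_only"]
    )
    for sp, gene in matched:
        og = table.gene_og.get(gene)
        if og is None:
            out.loc[sp, "homology_only"] += 1
        elif og_species_count[(og, sp)] == 1:
            out.loc[sp, "single_copy"] += 1
        else:
            out.loc[sp, "multi_copy"] += 1
    return out


def enrichment_vs_mean(
    matrix: DomainCountMatrix,
    domain_accs: str | Sequence[str],
    focal_species: str,
) -> float:
    """Focal-species count over the mean count of all other species.

    ``domain_accs`` may be a single accession or a group of accessions summed
    before the ratio (subfamily groupings).  Returns inf when the non-focal
    mean is 0 with a positive focal count, and NaN (undefined) for 0/0.
    """
    if isinstance(domain_accs, str):
        domain_accs = [domain_accs]
    others = [sp for sp in matrix.species if sp != focal_species]
    if not others:
        raise ValueError("enrichment needs at least one non-focal species")
    focal = sum(matrix.count(acc, focal_species) for acc in domain_accs)
    other_mean = sum(
        matrix.count(acc, sp) for acc in domain_accs for sp in others
    ) / len(others)
    if other_mean == 0:
        return math.inf if focal > 0 else math.nan
    return focal / other_mean


# ---------------------------------------------------------------------------
# I/O and plotting

ANNOTATION_COLUMNS = ("gene_id", "species_id", "domain_acc", "domain_name")


def read_annotations(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ANNOTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "domain_name" not in df.columns:
        df["domain_name"] = ""
    return [
        DomainAnnotation(r.gene_id, r.species_id, r.domain_acc, r.domain_name)
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.species_id}\t{a.domain_acc}\t{a.domain_name}\n")


def write_count_matrix(matrix: DomainCountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("domain_acc").to_csv(path, sep="\t")


def write_expansion_report(
    flagged: Sequence[tuple[str, tuple[str, ...], int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("domain_acc\tmax_species\tmax_count\n")
        for acc, species, count in flagged:
            fh.write(f"{acc}\t{','.join(species)}\t{count}\n")


def plot_family_stacked_bars(
    matrix: DomainCountMatrix,
    domain_accs: Sequence[str],
    path: str | Path,
    title: str = "",
) -> None:
    """Stacked per-species bar chart of subfamily counts, largest subfamily
    at the bottom and smallest at the top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = {acc: sum(matrix.count(acc, sp) for sp in matrix.species) for acc in domain_accs}
    ordered = sorted(domain_accs, key=lambda a: -totals[a])
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(matrix.species)), 4))
    bottom = [0.0] * len(matrix.species)
    for acc in ordered:
        vals = [matrix.count(acc, sp) for sp in matrix.species]
        ax.bar(matrix.species, vals, bottom=bottom, label=acc)
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("gene count")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    plt.setp(ax.get_xticklabels(), rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
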