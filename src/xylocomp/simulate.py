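"""Simulators that generate every pipeline input with known ground truth.

Each simulator is a pure function of its config (including the seed):
identical configs give bitwise-identical outputs.  The fixtures emulate the
study conditions of the analyses -- a 15-species, three-sets-of-five
phylogeny for gene-family duplication/loss, host genomes carrying diverged
bacterial insertions with junction-spanning read-pair evidence across
sequencing libraries, per-species domain annotations with planted
expansions, and negative-binomial count matrices with four replicates per
feeding condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .expression import CountMatrix
from .domains import DomainAnnotation
from .hgt import JunctionEvidence
from .io_formats import GeneModel, HomologyHit, SequenceRecord
from .ortho import GeneCategory, OrthoTable, SpeciesSetPartition

#: 15-tip species tree, three clades of five (Coleoptera; Lepidoptera +
#: Diptera; outgroup insects), tip names following the 5-letter species codes
#: used in cross-species genome comparisons.
DEFAULT_TREE = (
    "((((AGLAB:0.25,DPOND:0.25):0.15,(TCAST:0.3,(OTAUR:0.25,APLAN:0.25):0.05):0.1):0.3,"
    "((PXYLO:0.2,DPLEX:0.2):0.2,(DMELA:0.25,(AGAMB:0.2,MDEST:0.2):0.05):0.15):0.3):0.1,"
    "((ZNEVA:0.3,PHUMA:0.3):0.1,(APISU:0.3,(AMELL:0.25,NVITR:0.25):0.05):0.1):0.4);"
)

COLEOPTERA = ("AGLAB", "DPOND", "TCAST", "OTAUR", "APLAN")
LEP_DIP = ("PXYLO", "DPLEX", "DMELA", "AGAMB", "MDEST")
OUTGROUP = ("ZNEVA", "PHUMA", "APISU", "AMELL", "NVITR")

_BASES = np.array(list("ACGT"))


def default_partition() -> SpeciesSetPartition:
    """The study's three-sets-of-five species partition."""
    return SpeciesSetPartition(
        sets={
            "coleoptera": frozenset(COLEOPTERA),
            "lep_dip": frozenset(LEP_DIP),
            "outgroup": frozenset(OUTGROUP),
        },
        labels=("coleoptera", "lep_dip", "outgroup"),
    )


# ---------------------------------------------------------------------------
# Gene-family duplication/loss on a species tree


@dataclass(frozen=True)
class FamilySimConfig:
    """Birth-death gene-family simulation along a fixed species tree.

    Along each branch of length t, every extant copy is independently lost
    with probability 1 - exp(-loss_rate * t) and, if it survives, duplicates
    with probability 1 - exp(-dup_rate * t).
    """

    tree: str = DEFAULT_TREE
    n_families: int = 100
    dup_rate: float = 0.1
    loss_rate: float = 0.1
    seed: int = 0
    partition: Optional[SpeciesSetPartition] = None
    min_species_per_set: int = 2

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class FamilySimResult:
    table: OrthoTable
    truth: dict[str, GeneCategory]
    gene_species: dict[str, str]  # every simulated gene, OG or not
    fallback_genes: dict[str, str]  # genes absent from the OG table
    arthropod_hits: list[HomologyHit]
    self_hits: list[HomologyHit]
    partition: SpeciesSetPartition


def _perfect_hit(query: str, subject: str, db: str) -> HomologyHit:
    return HomologyHit(
        query_id=query, subject_id=subject, pct_identity=90.0, aln_length=100,
        mismatches=10, gap_openings=0, q_start=1, q_end=100, s_start=1,
        s_end=100, evalue=1e-30, bit_score=200.0, subject_db=db,
    )


def simulate_gene_families(config: FamilySimConfig) -> FamilySimResult:
    """Simulate OG membership by duplication/loss on the species tree.

    Each family starts with one copy at the root; surviving leaf copies
    become genes.  Families with genes from at least two species enter the
    OG table (one OG per family); single-species families and singletons
    rely on the homology fallbacks, for which perfect hit files (every pair
    of same-family genes hits at E=1e-30) are emitted.

    Truth labels are computed directly from the realized per-species
    presence counts -- three-set families give universal_single/multi,
    two-set and one-set families the lineage-restricted ortholog categories,
    and everything else falls to arthropod/self homology or unique --
    independently of the classifier under test.
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    partition = config.partition or default_partition()
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != partition.universe:
        raise ValueError("tree tips do not match the species partition universe")

    triples: list[tuple[str, str, str]] = []
    truth: dict[str, GeneCategory] = {}
    gene_species: dict[str, str] = {}
    fallback_genes: dict[str, str] = {}
    arthropod_hits: list[HomologyHit] = []
    self_hits: list[HomologyHit] = []

    set_of = {sp: label for label, s in partition.sets.items() for sp in s}

    for fam_idx in range(config.n_families):
        fam_id = f"OG{fam_idx:05d}"
        # copies per node, simulated along the tree
        copies_at = {tree.seed_node: 1}
        leaf_counts: dict[str, int] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            t = node.edge.length or 0.0
            p_loss = 1.0 - np.exp(-config.loss_rate * t)
            p_dup = 1.0 - np.exp(-config.dup_rate * t)
            n_in = copies_at[node.parent_node]
            survivors = int(rng.binomial(n_in, 1.0 - p_loss)) if n_in else 0
            duplicated = int(rng.binomial(survivors, p_dup)) if survivors else 0
            copies_at[node] = survivors + duplicated
            if node.is_leaf() and copies_at[node] > 0:
                leaf_counts[node.taxon.label] = copies_at[node]

        if not leaf_counts:
            continue  # family extinct

        genes = {
            sp: [f"{fam_id}_{sp}_{i + 1}" for i in range(k)]
            for sp, k in leaf_counts.items()
        }
        all_genes = [(sp, g) for sp, gl in genes.items() for g in gl]
        for sp, g in all_genes:
            gene_species[g] = sp

        # realized span, by definition from presence counts
        species_per_set: dict[str, set[str]] = {lab: set() for lab in partition.labels}
        for sp in leaf_counts:
            species_per_set[set_of[sp]].add(sp)
        counting = sum(
            1 for lab in partition.labels
            if len(species_per_set[lab]) >= config.min_species_per_set
        )

        in_table = len(leaf_counts) >= 2
        if in_table:
            triples.extend((fam_id, sp, g) for sp, g in all_genes)
        else:
            for _sp, g in all_genes:
                fallback_genes[g] = _sp

        if counting == 3:
            for sp, g in all_genes:
                truth[g] = (
                    GeneCategory.UNIVERSAL_SINGLE
                    if leaf_counts[sp] == 1
                    else GeneCategory.UNIVERSAL_MULTI
                )
        elif counting == 2:
            for _sp, g in all_genes:
                truth[g] = GeneCategory.TWO_SET
        elif counting == 1:
            for _sp, g in all_genes:
                truth[g] = GeneCategory.SET_RESTRICTED_ORTHOLOG
        else:
            # no counting set: homology fallbacks decide
            for sp, g in all_genes:
                cross = any(osp != sp for osp, _og in all_genes)
                paralog = any(osp == sp and og != g for osp, og in all_genes)
                if cross:
                    truth[g] = GeneCategory.ARTHROPOD_HOMOLOG
                elif paralog:
                    truth[g] = GeneCategory.SELF_HOMOLOG
                else:
                    truth[g] = GeneCategory.UNIQUE

        # perfect hit files for genes that may consult the fallbacks
        if counting == 0:
            for sp, g in all_genes:
                for osp, og in all_genes:
                    if og == g:
                        continue
                    if osp != sp:
                        arthropod_hits.append(_perfect_hit(g, og, "arthropod"))
                    else:
                        self_hits.append(_perfect_hit(g, og, "self"))

    table = OrthoTable(triples, species_universe=partition.universe)
    return FamilySimResult(
        table=table, truth=truth, gene_species=gene_species,
        fallback_genes=fallback_genes, arthropod_hits=arthropod_hits,
        self_hits=self_hits, partition=partition,
    )


# ---------------------------------------------------------------------------
# Host genome with planted bacterial insertions


@dataclass(frozen=True)
class HgtSimConfig:
    """Planted-insertion genome simulation.

    ``divergence`` is the per-site substitution probability applied to each
    inserted copy of its bacterial source; ``indel_rate`` is the per-site
    probability of an indel event (single-base by default, geometric lengths
    with ``indel_extend`` > 0).  Decoy conserved genes are host segments
    copied into the animal database nearly verbatim and into the bacterial
    database at higher divergence, so their animal hit out-scores the
    bacterial one.
    """

    host_length: int = 200_000
    n_insertions: int = 10
    insertion_length: int = 2_000
    divergence: float = 0.05
    indel_rate: float = 0.0
    n_libraries: int = 3
    n_decoys: int = 5
    decoy_length: int = 400
    decoy_bacterial_divergence: float = 0.15
    decoy_animal_divergence: float = 0.01
    indel_extend: float = 0.0  # geometric continuation prob for indel lengths
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.n_insertions * self.insertion_length >= self.host_length:
            raise ValueError("insertions do not fit inside the host")
        if self.n_libraries < 1:
            raise ValueError("n_libraries must be >= 1")


@dataclass
class HgtSimResult:
    host: SequenceRecord
    bacterial_db: list[SequenceRecord]  # insertion sources + decoy bacterial copies
    animal_db: list[SequenceRecord]  # decoy animal copies
    truth: pd.DataFrame  # insertion_id, start, end, identity, indel_events, source_id
    decoy_truth: pd.DataFrame  # decoy_id, start, end
    junctions: list[JunctionEvidence]
    genes: list[GeneModel]
    scaffold: str = "scaf1"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(
    seq: str, divergence: float, indel_rate: float, indel_extend: float,
    rng: np.random.Generator,
) -> tuple[str, float, int]:
    """Mutate a copy of ``seq``; return (copy, realized identity, indel events).

    Identity is recomputed from the realized edit alignment: matches over
    aligned columns, with every inserted or deleted base a non-match column.
    """
    out: list[str] = []
    matches = mismatches = gap_cols = events = 0
    for base in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            events += 1
            length = 1
            while indel_extend > 0 and rng.random() < indel_extend:
                length += 1
            if rng.random() < 0.5:  # insertion before this site
                out.extend(_BASES[rng.integers(0, 4, size=length)])
                gap_cols += length
            else:  # deletion starting at this site
                gap_cols += 1
                continue
        if divergence > 0 and rng.random() < divergence:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
            mismatches += 1
        else:
            out.append(base)
            matches += 1
    columns = matches + mismatches + gap_cols
    identity = 100.0 * matches / columns if columns else 0.0
    return "".join(out), identity, events


def simulate_hgt_genome(config: HgtSimConfig) -> HgtSimResult:
    """Plant diverged bacterial insertions in a random host genome.

    The host backbone is i.i.d. uniform nucleotide sequence; insertion
    positions are drawn by rejection until non-overlapping (error after 1000
    attempts); junction evidence is emitted in every library at both
    boundaries of every true insertion; flanking host genes are placed on
    each side of each insertion.
    """
    rng = np.random.default_rng(config.seed)
    backbone = _random_seq(rng, config.host_length)
    spacing = max(config.decoy_length + 2_000, 2_500)
    for _attempt in range(1000):
        pos = np.sort(rng.integers(2_000, config.host_length - 2_000,
                                   size=config.n_insertions))
        if config.n_insertions < 2 or np.diff(pos).min() >= spacing:
            break
    else:
        raise RuntimeError("could not place non-overlapping insertions in 1000 attempts")

    sources: list[SequenceRecord] = []
    inserts: list[tuple[int, str, float, int, str]] = []
    for i, p in enumerate(pos):
        source_id = f"BACT_SRC_{i:03d}"
        src = _random_seq(rng, config.insertion_length)
        mutated, identity, events = _mutate(
            src, config.divergence, config.indel_rate, config.indel_extend, rng
        )
        sources.append(SequenceRecord(source_id, src))
        inserts.append((int(p), mutated, identity, events, source_id))

    # assemble final host and record realized intervals
    pieces: list[str] = []
    truth_rows = []
    cursor = 0
    offset = 0
    for i, (p, mutated, identity, events, source_id) in enumerate(inserts):
        pieces.append(backbone[cursor:p])
        start = p + offset
        pieces.append(mutated)
        end = start + len(mutated)
        truth_rows.append(
            {"insertion_id": f"INS_{i:03d}", "start": start, "end": end,
             "identity": identity, "indel_events": events, "source_id": source_id}
        )
        offset += len(mutated)
        cursor = p
    pieces.append(backbone[cursor:])
    host_seq = "".join(pieces)
    scaffold = "scaf1"
    host = SequenceRecord(scaffold, host_seq)
    truth = pd.DataFrame(truth_rows)

    # decoy conserved genes: host segments mirrored into both databases
    intervals = [(r["start"], r["end"]) for r in truth_rows]
    decoy_rows = []
    animal_db: list[SequenceRecord] = []
    bacterial_db = list(sources)
    attempts = 0
    while len(decoy_rows) < config.n_decoys:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not place decoys away from insertions")
        s = int(rng.integers(0, len(host_seq) - config.decoy_length))
        e = s + config.decoy_length
        if any(s < ie + 200 and is_ - 200 < e for is_, ie in intervals):
            continue
        segment = host_seq[s:e]
        i = len(decoy_rows)
        animal_copy, _, _ = _mutate(segment, config.decoy_animal_divergence, 0.0, 0.0, rng)
        bact_copy, _, _ = _mutate(segment, config.decoy_bacterial_divergence, 0.002, 0.0, rng)
        animal_db.append(SequenceRecord(f"ANIM_{i:03d}", animal_copy))
        bacterial_db.append(SequenceRecord(f"BACT_DECOY_{i:03d}", bact_copy))
        decoy_rows.append({"decoy_id": f"DECOY_{i:03d}", "start": s, "end": e})
        intervals.append((s, e))
    decoy_truth = pd.DataFrame(decoy_rows)

    junctions: list[JunctionEvidence] = []
    for row in truth_rows:
        for lib in range(config.n_libraries):
            lib_id = f"LIB{lib + 1:02d}"
            for boundary in (row["start"], row["end"]):
                junctions.append(
                    JunctionEvidence(
                        scaffold=scaffold, position=int(boundary),
                        library_id=lib_id,
                        supporting_pairs=int(1 + rng.poisson(4)),
                    )
                )

    genes: list[GeneModel] = []
    for i, row in enumerate(truth_rows):
        left_end = row["start"] - 200
        if left_end - 300 >= 0:
            genes.append(GeneModel(f"GLEFT_{i:03d}", scaffold, left_end - 300, left_end))
        right_start = row["end"] + 200
        if right_start + 300 <= len(host_seq):
            genes.append(GeneModel(f"GRIGHT_{i:03d}", scaffold, right_start, right_start + 300))

    return HgtSimResult(
        host=host, bacterial_db=bacterial_db, animal_db=animal_db,
        truth=truth, decoy_truth=decoy_truth, junctions=junctions,
        genes=genes, scaffold=scaffold,
    )


def write_hgt_inputs(result: HgtSimResult, outdir: str | Path) -> dict[str, Path]:
    """Write every screen input (FASTA/TSV/GFF3/truth) into a directory."""
    from .hgt import write_junction_evidence
    from .io_formats import write_fasta, write_gene_models_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host": outdir / "host.fasta",
        "bacterial_db": outdir / "bacterial_db.fasta",
        "animal_db": outdir / "animal_db.fasta",
        "junctions": outdir / "junctions.tsv",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "decoy_truth": outdir / "decoy_truth.tsv",
    }
    write_fasta([result.host], paths["host"])
    write_fasta(result.bacterial_db, paths["bacterial_db"])
    write_fasta(result.animal_db, paths["animal_db"])
    write_junction_evidence(result.junctions, paths["junctions"])
    write_gene_models_gff3(result.genes, paths["genes"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    result.decoy_truth.to_csv(paths["decoy_truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Domain annotations with planted expansions


def simulate_domain_annotations(
    species: Sequence[str],
    n_domains: int,
    planted: Sequence[tuple[str, str, int]] = (),
    background_max: int = 2,
    seed: int = 0,
) -> tuple[list[DomainAnnotation], list[tuple[str, str, int]]]:
    """Uniform background domain counts with exactly-set planted cells.

    Background gene counts per (domain, species) are uniform on
    [0, background_max]; each planted (domain, species, count) cell is set
    exactly and must exceed the background maximum.  Returns the annotation
    list and the planted truth.
    """
    rng = np.random.default_rng(seed)
    species = list(species)
    for dom, sp, count in planted:
        if sp not in species:
            raise ValueError(f"planted species {sp!r} not in species list")
        if count <= background_max:
            raise ValueError("planted counts must exceed background_max")
    domains = [f"IPR{i:06d}" for i in range(n_domains)]
    planted_map = {(dom, sp): count for dom, sp, count in planted}
    unknown = {dom for dom, _sp in planted_map} - set(domains)
    if unknown:
        domains.extend(sorted(unknown))
    annotations: list[DomainAnnotation] = []
    counter = {sp: 0 for sp in species}
    for dom in domains:
        for sp in species:
            count = planted_map.get(
                (dom, sp), int(rng.integers(0, background_max + 1))
            )
            for _ in range(count):
                counter[sp] += 1
                annotations.append(
                    DomainAnnotation(
                        gene_id=f"{sp}_G{counter[sp]:05d}", species_id=sp,
                        domain_acc=dom, domain_name=f"domain {dom}",
                    )
                )
    return annotations, list(planted)


# ---------------------------------------------------------------------------
# Negative-binomial count matrices


@dataclass(frozen=True)
class CountSimConfig:
    """Two-condition count simulation with four replicates each by default.

    Per-condition means are baseline_mean * 2^(+-true_logfc/2); counts are
    negative binomial with variance mu + dispersion * mu^2 (Poisson when
    dispersion is 0).
    """

    n_genes: int = 2000
    n_reps: int = 4
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    true_logfc: float | Sequence[float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_counts(config: CountSimConfig) -> tuple[CountMatrix, dict[str, bool]]:
    """Simulate a genes x samples count matrix plus true-DE labels.

    Truth label is True iff the gene's true logFC is nonzero.
    """
    rng = np.random.default_rng(config.seed)
    lfc = np.asarray(config.true_logfc, dtype=float)
    if lfc.ndim == 0:
        lfc = np.full(config.n_genes, float(lfc))
    if lfc.shape != (config.n_genes,):
        raise ValueError("true_logfc must be scalar or length n_genes")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    mean_t = config.baseline_mean * np.power(2.0, lfc / 2.0)
    mean_c = config.baseline_mean * np.power(2.0, -lfc / 2.0)

    def draw(mean: np.ndarray, n_reps: int) -> np.ndarray:
        mu = np.repeat(mean[:, None], n_reps, axis=1)
        if config.dispersion == 0:
            return rng.poisson(mu)
        n = 1.0 / config.dispersion
        p = n / (n + mu)
        return rng.negative_binomial(n, p)

    t_counts = draw(mean_t, config.n_reps)
    c_counts = draw(mean_c, config.n_reps)
    samples = [f"T{i + 1}" for i in range(config.n_reps)] + [
        f"C{i + 1}" for i in range(config.n_reps)
    ]
    counts = pd.DataFrame(
        np.hstack([t_counts, c_counts]), index=genes, columns=samples
    )
    condition = {s: ("treatment" if s.startswith("T") else "control") for s in samples}
    truth = {g: bool(l != 0) for g, l in zip(genes, lfc)}
    return CountMatrix(counts, condition), truth
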