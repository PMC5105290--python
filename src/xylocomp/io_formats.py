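"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly and reject malformed records with the offending
line number rather than silently repairing them, so downstream stages can
assume clean inputs.  Internally every coordinate is 0-based half-open; the
1-based inclusive conventions of GFF3 and 12-column tabular alignment output
are converted at the file boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

SUBJECT_DBS = ("bacterial", "animal", "self", "arthropod")


class FormatError(ValueError):
    """A structurally invalid record in an input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (a genome scaffold or a database entry)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HomologyHit:
    """One tabular local-alignment record (BLAST outfmt-6 column order).

    Alignment coordinates keep the file's 1-based inclusive convention; use
    :meth:`q_interval` for the internal 0-based half-open view.  ``subject_db``
    labels which database the subject came from and is set by the loading
    call, never parsed from the file.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    subject_db: str

    def __post_init__(self) -> None:
        if self.subject_db not in SUBJECT_DBS:
            raise ValueError(f"unknown subject_db {self.subject_db!r}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} in hit {self.query_id}->{self.subject_id}")
        if self.pct_identity > 100 or self.pct_identity < 0:
            raise ValueError(f"identity {self.pct_identity} outside [0, 100]")
        if self.q_start > self.q_end:
            raise ValueError(f"query interval reversed ({self.q_start} > {self.q_end})")

    def q_interval(self) -> tuple[int, int]:
        """Query interval as 0-based half-open coordinates."""
        return (self.q_start - 1, self.q_end)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus on a scaffold; coordinates 0-based half-open."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    species: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Duplicate ids and empty sequences are format errors; record order is
    preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular alignment output (qseqid sseqid pident length mismatch
# gapopen qstart qend sstart send evalue bitscore)


def read_tabular_hits(path: str | Path, subject_db: str) -> list[HomologyHit]:
    """Read tabular alignment hits, labelling each with ``subject_db``."""
    if subject_db not in SUBJECT_DBS:
        raise ValueError(f"unknown subject_db {subject_db!r}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}")
            try:
                hit = HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_openings=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    subject_db=subject_db,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_openings}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, species: str = "") -> list[GeneModel]:
    """Read gene/mRNA features from a GFF3 file as :class:`GeneModel`.

    GFF3 coordinates are 1-based inclusive; they are converted here to the
    internal 0-based half-open convention (start-1, end).  Features of other
    types are skipped (count logged).
    """
    genes: list[GeneModel] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            ftype = cols[2]
            if ftype not in ("gene", "mRNA"):
                skipped += 1
                continue
            try:
                start_1, end_1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end_1 < start_1:
                raise FormatError(f"{path}:{lineno}: end {end_1} < start {start_1}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise FormatError(f"{path}:{lineno}: feature lacks an ID attribute")
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            genes.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    scaffold=cols[0],
                    start=start_1 - 1,
                    end=end_1,
                    strand=strand,
                    species=species,
                )
            )
    if skipped:
        logger.info("read_gff3(%s): skipped %d non-gene/mRNA features", path, skipped)
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as minimal GFF3 (used by the simulators)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\txylocomp\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Orthologous-group membership table

OG_TABLE_COLUMNS = ("og_id", "species_id", "gene_id")


def read_og_table(path: str | Path):
    """Read an OG membership TSV (header og_id/species_id/gene_id) into an
    :class:`~xylocomp.ortho.OrthoTable`.

    Exact duplicate rows are deduplicated with a warning; a gene assigned to
    two different OGs is an input error because the downstream classification
    gives each gene exactly one category.
    """
    from .ortho import OrthoTable  # local import to avoid a cycle

    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in OG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df[list(OG_TABLE_COLUMNS)].isna().any().any():
        bad = int(df[list(OG_TABLE_COLUMNS)].isna().any(axis=1).idxmax()) + 2
        raise FormatError(f"{path}:{bad}: empty field in OG table row")
    n_raw = len(df)
    df = df.drop_duplicates(subset=list(OG_TABLE_COLUMNS))
    if len(df) < n_raw:
        logger.warning("read_og_table(%s): dropped %d duplicate rows", path, n_raw - len(df))
    per_gene = df.groupby("gene_id")["og_id"].nunique()
    multi = per_gene[per_gene > 1]
    if not multi.empty:
        raise FormatError(
            f"{path}: gene(s) assigned to more than one OG: {', '.join(multi.index[:5])}"
        )
    triples = list(df[list(OG_TABLE_COLUMNS)].itertuples(index=False, name=None))
    return OrthoTable.from_triples(triples)


def write_og_table(table, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OG_TABLE_COLUMNS) + "\n")
        for og_id, species_id, gene_id in sorted(table.triples()):
            fh.write(f"{og_id}\t{species_id}\t{gene_id}\n")
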