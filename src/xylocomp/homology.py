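"""Homology calls at a fixed significance threshold.

Two routes produce :class:`~xylocomp.io_formats.HomologyHit` records: external
tabular search output (the production path, e.g. ``blastn -outfmt 6``), and a
built-in Smith-Waterman local aligner with affine gaps for fully
self-contained desk-scale runs.  Significance is a strict E-value cutoff
(default 1e-5); E-values for the built-in aligner follow the Karlin-Altschul
form E = K*m*n*exp(-lambda*S) with documented toy parameters -- the built-in
engine is not meant to reproduce BLAST statistics.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .io_formats import HomologyHit, SequenceRecord, read_tabular_hits


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores plus Karlin-Altschul parameters for E-values.

    ``gap_open`` is the score of the first base of a gap and ``gap_extend``
    of each further base (a length-k gap scores gap_open + (k-1)*gap_extend,
    the BLAST convention).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    karlin_lambda: float = 0.5
    karlin_K: float = 0.1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap scores must be <= 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class HomologyPolicy:
    """Strict E-value gate: a hit is significant iff evalue < threshold."""

    evalue_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue threshold must be > 0")


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expected hit count, E = K*m*n*exp(-lambda*S).

    Strictly decreasing in score, strictly increasing in both sequence
    lengths.
    """
    if m < 1 or n < 1:
        raise ValueError(f"sequence lengths must be >= 1, got m={m}, n={n}")
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * score)


def bit_score(score: float, scheme: ScoringScheme) -> float:
    """Normalized score S' = (lambda*S - ln K) / ln 2."""
    return (scheme.karlin_lambda * score - math.log(scheme.karlin_K)) / math.log(2)


def is_significant(hit: HomologyHit, policy: HomologyPolicy) -> bool:
    """True iff the hit's E-value is strictly below the policy threshold.

    Equality is insignificant: a hit at exactly the threshold fails.
    """
    return hit.evalue < policy.evalue_threshold


def best_hit(hits: Sequence[HomologyHit]) -> Optional[HomologyHit]:
    """The minimum-E-value hit of a single query.

    Ties break by maximum bit score, then lexicographically smallest
    subject_id; empty input yields None; mixed queries are an error.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"best_hit over mixed queries: {sorted(queries)}")
    return min(hits, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))


def local_align(
    query: SequenceRecord, subject: SequenceRecord, scheme: ScoringScheme
) -> HomologyHit:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Identity is matches over aligned columns with gap columns counting as
    non-matches, reported to one decimal as in tabular search output.  When
    no positive-scoring alignment exists the hit is empty (score 0, zero
    coordinates) and its E-value is the score-0 value K*m*n.
    """
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=scheme.match,
        mismatch_score=scheme.mismatch,
        open_gap_score=scheme.gap_open,
        extend_gap_score=scheme.gap_extend,
    )
    m, n = len(query), len(subject)
    score = aligner.score(query.seq, subject.seq)
    if score <= 0:
        return HomologyHit(
            query_id=query.id, subject_id=subject.id, pct_identity=0.0,
            aln_length=0, mismatches=0, gap_openings=0,
            q_start=0, q_end=0, s_start=0, s_end=0,
            evalue=evalue(0.0, m, n, scheme),
            bit_score=bit_score(0.0, scheme), subject_db="self",
        )
    aln = aligner.align(query.seq, subject.seq)[0]
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gap_cols = counts.internal_insertions + counts.internal_deletions
    gap_openings = counts.open_internal_insertions + counts.open_internal_deletions
    aln_length = identities + mismatches + gap_cols
    pct_identity = round(100.0 * identities / aln_length, 1) if aln_length else 0.0
    q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
    return HomologyHit(
        query_id=query.id,
        subject_id=subject.id,
        pct_identity=pct_identity,
        aln_length=aln_length,
        mismatches=mismatches,
        gap_openings=gap_openings,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        evalue=evalue(score, m, n, scheme),
        bit_score=bit_score(score, scheme),
        subject_db="self",
    )


def align_all(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    subject_db: str,
    policy: Optional[HomologyPolicy] = None,
) -> list[HomologyHit]:
    """All-vs-all local alignment; keeps significant hits when a policy is given."""
    hits = []
    for q in queries:
        for s in subjects:
            h = local_align(q, s, scheme)
            h = replace_subject_db(h, subject_db)
            if policy is None or is_significant(h, policy):
                hits.append(h)
    return hits


def replace_subject_db(hit: HomologyHit, subject_db: str) -> HomologyHit:
    import dataclasses

    return dataclasses.replace(hit, subject_db=subject_db)


def windowed_scan(
    host: SequenceRecord,
    database: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    subject_db: str,
    window: int = 400,
    step: int = 200,
    policy: Optional[HomologyPolicy] = None,
) -> list[HomologyHit]:
    """Scan a scaffold in overlapping windows with the built-in aligner.

    Each window is locally aligned against every database record; hit query
    coordinates are lifted back to the scaffold.  E-values use the full
    scaffold length as the query search space.  Intended for desk-scale
    fixtures; genome-scale screens use external tabular hits.
    """
    import dataclasses

    hits: list[HomologyHit] = []
    n = len(host)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts or starts[-1] + window < n:
        starts.append(max(n - window, 0))
    for w_start in starts:
        sub = SequenceRecord(host.id, host.seq[w_start:w_start + window])
        for rec in database:
            h = local_align(sub, rec, scheme)
            if h.aln_length == 0:
                continue
            h = dataclasses.replace(
                h,
                q_start=h.q_start + w_start,
                q_end=h.q_end + w_start,
                subject_db=subject_db,
                evalue=evalue(
                    (h.bit_score * math.log(2) + math.log(scheme.karlin_K))
                    / scheme.karlin_lambda,
                    n, len(rec), scheme,
                ),
            )
            if policy is None or is_significant(h, policy):
                hits.append(h)
    return hits


# ---------------------------------------------------------------------------
# External search engine (production path)


def blastn_hits(
    query_fasta: str | Path,
    db_fasta: str | Path,
    subject_db: str,
    evalue_cutoff: float = 1e-3,
    word_size: int | None = 7,
    threads: int = 1,
) -> list[HomologyHit]:
    """Run BLASTN (megablast off, plain ``-task blastn``) and load its
    12-column tabular output as labelled hits.

    This is the production route for genome-scale screens; requires the NCBI
    BLAST+ binaries on PATH.
    """
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("NCBI BLAST+ (blastn/makeblastdb) not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        db = str(Path(tmp) / "db")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "nucl", "-out", db],
            check=True, capture_output=True,
        )
        out = str(Path(tmp) / "hits.tsv")
        cmd = [
            "blastn", "-task", "blastn", "-query", str(query_fasta), "-db", db,
            "-outfmt", "6", "-evalue", str(evalue_cutoff), "-out", out,
            "-num_threads", str(threads), "-dust", "no",
        ]
        if word_size is not None:
            cmd += ["-word_size", str(word_size)]
        subprocess.run(cmd, check=True, capture_output=True)
        return read_tabular_hits(out, subject_db)
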