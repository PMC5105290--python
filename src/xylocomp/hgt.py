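"""DNA-based bacterial-to-eukaryote horizontal-gene-transfer screen.

Scaffold regions with significant bacterial similarity (E < 1e-5) are merged,
compared against an animal database, and excluded as slowly evolving
conserved genes when the best animal E-value is strictly smaller than the
bacterial one.  Surviving candidates are confirmed by junction-spanning
read-pair evidence across sequencing libraries, age-classified from their
identity to the bacterial source (high identity = recent insertion; low
identity plus indels = older insertion undergoing degradation), and reported
with their nearest flanking host genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .homology import HomologyPolicy, best_hit, is_significant
from .io_formats import GeneModel, HomologyHit


@dataclass(frozen=True)
class JunctionEvidence:
    """Read pairs from one library spanning a putative insertion boundary."""

    scaffold: str
    position: int  # 0-based point on the scaffold
    library_id: str
    supporting_pairs: int = 1

    def __post_init__(self) -> None:
        if self.supporting_pairs < 1:
            raise ValueError("supporting_pairs must be >= 1")


@dataclass(frozen=True)
class AgePolicy:
    """Identity/indel tiers separating recent from degrading insertions."""

    recent_min_identity: float = 90.0
    degrading_max_identity: float = 80.0
    degrading_min_indels: int = 1

    def __post_init__(self) -> None:
        if self.degrading_max_identity >= self.recent_min_identity:
            raise ValueError("degrading_max_identity must be < recent_min_identity")


@dataclass
class HgtCandidate:
    """One screened scaffold interval with its verdict."""

    scaffold: str
    interval: tuple[int, int]  # 0-based half-open
    best_bacterial: HomologyHit
    best_animal: Optional[HomologyHit] = None
    pct_identity: float = 0.0
    indel_events: int = 0
    junction_libraries: int = 0
    junction_confirmed: bool = False
    flanking_gene_ids: tuple[Optional[str], Optional[str]] = (None, None)
    status: str = "retained"  # retained | excluded_conserved | subthreshold
    age_class: str = "intermediate"  # recent | degrading | intermediate
    expressed: Optional[bool] = None  # reporting hook only, never a verdict input

    def check_invariant(self, policy: HomologyPolicy) -> None:
        if self.status == "retained":
            assert is_significant(self.best_bacterial, policy), (
                f"retained candidate {self.scaffold}:{self.interval} below threshold"
            )
            assert (
                self.best_animal is None
                or not self.best_animal.evalue < self.best_bacterial.evalue
            ), f"retained candidate {self.scaffold}:{self.interval} out-scored by animal hit"


def find_bacterial_regions(
    hits: Sequence[HomologyHit],
    policy: HomologyPolicy = HomologyPolicy(),
    merge_gap: int = 0,
) -> list[tuple[str, tuple[int, int], HomologyHit]]:
    """Merge significant bacterial hits into candidate regions per scaffold.

    Hits below the significance gate are dropped; overlapping query intervals
    on the same scaffold (within ``merge_gap`` bases, default 0 = strict
    overlap) merge into one region carrying the best constituent hit.
    """
    significant = [h for h in hits if is_significant(h, policy)]
    by_scaffold: dict[str, list[HomologyHit]] = {}
    for h in significant:
        by_scaffold.setdefault(h.query_id, []).append(h)
    regions: list[tuple[str, tuple[int, int], HomologyHit]] = []
    for scaffold in sorted(by_scaffold):
        shits = sorted(by_scaffold[scaffold], key=lambda h: h.q_interval())
        cur_start, cur_end = shits[0].q_interval()
        cur_hits = [shits[0]]
        for h in shits[1:]:
            s, e = h.q_interval()
            if s <= cur_end + merge_gap:
                cur_end = max(cur_end, e)
                cur_hits.append(h)
            else:
                regions.append(
                    (scaffold, (cur_start, cur_end), best_hit(cur_hits))
                )
                cur_start, cur_end, cur_hits = s, e, [h]
        regions.append((scaffold, (cur_start, cur_end), best_hit(cur_hits)))
    return regions


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def screen_region(
    region: tuple[str, tuple[int, int], HomologyHit],
    animal_hits: Sequence[HomologyHit],
) -> str:
    """Retain or exclude one bacterial region against the animal database.

    Excluded as a slowly evolving conserved gene iff the best overlapping
    animal E-value is strictly less than the bacterial one; no animal hit or
    a tie retains the candidate.
    """
    scaffold, interval, bact = region
    overlapping = [
        h for h in animal_hits
        if h.query_id == scaffold and _overlaps(h.q_interval(), interval)
    ]
    if not overlapping:
        return "retained"
    best_animal = min(overlapping, key=lambda h: h.evalue)
    return "excluded_conserved" if best_animal.evalue < bact.evalue else "retained"


def classify_age(
    pct_identity: float,
    indel_events: int,
    policy: AgePolicy = AgePolicy(),
) -> str:
    """Age tier of an insertion from identity to its bacterial source.

    recent: identity >= recent_min_identity; degrading: identity <=
    degrading_max_identity with at least degrading_min_indels indel events;
    everything else intermediate.
    """
    if not 0 < pct_identity <= 100:
        raise ValueError(f"identity {pct_identity} outside (0, 100]")
    if pct_identity >= policy.recent_min_identity:
        return "recent"
    if (
        pct_identity <= policy.degrading_max_identity
        and indel_events >= policy.degrading_min_indels
    ):
        return "degrading"
    return "intermediate"


def confirm_junctions(
    candidate: HgtCandidate,
    evidence: Sequence[JunctionEvidence],
    min_libraries: int = 2,
    window: int = 50,
) -> tuple[int, bool]:
    """Count libraries with junction evidence near the candidate boundaries.

    A library supports the candidate iff it has evidence within ``window``
    bases of either interval boundary; the candidate is confirmed iff at
    least ``min_libraries`` distinct libraries support BOTH boundaries.
    """
    start, end = candidate.interval
    left_libs: set[str] = set()
    right_libs: set[str] = set()
    for ev in evidence:
        if ev.scaffold != candidate.scaffold:
            continue
        if abs(ev.position - start) <= window:
            left_libs.add(ev.library_id)
        if abs(ev.position - end) <= window:
            right_libs.add(ev.library_id)
    supporting = left_libs | right_libs
    confirmed = len(left_libs) >= min_libraries and len(right_libs) >= min_libraries
    return len(supporting), confirmed


def flanking_genes(
    candidate: HgtCandidate, genes: Sequence[GeneModel]
) -> tuple[Optional[str], Optional[str]]:
    """Nearest non-overlapping gene on each side of the candidate interval."""
    start, end = candidate.interval
    on_scaffold = [g for g in genes if g.scaffold == candidate.scaffold]
    left = [g for g in on_scaffold if g.end <= start]
    right = [g for g in on_scaffold if g.start >= end]
    left_id = max(left, key=lambda g: (g.end, g.start)).gene_id if left else None
    right_id = min(right, key=lambda g: (g.start, g.end)).gene_id if right else None
    return (left_id, right_id)


def screen_genome(
    bacterial_hits: Sequence[HomologyHit],
    animal_hits: Sequence[HomologyHit],
    junction_evidence: Sequence[JunctionEvidence] = (),
    genes: Sequence[GeneModel] = (),
    policy: HomologyPolicy = HomologyPolicy(),
    age_policy: AgePolicy = AgePolicy(),
    min_libraries: int = 2,
    junction_window: int = 50,
    merge_gap: int = 0,
) -> list[HgtCandidate]:
    """Run the full screen and return one annotated candidate per region.

    Candidate identity and indel counts come from the best bacterial hit of
    the merged region; the retained-candidate invariant is asserted on every
    output.
    """
    regions = find_bacterial_regions(bacterial_hits, policy, merge_gap)
    candidates: list[HgtCandidate] = []
    for region in regions:
        scaffold, interval, bact = region
        cand = HgtCandidate(
            scaffold=scaffold,
            interval=interval,
            best_bacterial=bact,
            pct_identity=bact.pct_identity,
            indel_events=bact.gap_openings,
        )
        overlapping_animal = [
            h for h in animal_hits
            if h.query_id == scaffold and _overlaps(h.q_interval(), interval)
        ]
        if overlapping_animal:
            cand.best_animal = min(overlapping_animal, key=lambda h: h.evalue)
        cand.status = screen_region(region, animal_hits)
        cand.age_class = classify_age(
            max(cand.pct_identity, 1e-9), cand.indel_events, age_policy
        )
        cand.junction_libraries, cand.junction_confirmed = confirm_junctions(
            cand, junction_evidence, min_libraries, junction_window
        )
        cand.flanking_gene_ids = flanking_genes(cand, genes)
        if cand.status == "retained":
            cand.check_invariant(policy)
        candidates.append(cand)
    return candidates


CANDIDATE_COLUMNS = (
    "scaffold", "start", "end", "status", "age_class", "pct_identity",
    "indel_events", "bacterial_evalue", "animal_evalue",
    "junction_libraries", "junction_confirmed", "left_gene", "right_gene",
    "expressed",
)


def write_candidate_report(
    candidates: Iterable[HgtCandidate], path: str | Path
) -> None:
    """Write the candidate report TSV with all screening fields."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            animal_e = "" if c.best_animal is None else f"{c.best_animal.evalue:g}"
            expressed = "" if c.expressed is None else str(int(c.expressed))
            fh.write(
                f"{c.scaffold}\t{c.interval[0]}\t{c.interval[1]}\t{c.status}\t"
                f"{c.age_class}\t{c.pct_identity:.1f}\t{c.indel_events}\t"
                f"{c.best_bacterial.evalue:g}\t{animal_e}\t"
                f"{c.junction_libraries}\t{int(c.junction_confirmed)}\t"
                f"{c.flanking_gene_ids[0] or ''}\t{c.flanking_gene_ids[1] or ''}\t"
                f"{expressed}\n"
            )


def read_junction_evidence(path: str | Path) -> list[JunctionEvidence]:
    """Read junction-evidence TSV (scaffold, position, library_id, supporting_pairs)."""
    from .io_formats import FormatError

    out: list[JunctionEvidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["scaffold", "position", "library_id", "supporting_pairs"]
        if header != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                out.append(
                    JunctionEvidence(cols[0], int(cols[1]), cols[2], int(cols[3]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_junction_evidence(
    evidence: Iterable[JunctionEvidence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\tlibrary_id\tsupporting_pairs\n")
        for ev in evidence:
            fh.write(f"{ev.scaffold}\t{ev.position}\t{ev.library_id}\t{ev.supporting_pairs}\n")
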