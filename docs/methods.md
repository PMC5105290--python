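# Methods

This note records the models and procedures xylocomp implements, the
parameters that matter, what the simulators do and do not emulate, and the
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and 12-column tabular alignment output (1-based inclusive, possibly
reversed on the subject strand) are converted at the file boundary and
nowhere else, so no stage performs its own ±1 arithmetic. Readers reject
structurally invalid records with the offending line number instead of
repairing them; a gene assigned to two OGs is an input error because the
classification assigns each gene exactly one category. Strand is recorded
but the HGT screen ignores it: the screen is DNA-similarity based and a hit
on either strand is evidence of bacterial origin.

## Homology calls

A hit is significant iff its E-value is strictly below the threshold
(default 1e-5); equality fails. `best_hit` minimizes E-value with ties
broken by maximal bit score, then lexicographically smallest subject id, so
results are independent of input order.

The built-in aligner is optimal Smith–Waterman with affine gaps (a
length-k gap scores `gap_open + (k-1)*gap_extend`), delegated to
Biopython's `PairwiseAligner`; the test suite checks it against an
independent full-DP Gotoh oracle on hundreds of random sequence pairs.
Identity is matches over aligned columns with gap columns counting as
non-matches, reported to one decimal as tabular search output does.
E-values use the Karlin–Altschul form `E = K·m·n·exp(-λS)` with documented
toy defaults (K = 0.1, λ = 0.5). These are *not* BLAST's fitted
parameters: the built-in engine exists for self-contained desk-scale
fixtures, and genome-scale screens use externally produced tabular hits
(`blastn_hits` runs NCBI BLASTN with `-task blastn -word_size 7 -dust no`,
settings chosen so that 70%-identity insertions — the old, degraded tier —
are still seeded and found).

## Orthology partition

Species are partitioned into three disjoint sets (default: five
Coleoptera, five Lepidoptera/Diptera, five outgroup insects). An OG counts
in a set iff it contains genes from ≥ `min_species_per_set` (default 2)
distinct species of that set; the span label (three_set / two_set /
one_set / unshared) is the number of counting sets. Per-gene categories:

- three_set OG → `universal_single` if the gene's species has exactly one
  gene in the OG, else `universal_multi`. Summaries also expose the
  derived `widespread` super-class (all three-set genes), since both views
  of the conserved core are standard.
- two_set OG → `two_set`; one_set OG → `set_restricted_ortholog`.
- unshared OGs and OG-less genes fall through to homology evidence:
  `arthropod_homolog` if any significant non-self hit to another genome,
  else `self_homolog` if any significant hit to a *different* gene of the
  same genome (a gene's trivial match to itself never counts), else
  `unique`. A gene with both kinds of evidence is `arthropod_homolog`;
  lineage-restriction analysis treats below-threshold OGs as "without
  orthologs" rather than inventing an extra ortholog class.

`copy_number_split` tallies genes (not OGs) over three-set OGs: a species
with one gene in a shared OG contributes 1 to single-copy; with k > 1
genes it contributes k to multi-copy.

## HGT screen

Significant bacterial hits on a scaffold are merged by strict interval
overlap (a `merge_gap` parameter exists, default 0) into candidate
regions, each carrying its best hit. A region is excluded as a slowly
evolving conserved gene iff the best animal E-value over *any* overlapping
animal hit is strictly less than the bacterial one; no animal hit, or an
exact tie, retains the region — the exclusion clause is a strict "less
than", so equality is not evidence of conservation. How close an animal
hit must be is an open point in the screen's definition; any overlap with
the region interval is this package's contract.

Age tiers generalize the two observed regimes (recent insertions near 95%
identity; older degrading insertions at 70–71% with indels) into a policy:
recent iff identity ≥ 90, degrading iff identity ≤ 80 with ≥ 1 indel
event, otherwise intermediate. The thresholds live in `AgePolicy`, not in
code. Indel events are the gap openings of the region's best bacterial hit.

Junction confirmation reads "multiple libraries" in its weakest faithful
sense: ≥ 2 distinct libraries with junction-spanning evidence within 50 bp
of a boundary, required at *both* boundaries. Candidate expression is a
reporting hook only; it never enters the verdict.

## Domain-family expansions

Counting is gene-level: a gene with five matches to one domain contributes
one. The expansion rule is strict — a family is reported iff some species
has a count > 5 (a maximum of exactly 5 is suppressed); ties report all
arg-max species. The orthology-status partition puts each domain-matched
gene in exactly one of single_copy / multi_copy / homology_only, so the
three bins always sum to the count-matrix cell. Subfamily groupings (e.g.
a P450 "group II") are config-supplied accession lists summed before the
focal-vs-mean ratio; the grouping scheme itself is not reimplemented.
`enrichment_vs_mean` returns ∞ when the non-focal mean is 0 with a
positive focal count and NaN for 0/0.

## Differential expression

The procedure implements the exact-test formulation directly rather than
wrapping a count-model package: genes with < 10 reads total are removed,
counts are quantile normalized (every sample forced onto the row-mean
reference distribution; ties receive the mean of the reference values
their ranks span), and each gene is tested with a two-sided Fisher exact
test on `[[gene_t, rest_t], [gene_c, rest_c]]`, where rest = condition
library total − gene count and replicates are summed within condition.
Two-sided means summing all tables with fixed margins whose
hypergeometric probability is at most the observed table's (SciPy's
implementation, checked in the tests against an exact rational-arithmetic
enumeration). BH step-up adjusts the p-values; flags require |logFC| > 1.0
AND adjusted p < 0.05, both strict.

Two interpretation points were open and are resolved as follows. First,
whether normalization feeds the test or the report: here the exact test
uses raw-count condition margins (the test is only exact for integer
counts) while quantile-normalized values feed the reported logFC, with a
pseudocount of 0.5 (configurable) stabilizing zeros. Second, the flag is
sign-agnostic (|logFC|), since both up- and down-regulation are of
interest. Summing replicates before an exact test leaves replicate-level
biological dispersion unmodeled; the test is therefore optimistic for
overdispersed genes, which is exactly why the null false-positive rate
under negative-binomial noise (dispersion 0.2) is one of the quantities
the acceptance script measures rather than something assumed.

## Simulators

All simulators are pure functions of their config (seed included):
identical configs give bitwise-identical outputs.

**Gene families.** One copy per family at the root of the default 15-tip
tree (three clades of five, tip labels the 5-letter species codes); along
each branch of length t each copy is independently lost with probability
`1 − exp(−μt)` and, surviving, duplicates with probability `1 − exp(−λt)`.
Branch-wise event probabilities rather than explicit event times keep the
simulator simple and exactly seedable. Families with genes from ≥ 2
species become OGs (an orthology resource clusters across species);
single-species families and singletons are left OG-less and exercise the
homology fallbacks, for which "perfect" hit files (every same-family pair
significant at E = 1e-30) are emitted. Truth labels are computed directly
from realized presence counts, not by the classifier under test. Default
rates (λ = 0.1, μ = 0.1 per branch-length unit) give mostly-conserved
families; the tests and acceptance script raise μ to produce
lineage-restricted and fallback genes.

**HGT genomes.** The host backbone is i.i.d. uniform nucleotide sequence —
deliberately free of repeats, GC structure, and low-complexity tracts, so
recovery rates measure the screen, not the hardness of real genomes.
Insertion copies mutate per site with probability d and suffer indel
events at `indel_rate` per site (single-base by default; geometric lengths
via `indel_extend`); realized identity is recomputed from the applied edit
alignment (gap columns as non-matches), never assumed to equal 1 − d.
Junction evidence is emitted in every library at both boundaries of every
true insertion. Decoy conserved genes are host segments copied into the
animal database at 1% divergence and into the bacterial database at 15%
divergence over 400 bp — similar enough for a significant bacterial hit,
but always out-scored by the animal copy. The decoy segments are kept
short enough that both E-values stay above the floating-point underflow of
tabular E-value reporting; at multi-kilobase lengths both would print as
0.0 and the strict "animal < bacterial" comparison would degenerate to a
tie.

**Domain annotations.** Background gene counts per (domain, species) are
uniform on [0, background_max] (default 2); planted cells are set exactly
and must exceed the background bound, so the planted truth is recoverable
by construction.

**Counts.** Negative binomial with mean `baseline·2^(±logFC/2)` per
condition and variance `μ + φμ²` (Poisson at φ = 0), four replicates per
condition by default, matching the four-larvae-per-diet design the
procedure targets. The null experiment uses 2000 genes at baseline mean
100 and dispersion 0.2 — a constant moderate expression level chosen so
the null flagged fraction isolates the statistic's behaviour from
mean-expression heterogeneity.

## Problem sizes used in verification

The acceptance script and test suite run: 200 random OG tables (≤ 8
species, ≤ 50 OGs) against nested-loop recount oracles; closed-loop
simulator/classifier comparison on 1000 families at zero and at positive
rates; planted-insertion screens of 50 × 2 kb insertions in a 1 Mb host at
divergence 0.05 (and 0.30 with indels) with 10 decoys, using BLASTN for
hit generation, while a 12 kb host with 3 insertions exercises the same
screen end-to-end through the built-in windowed aligner; exact-test
enumeration over all 2×2 tables with margins ≤ 30; and a 2000-gene null DE
matrix. These sizes complete in well under a minute each while leaving
every rule's boundary (thresholds, tie-breaks, strictness) covered
explicitly.

## Known limitations

- The built-in aligner's Karlin–Altschul parameters are toy values; its
  E-values order hits correctly but are not calibrated to any database
  search engine.
- The exact-test DE formulation ignores replicate dispersion (see above);
  it reproduces the stated procedure, not a moderated count model.
- The HGT screen assigns no taxonomic source and does no phylogenetic
  placement; it reports candidates, ages, junction support, and flanks.
- Simulated genomes lack repeats and compositional structure; recovery
  rates on real assemblies will be lower, and the decoy-rejection result
  shows the comparison logic works, not that real conserved genes are
  always caught.
- OGs are inputs; the package does not reconstruct orthology clustering.
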