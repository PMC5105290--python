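"""Independent brute-force oracles the tests check the implementation against.

These deliberately share no code with the package: the aligner oracle is a
plain Gotoh dynamic program over Python lists, the orthology oracle is
nested loops over raw membership triples, and the exact-test oracle is a
rational-arithmetic hypergeometric enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

NEG = float("-inf")


def sw_score(a: str, b: str, match: float, mismatch: float,
             gap_open: float, gap_extend: float) -> float:
    """Optimal Smith-Waterman local score with affine gaps, full DP table.

    A length-k gap scores gap_open + (k-1)*gap_extend; adjacent gaps in
    opposite directions are allowed (each pays its own opening).
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
            best = max(best, M[i][j])
    return best


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact enumeration over fixed margins.

    Sums hypergeometric probabilities of all tables at most as probable as
    the observed one, with the conventional 1e-7 relative tie tolerance.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        return 1.0
    denom = comb(N, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    obs = pmf(a)
    gate = obs * Fraction(10**7 + 1, 10**7)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = pmf(x)
        if p <= gate:
            total += p
    return float(min(Fraction(1), total))


# ---------------------------------------------------------------------------
# Naive orthology classification: nested loops over raw triples.


def naive_classify(
    triples: list[tuple[str, str, str]],
    set_map: dict[str, str],
    min_per_set: int,
    arth_hits: list[tuple[str, str, float]],
    self_hits: list[tuple[str, str, float]],
    extra_genes: dict[str, str],
    evalue_threshold: float = 1e-5,
) -> dict[str, str]:
    n_sets = len(set(set_map.values()))

    def fallback(gene: str) -> str:
        for q, s, e in arth_hits:
            if q == gene and s != gene and e < evalue_threshold:
                return "arthropod_homolog"
        for q, s, e in self_hits:
            if q == gene and s != gene and e < evalue_threshold:
                return "self_homolog"
        return "unique"

    cats: dict[str, str] = {}
    for og in sorted({og for og, _, _ in triples}):
        members = [(sp, g) for o, sp, g in triples if o == og]
        counting = 0
        for lab in sorted(set(set_map.values())):
            if len({sp for sp, _ in members if set_map[sp] == lab}) >= min_per_set:
                counting += 1
        for sp, g in members:
            copies = sum(1 for sp2, _ in members if sp2 == sp)
            if counting == n_sets:
                cats[g] = "universal_single" if copies == 1 else "universal_multi"
            elif counting == 2:
                cats[g] = "two_set"
            elif counting == 1:
                cats[g] = "set_restricted_ortholog"
            else:
                cats[g] = fallback(g)
    for g in extra_genes:
        if g not in cats:
            cats[g] = fallback(g)
    return cats


def naive_species_counts(
    cats: dict[str, str], gene_species: dict[str, str]
) -> dict[tuple[str, str], int]:
    """Recount (species, category) cells gene by gene."""
    out: dict[tuple[str, str], int] = {}
    for g, cat in cats.items():
        key = (gene_species[g], cat)
        out[key] = out.get(key, 0) + 1
    return out


def naive_copy_number(
    triples: list[tuple[str, str, str]],
    set_map: dict[str, str],
    min_per_set: int,
) -> dict[str, tuple[int, int]]:
    """Per-species (single, multi) gene tallies over three-set OGs."""
    n_sets = len(set(set_map.values()))
    out: dict[str, tuple[int, int]] = {sp: (0, 0) for sp in set_map}
    for og in sorted({og for og, _, _ in triples}):
        members = [(sp, g) for o, sp, g in triples if o == og]
        counting = sum(
            1 for lab in sorted(set(set_map.values()))
            if len({sp for sp, _ in members if set_map[sp] == lab}) >= min_per_set
        )
        if counting != n_sets:
            continue
        for sp in {sp for sp, _ in members}:
            copies = sum(1 for sp2, _ in members if sp2 == sp)
            single, multi = out[sp]
            if copies == 1:
                out[sp] = (single + 1, multi)
            else:
                out[sp] = (single, multi + copies)
    return out
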