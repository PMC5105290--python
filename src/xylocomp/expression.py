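"""Differential-expression flagging for a two-condition RNA-seq comparison.

The procedure: drop genes with fewer than ten mapped reads in total, quantile
normalize the count matrix, test each gene with a two-sided Fisher exact test
on the 2x2 table of (gene reads, remaining reads) per condition, adjust the
p-values with Benjamini-Hochberg step-up FDR, and flag genes with |log2 fold
change| strictly greater than 1.0 and adjusted p strictly below 0.05.

Replicates are summed within condition before the exact test; the
replicate-level dispersion this leaves unmodeled is documented in the methods
note.  Quantile-normalized values feed logFC reporting while the exact test
keeps raw-count condition margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FormatError

CONDITIONS = ("treatment", "control")


@dataclass(frozen=True)
class DEPolicy:
    """Thresholds of the flagging procedure (all comparisons strict)."""

    min_total_reads: int = 10
    logfc_threshold: float = 1.0
    adj_p_threshold: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_total_reads, self.logfc_threshold, self.adj_p_threshold,
               self.pseudocount) <= 0:
            raise ValueError("DEPolicy thresholds must be positive")


class CountMatrix:
    """Genes x samples read counts with a condition label per sample."""

    def __init__(self, counts: pd.DataFrame, condition: Mapping[str, str]) -> None:
        self.counts = counts.astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        self.condition = dict(condition)
        missing = [s for s in self.counts.columns if s not in self.condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        bad = {c for c in self.condition.values()} - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            if not self.samples(cond):
                raise ValueError(f"no samples for condition {cond!r}")

    def samples(self, cond: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == cond]

    def condition_totals(self, cond: str) -> pd.Series:
        """Per-gene read counts summed over the condition's replicates."""
        return self.counts[self.samples(cond)].sum(axis=1)

    def library_size(self, cond: str) -> int:
        return int(self.condition_totals(cond).sum())


def filter_low_counts(matrix: CountMatrix, policy: DEPolicy = DEPolicy()) -> CountMatrix:
    """Drop genes whose total count across all samples is below the minimum."""
    keep = matrix.counts.sum(axis=1) >= policy.min_total_reads
    return CountMatrix(matrix.counts.loc[keep], matrix.condition)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the row-mean reference distribution.

    After normalization each column's sorted values equal the reference
    (the mean over samples of the per-rank sorted values); tied values within
    a sample receive the mean of the reference values their ranks span.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(arr.shape[0])
        col[order] = reference
        s = pd.Series(col, index=df.index)
        out[:, j] = s.groupby(df.iloc[:, j].to_numpy()).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def gene_exact_test(
    count_a: int,
    count_b: int,
    lib_a: int,
    lib_b: int,
    policy: DEPolicy = DEPolicy(),
) -> tuple[float, float]:
    """(logFC, two-sided Fisher exact p) for one gene's condition totals.

    The 2x2 table is [[count_a, lib_a - count_a], [count_b, lib_b - count_b]];
    the two-sided p sums all tables with fixed margins whose hypergeometric
    probability is at most the observed table's.  logFC applies the policy
    pseudocount to the library-scaled proportions:
    log2(((a + c)/lib_a) / ((b + c)/lib_b)).
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("gene count exceeds its library size")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    c = policy.pseudocount
    logfc = math.log2(((count_a + c) / lib_a) / ((count_b + c) / lib_b))
    return logfc, float(min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_de(results: pd.DataFrame, policy: DEPolicy = DEPolicy()) -> pd.DataFrame:
    """Set the ``flagged`` column: |logFC| > threshold AND adj_p < threshold.

    Both comparisons are strict; a gene at logFC exactly 1.0 or adjusted p
    exactly 0.05 is not flagged.
    """
    out = results.copy()
    out["flagged"] = (out["logFC"].abs() > policy.logfc_threshold) & (
        out["adj_p"] < policy.adj_p_threshold
    )
    return out


def de_pipeline(matrix: CountMatrix, policy: DEPolicy = DEPolicy()) -> pd.DataFrame:
    """Full flagging procedure; returns gene_id/logFC/p/adj_p/flagged.

    Exact-test margins use raw condition totals; logFC is computed from
    quantile-normalized values summed within condition (normalization
    equalizes library distributions, so no further library scaling applies).
    """
    filtered = filter_low_counts(matrix, policy)
    if filtered.counts.empty:
        return pd.DataFrame(columns=["gene_id", "logFC", "p", "adj_p", "flagged"])
    norm = quantile_normalize(filtered.counts)
    t_samples = filtered.samples("treatment")
    c_samples = filtered.samples("control")
    norm_t = norm[t_samples].sum(axis=1)
    norm_c = norm[c_samples].sum(axis=1)
    raw_t = filtered.condition_totals("treatment")
    raw_c = filtered.condition_totals("control")
    lib_t, lib_c = filtered.library_size("treatment"), filtered.library_size("control")
    c = policy.pseudocount
    logfc = np.log2((norm_t + c) / (norm_c + c))
    pvals = [
        gene_exact_test(int(a), int(b), lib_t, lib_c, policy)[1]
        for a, b in zip(raw_t, raw_c)
    ]
    results = pd.DataFrame(
        {
            "gene_id": filtered.counts.index,
            "logFC": logfc.to_numpy(),
            "p": pvals,
            "adj_p": bh_adjust(pvals),
        }
    )
    results = flag_de(results, policy)
    assert ((results["adj_p"] >= results["p"] - 1e-12) & (results["adj_p"] <= 1)).all()
    return results


# ---------------------------------------------------------------------------
# I/O


def read_count_matrix(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (header = sample ids, first column gene_id)
    and a sample_id/condition map TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond_df = pd.read_csv(conditions_path, sep="\t", dtype=str)
    if list(cond_df.columns[:2]) != ["sample_id", "condition"]:
        raise FormatError(
            f"{conditions_path}: expected columns sample_id, condition"
        )
    condition = dict(zip(cond_df["sample_id"], cond_df["condition"]))
    return CountMatrix(counts, condition)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path,
                       conditions_path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    with open(conditions_path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in matrix.counts.columns:
            fh.write(f"{s}\t{matrix.condition[s]}\n")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def plot_flagged_heatmap(
    matrix: CountMatrix, results: pd.DataFrame, path: str | Path
) -> None:
    """Heatmap of quantile-normalized expression for flagged genes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flagged = results.loc[results["flagged"], "gene_id"]
    if flagged.empty:
        raise ValueError("no flagged genes to plot")
    norm = quantile_normalize(matrix.counts)
    data = np.log2(norm.loc[flagged] + 1)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(flagged))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 normalized count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
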