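"""RPKM normalization and row-centered log2 heatmap matrices.

RPKM = counts / (gene length in kb x total mapped reads in millions).
Heatmap values are log2(RPKM + pseudocount) with each gene row centered on
its mean, so rows sum to zero and color encodes within-gene variation
across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CountMatrix


class RnaseqError(ValueError):
    pass


def rpkm(counts, gene_lengths=None, total_reads=None) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    Accepts a :class:`~trpquant.synthetic.CountMatrix` or a genes x samples
    DataFrame plus explicit lengths (bp) and per-sample totals (defaulting
    to column sums).
    """
    if isinstance(counts, CountMatrix):
        gene_lengths = counts.gene_lengths
        total_reads = counts.total_reads
        counts = counts.counts
    if gene_lengths is None:
        raise RnaseqError("gene lengths required")
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        raise RnaseqError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise RnaseqError("gene lengths must be positive")
    if total_reads is None:
        total_reads = counts.sum(axis=0)
    totals = pd.Series(total_reads, dtype=float).reindex(counts.columns)
    if (totals <= 0).any():
        raise RnaseqError("total mapped reads must be positive for every sample")
    return counts.astype(float).div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def row_centered_log2(rpkm_matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(RPKM + pseudocount), each row centered on its mean (rows sum to 0)."""
    if not pseudocount > 0:
        raise RnaseqError("pseudocount must be positive")
    v = np.log2(rpkm_matrix.astype(float) + pseudocount)
    return v.sub(v.mean(axis=1), axis=0)


def fold_change_rank_table(
    rpkm_matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Simple expression screen between two sample groups.

    Per gene: log2 fold change of mean RPKM (A over B, pseudocounted) and a
    Mann–Whitney rank p-value with Benjamini–Hochberg adjustment.  This is
    a ranking aid, not DESeq2 — no dispersion modeling or shrinkage; use a
    dedicated differential-expression tool for inference.
    """
    for col in [*group_a, *group_b]:
        if col not in rpkm_matrix.columns:
            raise RnaseqError(f"sample {col!r} not in matrix")
    a = rpkm_matrix[group_a].to_numpy(float)
    b = rpkm_matrix[group_b].to_numpy(float)
    lfc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
    pvals = np.array([
        stats.mannwhitneyu(ra, rb, alternative="two-sided").pvalue
        if (np.ptp(np.concatenate([ra, rb])) > 0) else 1.0
        for ra, rb in zip(a, b)
    ])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": rpkm_matrix.index,
        "log2_fold_change": lfc,
        "p_value": pvals,
        "p_adjusted": padj,
        "method": "mean-RPKM log2FC + Mann-Whitney/BH (not DESeq2)",
    }).set_index("gene")


def plot_heatmap(matrix: pd.DataFrame, ax=None, cmap: str = "RdBu_r"):
    """Render a row-centered log2 matrix as a heatmap; returns the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.5 * matrix.shape[1], 0.8 + 0.25 * matrix.shape[0]))
    lim = float(np.nanmax(np.abs(matrix.to_numpy()))) or 1.0
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), labels=list(matrix.index))
    ax.figure.colorbar(im, ax=ax, label="row-centered log2 RPKM")
    return ax
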