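"""Coupling between increased intron retention and gene expression change.

Intron retention frequently introduces premature termination codons, so
transcripts with more-retained introns are expected to be degraded
(nonsense-mediated decay) or sequestered, lowering their apparent
expression. The test compares the log2 fold-change distribution of genes
harboring at least one significantly more-retained intron against the
background of expressed genes with none, with a two-sided Mann-Whitney U
test; the median log2FC shift is reported as the directional effect
summary.

Differential-expression model fitting is out of scope here: the link test
needs only a per-gene fold-change coordinate, computed from library-size
normalized counts (median-of-ratios when an all-positive reference
exists, total-count scaling otherwise) with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean, mannwhitneyu

from .events import SplicingEvent

EXACT_MW_MAX_N = 12


@dataclass
class LinkTestResult:
    n_ir_genes: int
    n_background_genes: int
    u_statistic: float
    p: float
    median_shift: float

    def to_dict(self) -> dict:
        return {
            "n_ir_genes": self.n_ir_genes,
            "n_background_genes": self.n_background_genes,
            "u_statistic": self.u_statistic,
            "p": self.p,
            "median_shift": self.median_shift,
        }


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; total-count scaling as fallback
    when no gene is positive in every sample."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= 1:
        ref = gmean(positive, axis=1)
        factors = positive.div(ref, axis=0).median(axis=0)
    else:
        totals = counts.sum(axis=0).astype(float)
        factors = totals / gmean(totals[totals > 0]) if (totals > 0).any() else totals * 0 + 1.0
    factors = factors.replace(0, 1.0)
    # anchor the overall scale so equal-depth samples get factor 1 exactly
    return factors / gmean(factors)


def gene_log2fc(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene normalized means and log2 fold change (a vs b).

    ``counts`` is genes x samples of non-negative integers. The
    pseudocount keeps the fold change finite for all-zero genes.
    """
    for s in group_a + group_b:
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} missing from gene count table")
    if counts.isna().any().any():
        raise ValueError("gene count table contains missing values")
    if (counts < 0).any().any():
        raise ValueError("gene counts must be non-negative")
    sub = counts[group_a + group_b].astype(float)
    norm = sub / _size_factors(sub)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"mean_count_a": mean_a, "mean_count_b": mean_b, "log2fc": log2fc}
    ).rename_axis("gene_id")


def partition_genes(
    results: pd.DataFrame,
    events: list[SplicingEvent],
    records: pd.DataFrame,
    min_expressed_mean: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Split genes into (ir_genes, background_genes).

    IR genes have >= 1 RI event significant in the increased direction;
    background genes are expressed genes (normalized mean count above
    ``min_expressed_mean`` in at least one group) with none.
    """
    gene_of = {e.event_id: e.gene_id for e in events}
    inc = results[
        (results["direction"] == "increased") & results["significant"]
    ]
    if "kind" in inc.columns:
        inc = inc[inc["kind"] == "RI"]
    ir_genes = {gene_of[eid] for eid in inc["event_id"] if eid in gene_of}
    expressed = records[
        (records["mean_count_a"] > min_expressed_mean)
        | (records["mean_count_b"] > min_expressed_mean)
    ].index
    ir = sorted(g for g in ir_genes if g in records.index)
    background = sorted(set(expressed) - ir_genes)
    return ir, background


def mw_link_test(
    records: pd.DataFrame,
    ir_genes: list[str],
    background_genes: list[str],
) -> LinkTestResult:
    """Two-sided Mann-Whitney U comparing log2FC of IR genes to
    background genes (exact when both groups have <= 12 genes and no
    ties, tie-corrected normal approximation otherwise)."""
    if not ir_genes or not background_genes:
        raise ValueError("both gene sets must be non-empty")
    x = records.loc[ir_genes, "log2fc"].to_numpy()
    y = records.loc[background_genes, "log2fc"].to_numpy()
    small = len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return LinkTestResult(
        n_ir_genes=len(x),
        n_background_genes=len(y),
        u_statistic=float(res.statistic),
        p=float(res.pvalue),
        median_shift=float(np.median(x) - np.median(y)),
    )


def read_gene_counts(path) -> pd.DataFrame:
    """Gene count TSV: first column gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_gene_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")
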