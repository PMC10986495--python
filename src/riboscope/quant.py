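"""Gene-level counting, median-of-ratios normalization, and log2 fold change.

Differential testing proper is out of scope here: only the standard
size-factor normalization (median over all-nonzero genes of the ratio to the
per-gene geometric mean) and a pseudocounted log2 fold-change estimate are
implemented, so two-condition fold changes are computable without an
external differential-expression package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeBundle
from .ingest import end_positions

PSEUDOCOUNT = 0.5


def _gene_lookup(bundle: GenomeBundle):
    """Per contig/strand: position -> gene row index, -1 intergenic, -2
    ambiguous (overlapping same-strand genes)."""
    lookup = {
        contig: {s: np.full(L, -1, dtype=np.int32) for s in "+-"}
        for contig, L in bundle.contig_lengths().items()
    }
    for i, g in enumerate(bundle.genes):
        arr = lookup[g.contig][g.strand]
        occupied = arr[g.start:g.end] != -1
        arr[g.start:g.end] = np.where(occupied, -2, i)
    return lookup


def count_genes(
    alignments: pd.DataFrame,
    bundle: GenomeBundle,
    end_choice: str = "3p",
    unambiguous_only: bool = True,
) -> tuple[pd.Series, int]:
    """Count each read for the single same-strand gene containing its end.

    Reads landing in no gene, or at a position shared by overlapping
    same-strand genes, are uncounted and tallied. Returns (counts, uncounted).
    """
    df = alignments
    if unambiguous_only and len(df):
        df = df[~df["name"].duplicated(keep=False)]
    lookup = _gene_lookup(bundle)
    gene_ids = [g.gene_id for g in bundle.genes]
    counts = np.zeros(len(gene_ids), dtype=np.int64)
    uncounted = 0
    if len(df):
        ends = end_positions(df, end_choice)
        for (contig, strand), idx in df.groupby(["chrom", "strand"]).indices.items():
            hits = lookup[contig][strand][ends[idx]]
            valid = hits >= 0
            np.add.at(counts, hits[valid], 1)
            uncounted += int((~valid).sum())
    return pd.Series(counts, index=gene_ids, name="count"), uncounted


def build_count_matrix(
    beds: dict[str, pd.DataFrame], bundle: GenomeBundle, **kwargs
) -> tuple[pd.DataFrame, pd.Series]:
    cols, uncounted = {}, {}
    for label, bed in beds.items():
        cols[label], uncounted[label] = count_genes(bed, bundle, **kwargs)
    return pd.DataFrame(cols), pd.Series(uncounted, name="uncounted")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes nonzero in every library."""
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every library; "
            "add a pseudocount or drop sparse libraries"
        )
    sub = mat[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_fold_change(
    counts: pd.DataFrame,
    library_conditions: dict[str, str],
    cond_a: str,
    cond_b: str,
    pseudocount: float = PSEUDOCOUNT,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2(meanB + c) - log2(meanA + c) on normalized counts.

    Repression in condition B gives a negative log2fc; ``fold`` is the
    absolute fold-change magnitude 2**|log2fc|.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors
    libs_a = [l for l, c in library_conditions.items() if c == cond_a and l in counts]
    libs_b = [l for l, c in library_conditions.items() if c == cond_b and l in counts]
    if not libs_a or not libs_b:
        raise ValueError("need at least one library per condition")
    mean_a = norm[libs_a].mean(axis=1)
    mean_b = norm[libs_b].mean(axis=1)
    l2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": l2fc,
            "fold": 2.0 ** l2fc.abs(),
            "direction": np.where(l2fc < 0, "down", np.where(l2fc > 0, "up", "flat")),
        }
    )
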