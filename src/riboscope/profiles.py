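"""Sub-codon phasing and start/stop metagene profiles.

Frame is defined from the annotated start codon — frame f at gene-local
position l means l mod 3 == f — with no P-site offsetting. Metagene
inclusion follows two rules: a gene must be isolated from any other coding
region by at least ``min_isolation`` nt on both flanks, and carry strictly
more than ``min_reads`` mapped reads; each included gene's window is
normalised by its own window mean before the equal-weight average, so a flat
track averages to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBundle
from .ingest import EndTrack, end_positions


@dataclass
class PhasingTable:
    """Frame counts of CDS-assigned read ends, per read length."""

    per_length: pd.DataFrame  # index: length; columns f0, f1, f2
    summary: np.ndarray  # overall frame fractions

    def total(self) -> int:
        return int(self.per_length.values.sum())


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray
    density: np.ndarray
    n_genes: int
    empty: bool = False
    gene_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_density": self.density,
             "n_genes": self.n_genes}
        )


def _frame_lookup(bundle: GenomeBundle) -> dict[str, dict[str, np.ndarray]]:
    """Per-contig/strand arrays: frame at each CDS position, -1 elsewhere."""
    lookup = {
        contig: {"+": np.full(L, -1, dtype=np.int8), "-": np.full(L, -1, dtype=np.int8)}
        for contig, L in bundle.contig_lengths().items()
    }
    for g in bundle.genes:
        if g.length % 3 != 0:
            warnings.warn(f"{g.gene_id}: length not divisible by 3; excluded from phasing")
            continue
        local = np.arange(g.length)
        frames = (local % 3).astype(np.int8)
        if g.strand == "+":
            lookup[g.contig]["+"][g.start:g.end] = frames
        else:
            lookup[g.contig]["-"][g.start:g.end] = frames[::-1]
    return lookup


def phase_decomposition(
    alignments: pd.DataFrame, bundle: GenomeBundle, end_choice: str = "3p"
) -> PhasingTable:
    """Assign each in-CDS read end to a frame, stratified by read length.

    Takes the alignment table (BED6, read length in the score column) rather
    than a prebuilt track because the phasing table is per read length.
    """
    lookup = _frame_lookup(bundle)
    rows: dict[int, np.ndarray] = {}
    if len(alignments):
        ends = end_positions(alignments, end_choice)
        lengths = alignments["score"].values
        for (contig, strand), idx in alignments.groupby(
            ["chrom", "strand"]
        ).indices.items():
            frames = lookup[contig][strand][ends[idx]]
            keep = frames >= 0
            for ln, fr in zip(lengths[idx][keep], frames[keep]):
                rows.setdefault(int(ln), np.zeros(3, dtype=np.int64))[fr] += 1
    per_length = pd.DataFrame(
        {f"f{k}": {ln: v[k] for ln, v in rows.items()} for k in range(3)}
    ).sort_index()
    per_length.index.name = "length"
    totals = per_length.values.sum(axis=0) if len(per_length) else np.zeros(3)
    grand = totals.sum()
    summary = totals / grand if grand else np.full(3, np.nan)
    return PhasingTable(per_length, summary)


def metagene(
    track: EndTrack,
    bundle: GenomeBundle,
    anchor: str = "start",
    window: int = 100,
    min_isolation: int = 50,
    min_reads: int = 10,
) -> MetageneProfile:
    """Equal-weight metagene over qualifying coding genes.

    Genes within ``min_isolation`` nt of another coding region (either
    flank, either strand), with <= ``min_reads`` mapped reads (strictly more
    than ``min_reads`` required), or whose window leaves the contig, are
    excluded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    offsets = np.arange(-window, window + 1)
    vectors = []
    included: list[str] = []
    coding = [g for g in bundle.genes if not g.is_pseudogene]
    for g in coding:
        gap = min(
            (
                max(o.start - g.end, g.start - o.end)
                for o in coding
                if o is not g and o.contig == g.contig
            ),
            default=np.inf,
        )
        if gap < min_isolation:
            continue
        if track.gene_vector(g).sum() <= min_reads:
            continue
        anchor_pos = g.atg_position if anchor == "start" else g.genomic(g.length - 1)
        L = len(bundle.contigs[g.contig])
        if anchor_pos - window < 0 or anchor_pos + window >= L:
            continue
        vec = track.window_vector(g.contig, g.strand, anchor_pos, -window, window)
        m = vec.mean()
        if m == 0:
            continue
        vectors.append(vec / m)
        included.append(g.gene_id)
    if not vectors:
        return MetageneProfile(anchor, offsets, np.zeros(len(offsets)), 0, empty=True)
    density = np.mean(vectors, axis=0)
    return MetageneProfile(anchor, offsets, density, len(vectors), gene_ids=included)
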