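"""Read preprocessing and strand-aware end-coverage tracks.

The preprocessing order is fixed: barcode demultiplexing, then duplicate
removal on the full sequence (UMI still attached, so distinct UMIs survive
and PCR duplicates collapse), then UMI stripping with a minimum-length
filter. ``preprocess_reads`` applies exactly that order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .genome import Gene, GenomeBundle

UMI_PREFIX = 2
UMI_SUFFIX = 5
BARCODE_LEN = 5
MIN_READ_LEN = 5


@dataclass
class RawReadBatch:
    """(read-id, sequence) records from one FASTQ source."""

    records: list[tuple[str, str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "RawReadBatch":
        return cls(io.read_fastq(path), provenance=str(path))


@dataclass
class StripReport:
    n_input: int
    n_unstrippable: int
    n_too_short: int
    n_kept: int
    length_counts: dict[int, int] = field(default_factory=dict)

    def fraction_in(self, lo: int, hi: int) -> float:
        """Fraction of kept footprints with length in [lo, hi] inclusive."""
        total = sum(self.length_counts.values())
        if total == 0:
            return float("nan")
        return sum(v for k, v in self.length_counts.items() if lo <= k <= hi) / total


def demultiplex(batch: RawReadBatch, barcodes: dict[str, str]) -> dict[str, RawReadBatch]:
    """Bin reads by exact match of their last 5 nt; barcode removed on match.

    Returns one batch per label plus an ``unassigned`` bin; every input read
    lands in exactly one bin.
    """
    if "unassigned" in barcodes:
        raise ValueError("'unassigned' is a reserved bin label")
    for label, bc in barcodes.items():
        if len(bc) != BARCODE_LEN:
            raise ValueError(f"barcode {label}={bc!r} is not {BARCODE_LEN} nt")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcode sequences")
    by_seq = {bc: label for label, bc in barcodes.items()}
    bins: dict[str, list[tuple[str, str]]] = {label: [] for label in barcodes}
    bins["unassigned"] = []
    for name, seq in batch.records:
        label = by_seq.get(seq[-BARCODE_LEN:]) if len(seq) >= BARCODE_LEN else None
        if label is None:
            bins["unassigned"].append((name, seq))
        else:
            bins[label].append((name, seq[:-BARCODE_LEN]))
    return {
        label: RawReadBatch(records, provenance=f"{batch.provenance}[{label}]")
        for label, records in bins.items()
    }


def deduplicate(batch: RawReadBatch) -> RawReadBatch:
    """Keep one record per distinct sequence string, first occurrence wins.

    Run before UMI removal: identical footprints with different UMIs are
    distinct sequences and both survive, while true PCR duplicates collapse.
    """
    seen: dict[str, str] = {}
    for name, seq in batch.records:
        if seq not in seen:
            seen[seq] = name
    return RawReadBatch(
        [(name, seq) for seq, name in seen.items()], provenance=batch.provenance
    )


def strip_umi_and_filter(batch: RawReadBatch) -> tuple[RawReadBatch, StripReport]:
    """Remove the 2 nt UMI prefix and 5 nt UMI suffix; drop footprints < 5 nt."""
    kept: list[tuple[str, str]] = []
    n_unstrippable = n_short = 0
    lengths: Counter[int] = Counter()
    for name, seq in batch.records:
        if len(seq) < UMI_PREFIX + UMI_SUFFIX:
            n_unstrippable += 1
            continue
        core = seq[UMI_PREFIX:len(seq) - UMI_SUFFIX]
        if len(core) < MIN_READ_LEN:
            n_short += 1
            continue
        kept.append((name, core))
        lengths[len(core)] += 1
    report = StripReport(
        n_input=len(batch.records),
        n_unstrippable=n_unstrippable,
        n_too_short=n_short,
        n_kept=len(kept),
        length_counts=dict(sorted(lengths.items())),
    )
    return RawReadBatch(kept, provenance=batch.provenance), report


def preprocess_reads(
    batch: RawReadBatch, barcodes: dict[str, str]
) -> tuple[dict[str, RawReadBatch], dict[str, StripReport]]:
    """Fixed pipeline order: demultiplex -> deduplicate -> strip UMI/filter."""
    batches, reports = {}, {}
    for label, b in demultiplex(batch, barcodes).items():
        if label == "unassigned":
            batches[label] = b
            continue
        stripped, report = strip_umi_and_filter(deduplicate(b))
        batches[label] = stripped
        reports[label] = report
    return batches, reports


def filter_contaminants(
    alignments: pd.DataFrame, contaminant_intervals: list[tuple[str, int, int]]
) -> tuple[pd.DataFrame, int]:
    """Drop any read overlapping a contaminant interval by >= 1 nt (either
    strand); returns (survivors, n_removed)."""
    if not len(alignments):
        return alignments, 0
    drop = np.zeros(len(alignments), dtype=bool)
    for contig, cs, ce in contaminant_intervals:
        drop |= (
            (alignments["chrom"].values == contig)
            & (alignments["start"].values < ce)
            & (alignments["end"].values > cs)
        )
    return alignments.loc[~drop].reset_index(drop=True), int(drop.sum())


@dataclass
class EndTrack:
    """Strand-aware per-position counts of a chosen read end for one library."""

    counts: dict[str, dict[str, np.ndarray]]
    end_choice: str  # "5p" | "3p"
    metadata: dict = field(default_factory=dict)

    def vector(self, contig: str, strand: str) -> np.ndarray:
        return self.counts[contig][strand]

    def total(self) -> int:
        return int(sum(v.sum() for d in self.counts.values() for v in d.values()))

    def gene_vector(self, gene: Gene) -> np.ndarray:
        """Per-position counts over the gene body in gene-local 5'->3' order."""
        v = self.counts[gene.contig][gene.strand][gene.start:gene.end]
        return v if gene.strand == "+" else v[::-1]

    def window_vector(self, contig: str, strand: str, anchor: int, lo: int, hi: int) -> np.ndarray:
        """Counts at strand-aware offsets lo..hi (inclusive) around ``anchor``."""
        n = len(self.counts[contig][strand])
        offs = np.arange(lo, hi + 1)
        pos = anchor + offs if strand == "+" else anchor - offs
        out = np.zeros(len(offs))
        ok = (pos >= 0) & (pos < n)
        out[ok] = self.counts[contig][strand][pos[ok]]
        return out

    def scaled(self, factor: float) -> "EndTrack":
        return EndTrack(
            {c: {s: v * factor for s, v in d.items()} for c, d in self.counts.items()},
            self.end_choice,
            dict(self.metadata),
        )

    def mirrored(self) -> "EndTrack":
        """Track under genome mirroring: position p -> L-1-p, strands flipped."""
        return EndTrack(
            {c: {"+": d["-"][::-1].copy(), "-": d["+"][::-1].copy()}
             for c, d in self.counts.items()},
            self.end_choice,
            dict(self.metadata),
        )

    def to_bedgraph(self, outdir: str | Path, prefix: str) -> list[Path]:
        outdir = Path(outdir)
        paths = []
        for contig, per_strand in self.counts.items():
            for strand, tag in (("+", "plus"), ("-", "minus")):
                p = outdir / f"{prefix}.{contig}.{tag}.bedgraph"
                io.write_bedgraph(per_strand[strand], contig, p)
                paths.append(p)
        return paths

    @classmethod
    def from_bedgraph(
        cls, paths: dict[tuple[str, str], str | Path],
        contig_lengths: dict[str, int], end_choice: str, metadata: dict | None = None,
    ) -> "EndTrack":
        counts: dict[str, dict[str, np.ndarray]] = {}
        for (contig, strand), path in paths.items():
            counts.setdefault(contig, {})[strand] = io.read_bedgraph(
                path, contig_lengths[contig]
            )
        for contig, L in contig_lengths.items():
            counts.setdefault(contig, {})
            for strand in "+-":
                counts[contig].setdefault(strand, np.zeros(L))
        return cls(counts, end_choice, metadata or {})


def end_positions(alignments: pd.DataFrame, end_choice: str) -> np.ndarray:
    """Biological end coordinate of each read (strand-aware).

    The 3' end of a minus-strand read is its lower genomic coordinate.
    """
    plus = alignments["strand"].values == "+"
    if end_choice == "3p":
        return np.where(plus, alignments["end"].values - 1, alignments["start"].values)
    if end_choice == "5p":
        return np.where(plus, alignments["start"].values, alignments["end"].values - 1)
    raise ValueError("end_choice must be '5p' or '3p'")


def build_end_track(
    alignments: pd.DataFrame,
    contig_lengths: dict[str, int],
    end_choice: str = "3p",
    unambiguous_only: bool = False,
    metadata: dict | None = None,
) -> EndTrack:
    """One count per retained read at its biological 5' or 3' end.

    ``unambiguous_only`` drops reads whose id occurs on more than one
    alignment line (multi-mappers).
    """
    df = alignments
    if unambiguous_only and len(df):
        df = df[~df["name"].duplicated(keep=False)]
    counts = {
        contig: {"+": np.zeros(L), "-": np.zeros(L)}
        for contig, L in contig_lengths.items()
    }
    if len(df):
        ends = end_positions(df, end_choice)
        for contig in df["chrom"].unique():
            if contig not in contig_lengths:
                raise io.DataFormatError(f"alignment on unknown contig {contig!r}")
        oob = (ends < 0) | (
            ends >= df["chrom"].map(contig_lengths).values
        )
        if oob.any():
            raise io.DataFormatError("alignment end beyond contig bounds")
        for contig, sub in df.groupby("chrom"):
            e = end_positions(sub, end_choice)
            for strand in "+-":
                sel = sub["strand"].values == strand
                np.add.at(counts[contig][strand], e[sel], 1)
    return EndTrack(counts, end_choice, metadata or {})


def read_fate_table(reports: dict[str, StripReport]) -> pd.DataFrame:
    rows = []
    for label, r in reports.items():
        rows.append(
            {
                "library": label,
                "input": r.n_input,
                "unstrippable": r.n_unstrippable,
                "too_short": r.n_too_short,
                "kept": r.n_kept,
                "frac_16_26": r.fraction_in(16, 26),
            }
        )
    return pd.DataFrame(rows)
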