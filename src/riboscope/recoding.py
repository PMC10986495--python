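"""Pseudogene translation flags, ORF re-annotation, and shift efficiency.

A locus is anomalous when its annotated reading frame lacks an ATG first
codon, lacks a terminal stop, or contains an internal stop. Anomalous loci
are ranked by footprint totals; ORF boundaries are then proposed by a
deterministic coverage-explanation score, replacing manual profile review.
Readthrough/frameshift efficiency is the ratio of mean per-nt footprint-end
density downstream of the shift site to that upstream, with 9 nt excluded
at every ORF boundary to avoid initiation/termination peaks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Gene, GenomeBundle, STOP_CODONS
from .ingest import EndTrack

BOUNDARY_EXCLUSION = 9


@dataclass
class PseudogeneFlag:
    gene_id: str
    anomalies: list[str]
    total_footprints: float
    rank: int = 0


@dataclass
class OrfProposal:
    gene_id: str
    start: int  # genomic, 0-based half-open with `end`
    end: int
    strand: str
    in_orf_fraction: float
    uses_ancestral_start: bool
    score: float


@dataclass
class ShiftEstimate:
    locus_id: str
    shift_position: int  # gene-local nt
    upstream_mean: float
    downstream_mean: float
    efficiency: float | None  # None when upstream density is zero

    @property
    def defined(self) -> bool:
        return self.efficiency is not None


def sequence_anomalies(cds: str) -> list[str]:
    """The three annotation anomalies, evaluated on the coding-strand CDS."""
    anomalies = []
    codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if not codons:
        return ["non_ATG_start", "missing_stop"]
    if codons[0] != "ATG":
        anomalies.append("non_ATG_start")
    if codons[-1] not in STOP_CODONS:
        anomalies.append("missing_stop")
    if any(c in STOP_CODONS for c in codons[:-1]):
        anomalies.append("internal_stop")
    return anomalies


def flag_pseudogenes(bundle: GenomeBundle, track: EndTrack) -> list[PseudogeneFlag]:
    """Scan every annotated gene for the three anomalies; rank anomalous
    genes by descending footprint total (ties stable by coordinate)."""
    flags = []
    for g in sorted(bundle.genes, key=lambda g: (g.contig, g.start)):
        anomalies = sequence_anomalies(bundle.cds_sequence(g))
        if anomalies:
            flags.append(
                PseudogeneFlag(g.gene_id, anomalies, float(track.gene_vector(g).sum()))
            )
    flags.sort(key=lambda f: -f.total_footprints)
    for i, f in enumerate(flags):
        f.rank = i + 1
    return flags


def flags_frame(flags: list[PseudogeneFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [f.gene_id for f in flags],
            "anomalies": [",".join(f.anomalies) for f in flags],
            "total_footprints": [f.total_footprints for f in flags],
            "rank": [f.rank for f in flags],
        }
    )


class InsufficientCoverage(ValueError):
    pass


def _candidate_orfs(seq: str) -> list[tuple[int, int, bool]]:
    """(start, end, is_ancestral) local half-open candidate ORFs: the
    ancestral (annotated) start plus every in-locus ATG, each run to its
    first in-frame stop (or locus end if none)."""
    starts = {0: True}
    for m in re.finditer("ATG", seq):
        starts.setdefault(m.start(), False)
    orfs = []
    for s, ancestral in sorted(starts.items()):
        end = None
        for i in range(s, len(seq) - 2, 3):
            if seq[i:i + 3] in STOP_CODONS and i > s:
                end = i + 3
                break
        orfs.append((s, end if end is not None else len(seq), ancestral))
    return orfs


def propose_orf(
    gene: Gene,
    track: EndTrack,
    bundle: GenomeBundle,
    min_footprints: int = 20,
    length_penalty: float = 0.1,
) -> OrfProposal:
    """Pick the candidate ORF best explaining the footprint profile.

    score = (fraction of locus footprints inside the ORF)
            - length_penalty * ORF_length / locus_length.
    Ties prefer the ancestral start, then the longest, then the 5'-most.
    """
    vec = track.gene_vector(gene)
    total = vec.sum()
    if total < min_footprints:
        raise InsufficientCoverage(
            f"{gene.gene_id}: {int(total)} footprints < {min_footprints}"
        )
    seq = bundle.cds_sequence(gene)
    L = len(seq)
    best = None
    for s, e, ancestral in _candidate_orfs(seq):
        frac = float(vec[s:e].sum() / total)
        score = frac - length_penalty * (e - s) / L
        key = (score, ancestral, e - s, -s)
        if best is None or key > best[0]:
            best = (key, (s, e, ancestral, frac, score))
    s, e, ancestral, frac, score = best[1]
    g_start = gene.genomic(s) if gene.strand == "+" else gene.genomic(e - 1)
    g_end = gene.genomic(e - 1) + 1 if gene.strand == "+" else gene.genomic(s) + 1
    return OrfProposal(
        gene_id=gene.gene_id,
        start=g_start,
        end=g_end,
        strand=gene.strand,
        in_orf_fraction=frac,
        uses_ancestral_start=ancestral,
        score=score,
    )


def shift_efficiency(
    gene: Gene,
    track: EndTrack,
    shift_position: int,
    boundary_exclusion: int = BOUNDARY_EXCLUSION,
) -> ShiftEstimate:
    """Readthrough efficiency = mean downstream / mean upstream end density.

    Upstream ORF region: [exclusion, shift - exclusion); downstream:
    [shift + exclusion, L - exclusion). Efficiency is undefined (None) when
    the upstream mean is zero.
    """
    vec = track.gene_vector(gene)
    L = len(vec)
    m = boundary_exclusion
    up = vec[m:shift_position - m]
    down = vec[shift_position + m:L - m]
    if len(up) == 0 or len(down) == 0:
        raise ValueError("boundary exclusion exhausts an ORF region")
    up_mean = float(up.mean())
    down_mean = float(down.mean())
    eff = None if up_mean == 0 else down_mean / up_mean
    return ShiftEstimate(gene.gene_id, shift_position, up_mean, down_mean, eff)


@dataclass
class MotifReport:
    slippery: list[dict] = field(default_factory=list)
    homopolymer_runs: list[dict] = field(default_factory=list)
    at_rich_windows: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.slippery or self.homopolymer_runs or self.at_rich_windows)


def detect_slippery(seq: str, min_run: int = 8, at_window: int = 13, at_min: int = 12) -> MotifReport:
    """Scan for -1 frameshift-prone contexts.

    Reports X_XXY_YYZ heptamers (X and Y each a homotrinucleotide; X may
    equal Y, covering homopolymeric slip sites), homopolymeric A/T runs >=
    min_run (transcriptional-slippage candidates), and windows of
    ``at_window`` nt containing >= ``at_min`` A/T.
    """
    seq = seq.upper()
    report = MotifReport()
    for i in range(len(seq) - 6):
        h = seq[i:i + 7]
        if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            report.slippery.append(
                {"position": i, "motif": f"{h[0]}_{h[0]}{h[0]}{h[3]}_{h[3]}{h[3]}{h[6]}",
                 "X": h[0], "Y": h[3], "Z": h[6]}
            )
    for m in re.finditer(r"A{%d,}|T{%d,}" % (min_run, min_run), seq):
        report.homopolymer_runs.append(
            {"position": m.start(), "length": m.end() - m.start(), "base": seq[m.start()]}
        )
    at = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_at = (at == ord("A")) | (at == ord("T"))
    if len(seq) >= at_window:
        sums = np.convolve(is_at.astype(int), np.ones(at_window, dtype=int), "valid")
        in_window = sums >= at_min
        # report the first position of each run of qualifying windows
        for i in np.flatnonzero(in_window):
            if i == 0 or not in_window[i - 1]:
                report.at_rich_windows.append(
                    {"position": int(i), "at_count": int(sums[i]), "window": at_window}
                )
    return report
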