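"""Shared coordinate frame: contig sequences plus gene models.

All coordinates in this package are 0-based, half-open and strand-explicit.
"Upstream" always means 5' of a feature on its own strand. GFF3's 1-based
inclusive convention is converted only at the I/O boundary (see ``io``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Gene:
    """One annotated gene (CDS-like feature) on the shared coordinate frame.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``tss`` is the
    genomic position of the transcript 5' end where known (simulated or
    called), and ``leader`` the 5' UTR length in nt.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    is_pseudogene: bool = False
    tss: int | None = None
    utr3: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def atg_position(self) -> int:
        """Genomic coordinate of the first nucleotide of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def leader(self) -> int | None:
        if self.tss is None:
            return None
        if self.strand == "+":
            return self.start - self.tss
        return self.tss - (self.end - 1)

    def local(self, pos: int) -> int:
        """Gene-local coordinate (0 at start codon, increasing 5'->3')."""
        return pos - self.start if self.strand == "+" else self.end - 1 - pos

    def genomic(self, local: int) -> int:
        return self.start + local if self.strand == "+" else self.end - 1 - local

    def transcript_interval(self) -> tuple[int, int]:
        """Genomic half-open interval covered by the transcript."""
        t5 = self.tss if self.tss is not None else self.atg_position
        if self.strand == "+":
            return t5, self.end + self.utr3
        return self.start - self.utr3, t5 + 1


@dataclass
class GenomeBundle:
    """Contig sequences and gene models sharing one coordinate frame."""

    contigs: dict[str, str]
    genes: list[Gene]
    contaminant_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(f"{g.gene_id} exceeds contig bounds")

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def cds_sequence(self, gene: Gene | str) -> str:
        """Coding-strand sequence of the gene, 5'->3'."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        seq = self.contigs[gene.contig][gene.start:gene.end]
        return seq if gene.strand == "+" else revcomp(seq)

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "contig": [g.contig for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "is_pseudogene": [g.is_pseudogene for g in self.genes],
                "tss": [g.tss for g in self.genes],
            }
        )

    def mirrored(self) -> "GenomeBundle":
        """Reverse-complement every contig and flip all features.

        Used by strand-symmetry tests: position p maps to L-1-p.
        """
        contigs = {name: revcomp(seq) for name, seq in self.contigs.items()}
        genes = []
        for g in self.genes:
            L = len(self.contigs[g.contig])
            genes.append(
                Gene(
                    gene_id=g.gene_id,
                    contig=g.contig,
                    start=L - g.end,
                    end=L - g.start,
                    strand="-" if g.strand == "+" else "+",
                    is_pseudogene=g.is_pseudogene,
                    tss=None if g.tss is None else L - 1 - g.tss,
                    utr3=g.utr3,
                )
            )
        contaminants = [
            (c, len(self.contigs[c]) - e, len(self.contigs[c]) - s)
            for c, s, e in self.contaminant_intervals
        ]
        return GenomeBundle(contigs, genes, contaminants)
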