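"""Format readers/writers shared by all stages.

FASTA/FASTQ go through Biopython. BED6 and bedGraph are held as pandas
DataFrames / numpy vectors; both are 0-based half-open on disk and in memory.
GFF3 is converted between its native 1-based inclusive coordinates and the
package's 0-based half-open frame at this boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .genome import Gene, GenomeBundle

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class DataFormatError(ValueError):
    """Malformed input data (exit code 3 at the CLI)."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Return (read-id, sequence) pairs; truncated records name their index."""
    records: list[tuple[str, str]] = []
    try:
        for title, seq, _qual in FastqGeneralIterator(str(path)):
            records.append((title.split()[0], seq.upper()))
    except ValueError as exc:
        raise DataFormatError(
            f"{path}: malformed FASTQ at record index {len(records)}: {exc}"
        ) from exc
    return records


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------- GFF3

def write_gff3(bundle: GenomeBundle, path: str | Path) -> None:
    """Write gene models as CDS features; pseudogenes carry pseudo=true."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in bundle.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(bundle.genes, key=lambda g: (g.contig, g.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.is_pseudogene:
                attrs.append("pseudo=true")
            if g.tss is not None:
                attrs.append(f"tss={g.tss + 1}")
            if g.utr3:
                attrs.append(f"utr3={g.utr3}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "riboscope",
                        "CDS",
                        str(g.start + 1),  # GFF3 is 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path, contigs: dict[str, str] | None = None) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DataFormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start1, end1, _score, strand, _phase, attr = fields
            if ftype not in ("CDS", "gene", "pseudogene"):
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise DataFormatError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in attr.split(";") if "=" in kv
            )
            if contigs is not None and end > len(contigs.get(contig, "")):
                raise DataFormatError(f"{path}:{lineno}: coordinate beyond contig end")
            tss = int(attrs["tss"]) - 1 if "tss" in attrs else None
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"feature{lineno}"),
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    is_pseudogene=attrs.get("pseudo", "").lower() == "true"
                    or ftype == "pseudogene",
                    tss=tss,
                    utr3=int(attrs.get("utr3", 0)),
                )
            )
    return genes


# ---------------------------------------------------------------- BED6

def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            header=None,
            names=BED_COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "name": str, "score": np.int64, "strand": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"{path}: malformed BED6: {exc}") from exc
    if len(df) and not df["strand"].isin(["+", "-"]).all():
        bad = int((~df["strand"].isin(["+", "-"])).idxmax()) + 1
        raise DataFormatError(f"{path}: line {bad}: bad strand field")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED_COLUMNS].to_csv(str(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(vector: np.ndarray, contig: str, path: str | Path) -> None:
    """Run-length encode one per-position vector (0-based half-open)."""
    v = np.asarray(vector)
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(v)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{contig}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path: str | Path, contig_length: int) -> np.ndarray:
    vec = np.zeros(contig_length)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataFormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            _chrom, s, e, val = fields
            s, e = int(s), int(e)
            if e > contig_length:
                raise DataFormatError(f"{path}:{lineno}: interval beyond contig end")
            vec[s:e] = float(val)
    return vec


# ---------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
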