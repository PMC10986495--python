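"""Synthetic genomes and Ribo-seq / RNA-seq / Rend-seq read sets with known truth.

The generator emulates the observable structure of a bacterial
ribosome-profiling experiment on a phage-infected host:

* short footprints whose length distribution puts ~80% of reads in 16-26 nt;
* triplet periodicity of footprint 3' ends relative to the reading frame;
* a bimodal 5' leader-length distribution (leaderless <5 nt, leadered ~40 nt)
  with no leaders of 4-14 nt;
* Rend-seq libraries with sharp 5'-end peaks at transcription start sites,
  calibrated so the expected peak / mean-body end-count ratio equals
  ``rendseq_end_enrichment``;
* two-condition expression fold changes, per-gene silhouette perturbations
  under condition B, and two-ORF frameshift loci with a fixed readthrough
  efficiency.

Read placement is Poisson/multinomial per position: the simplest noise model
consistent with count data, which keeps recovery tolerances computable.
Every emitted read is attributed to its generating gene in an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import Gene, GenomeBundle, STOP_CODONS, revcomp

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

NON_ATG_STARTS = ["GTG", "TTG", "CTG"]

ANOMALY_TYPES = ["internal_stop", "non_ATG_start", "missing_stop"]


class CapacityError(ValueError):
    """Requested genes cannot be packed into the requested genome length."""


def default_read_length_dist() -> dict[int, float]:
    """Footprint length distribution over 15-45 nt.

    Calibrated so that exactly 80% of the probability mass falls in the
    16-26 nt range, matching the short bacterial footprints this package
    is designed around; the mode sits at 20 nt and the >26 nt tail decays
    geometrically.
    """
    inner = {16 + i: w for i, w in enumerate([2, 4, 7, 10, 9, 8, 6, 4, 3, 2, 1.5])}
    s = sum(inner.values())
    dist = {k: 0.80 * v / s for k, v in inner.items()}
    outer = {15: 1.0}
    for k in range(27, 46):
        outer[k] = 1.5 * 0.75 ** (k - 27)
    s = sum(outer.values())
    for k, v in outer.items():
        dist[k] = 0.20 * v / s
    return dict(sorted(dist.items()))


@dataclass
class LeaderModel:
    """Mixture model for 5' leader lengths.

    60% leaderless (0..leaderless_max nt) and 40% Normal(40, 8) truncated at
    >=15 nt by default; lengths inside ``forbidden_range`` (inclusive) are
    never emitted, reproducing the empty 4-14 nt gap.
    """

    fraction_leaderless: float = 0.6
    leaderless_max: int = 3
    leadered_mean: float = 40.0
    leadered_sd: float = 8.0
    forbidden_range: tuple[int, int] = (4, 14)


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 100
    genome_length: int | None = None
    leader_model: LeaderModel = field(default_factory=LeaderModel)
    read_length_dist: dict[int, float] = field(default_factory=default_read_length_dist)
    periodicity: tuple[float, float, float] = (0.8, 0.1, 0.1)
    expression_sigma: float = 0.5  # log-normal sd of per-gene expression
    fold_changes: dict[str, float] = field(default_factory=dict)
    n_perturbed: int = 0
    perturb_factor: float = 8.0
    frameshift_loci: list[dict] = field(default_factory=list)
    depth: int = 100_000
    rendseq_end_enrichment: float = 30.0
    conditions: tuple[str, str] = ("A", "B")
    fraction_minus: float = 0.4
    min_spacing: int = 150
    gene_length_mean: float = 450.0
    gene_length_sd: float = 120.0
    gene_length_min: int = 90
    pseudogene_fraction: float = 0.1
    contaminant_fraction: float = 0.0
    utr3: int = 15
    edge_margin: int = 200
    rnaseq_read_length: tuple[int, int] = (20, 40)

    def validate(self) -> None:
        p = np.asarray(self.periodicity, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("periodicity must be a probability vector (sum 1)")
        d = np.array(list(self.read_length_dist.values()), dtype=float)
        if d.min() < 0 or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("read_length_dist must be a probability vector (sum 1)")
        for fc in self.fold_changes.values():
            if fc <= 0:
                raise ValueError("fold changes must be > 0")
        for locus in self.frameshift_loci:
            if not 0.0 <= locus["efficiency"] <= 1.0:
                raise ValueError("frameshift efficiency must be in [0, 1]")
        if self.rendseq_end_enrichment < 1:
            raise ValueError("rendseq_end_enrichment must be >= 1")
        if not 0.0 <= self.leader_model.fraction_leaderless <= 1.0:
            raise ValueError("fraction_leaderless must be in [0, 1]")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")

    def to_yaml(self, path) -> None:
        obj = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        if "leader_model" in obj:
            lm = obj["leader_model"]
            if "forbidden_range" in lm:
                lm["forbidden_range"] = tuple(lm["forbidden_range"])
            obj["leader_model"] = LeaderModel(**lm)
        for key in ("periodicity", "conditions", "rnaseq_read_length"):
            if key in obj:
                obj[key] = tuple(obj[key])
        if "read_length_dist" in obj:
            obj["read_length_dist"] = {int(k): float(v) for k, v in obj["read_length_dist"].items()}
        cfg = cls(**obj)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """What the simulator actually did, for recovery tests."""

    tss_positions: dict[str, int] = field(default_factory=dict)
    leaders: dict[str, int] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    true_silhouette_diff: list[str] = field(default_factory=list)
    true_efficiencies: dict[str, float] = field(default_factory=dict)
    pseudogene_anomalies: dict[str, list[str]] = field(default_factory=dict)
    audit: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json_obj(cls, obj: dict) -> "GroundTruth":
        return cls(**obj)


@dataclass
class SimulatedLibrary:
    label: str
    assay: str
    condition: str
    replicate: int
    bed: pd.DataFrame
    fastq: list[tuple[str, str]] | None
    audit: dict[str, int]
    barcode: str | None = None


# ------------------------------------------------------------------ genome


def _draw_leader(rng: np.random.Generator, lm: LeaderModel) -> int:
    lo, hi = lm.forbidden_range
    for _ in range(1000):
        if rng.random() < lm.fraction_leaderless:
            leader = int(rng.integers(0, lm.leaderless_max + 1))
        else:
            leader = int(round(rng.normal(lm.leadered_mean, lm.leadered_sd)))
            if leader < 15:
                continue
        if lo <= leader <= hi:
            continue
        if leader >= 0:
            return leader
    raise RuntimeError("leader model rejects everything; check forbidden_range")


def simulate_genome(config: SimConfig) -> tuple[GenomeBundle, GroundTruth]:
    """Generate a genome with ATG/stop-bounded genes on both strands.

    A designated subset is made pseudogene-like by injecting exactly one of:
    an internal stop codon, a non-ATG start, or a missing terminal stop.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    n_codons = np.maximum(
        config.gene_length_min // 3,
        np.round(rng.normal(config.gene_length_mean, config.gene_length_sd, n) / 3).astype(int),
    )
    lengths = 3 * n_codons

    spacings = rng.integers(config.min_spacing, config.min_spacing + 150, n)
    spacings[0] = 0
    starts = config.edge_margin + np.cumsum(spacings) + np.concatenate(
        ([0], np.cumsum(lengths[:-1]))
    )
    ends = starts + lengths
    contaminant_zone = 400
    needed = int(ends[-1]) + config.edge_margin + contaminant_zone
    if config.genome_length is not None and config.genome_length < needed:
        raise CapacityError(
            f"{n} genes need >= {needed} bp, genome_length={config.genome_length}"
        )
    genome_len = config.genome_length or needed

    n_minus = int(round(config.fraction_minus * n))
    strands = np.array(["+"] * (n - n_minus) + ["-"] * n_minus)
    rng.shuffle(strands)

    n_pseudo = int(round(config.pseudogene_fraction * n))
    pseudo_idx = set(rng.choice(n, size=n_pseudo, replace=False).tolist())

    seq = rng.choice(list("ACGT"), size=genome_len)
    genes: list[Gene] = []
    truth = GroundTruth(fold_changes=dict(config.fold_changes))

    for i in range(n):
        gene_id = f"g{i + 1:04d}"
        codons = [
            "ATG",
            *rng.choice(SENSE_CODONS, size=n_codons[i] - 2).tolist(),
            str(rng.choice(STOP_CODONS)),
        ]
        anomalies: list[str] = []
        if i in pseudo_idx:
            kind = str(rng.choice(ANOMALY_TYPES))
            anomalies = [kind]
            if kind == "internal_stop":
                codons[int(rng.integers(1, len(codons) - 1))] = str(rng.choice(STOP_CODONS))
            elif kind == "non_ATG_start":
                codons[0] = str(rng.choice(NON_ATG_STARTS))
            else:
                codons[-1] = str(rng.choice(SENSE_CODONS))
        cds = "".join(codons)
        placed = cds if strands[i] == "+" else revcomp(cds)
        seq[starts[i]:ends[i]] = list(placed)

        leader = _draw_leader(rng, config.leader_model)
        gene = Gene(
            gene_id=gene_id,
            contig="chr",
            start=int(starts[i]),
            end=int(ends[i]),
            strand=str(strands[i]),
            is_pseudogene=bool(anomalies),
            utr3=config.utr3,
        )
        gene.tss = gene.start - leader if gene.strand == "+" else gene.end - 1 + leader
        genes.append(gene)
        truth.tss_positions[gene_id] = gene.tss
        truth.leaders[gene_id] = leader
        truth.expression[gene_id] = float(rng.lognormal(0.0, config.expression_sigma))
        if anomalies:
            truth.pseudogene_anomalies[gene_id] = anomalies

    contaminants = [("chr", genome_len - contaminant_zone + 50, genome_len - 50)]
    bundle = GenomeBundle({"chr": "".join(seq)}, genes, contaminants)

    gene_ids = {g.gene_id for g in genes}
    for locus in config.frameshift_loci:
        if locus["gene"] not in gene_ids:
            raise ValueError(f"frameshift locus names unknown gene {locus['gene']}")
        g = bundle.gene(locus["gene"])
        if not 0 < locus["shift_position"] < g.length:
            raise ValueError("shift_position outside gene body")
        truth.true_efficiencies[locus["gene"]] = float(locus["efficiency"])

    if config.n_perturbed:
        coding = [g.gene_id for g in genes if not g.is_pseudogene]
        picked = rng.choice(len(coding), size=config.n_perturbed, replace=False)
        truth.true_silhouette_diff = sorted(coding[j] for j in picked)
    return bundle, truth


# ------------------------------------------------------------------ reads


def _library_rng(config: SimConfig, assay: str, condition: str, replicate: int):
    key = [config.seed, sum(map(ord, assay)), sum(map(ord, condition)), replicate]
    return np.random.default_rng(key)


def _umi(rng: np.random.Generator, k: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, k)])


def _gene_weights(truth: GroundTruth, bundle: GenomeBundle, config: SimConfig,
                  condition: str, per_nt: bool = False) -> np.ndarray:
    w = np.array([truth.expression[g.gene_id] for g in bundle.genes])
    if condition == config.conditions[1]:
        w *= np.array(
            [truth.fold_changes.get(g.gene_id, 1.0) for g in bundle.genes]
        )
    if per_nt:
        w *= np.array([g.transcript_interval()[1] - g.transcript_interval()[0]
                       for g in bundle.genes])
    return w


def simulate_riboseq(
    bundle: GenomeBundle,
    truth: GroundTruth,
    config: SimConfig,
    condition: str = "A",
    replicate: int = 1,
    with_fastq: bool = False,
    barcode: str = "ACGTC",
    depth: int | None = None,
) -> SimulatedLibrary:
    """Emit aligned footprints (BED6) and optionally the raw multiplexed reads.

    3'-end positions step codon-wise with frame offsets drawn from
    ``config.periodicity``; per-codon rates carry the silhouette perturbation
    (condition B, designated genes: downstream half x perturb_factor) and the
    frameshift attenuation (codons past the shift site x efficiency). Raw
    reads are laid out as 2 nt UMI + footprint + 5 nt UMI + 5 nt barcode.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; expected {config.conditions}")
    depth = config.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = _library_rng(config, "ribo", condition, replicate)
    shift_by_gene = {l["gene"]: l for l in config.frameshift_loci}

    w = _gene_weights(truth, bundle, config, condition)
    contig_len = len(bundle.contigs["chr"])
    n_cont = (
        rng.binomial(depth, config.contaminant_fraction)
        if config.contaminant_fraction and bundle.contaminant_intervals
        else 0
    )
    per_gene = rng.multinomial(depth - n_cont, w / w.sum())

    len_values = np.array(list(config.read_length_dist.keys()))
    len_probs = np.array(list(config.read_length_dist.values()))
    periodicity = np.asarray(config.periodicity, dtype=float)

    chroms, bstarts, bends, names, scores, strands_out = [], [], [], [], [], []
    audit: dict[str, int] = {}
    for gi, gene in enumerate(bundle.genes):
        ng = int(per_gene[gi])
        audit[gene.gene_id] = ng
        if ng == 0:
            continue
        ncod = gene.length // 3
        cw = np.ones(ncod)
        if condition == config.conditions[1] and gene.gene_id in truth.true_silhouette_diff:
            cw[ncod // 2:] *= config.perturb_factor
        if gene.gene_id in shift_by_gene:
            locus = shift_by_gene[gene.gene_id]
            cw[locus["shift_position"] // 3:] *= locus["efficiency"]
        codon = rng.choice(ncod, size=ng, p=cw / cw.sum())
        frame = rng.choice(3, size=ng, p=periodicity)
        local3 = np.minimum(3 * codon + frame, gene.length - 1)
        length = rng.choice(len_values, size=ng, p=len_probs)
        if gene.strand == "+":
            e3 = gene.start + local3
            bs, be = e3 - length + 1, e3 + 1
        else:
            e3 = gene.end - 1 - local3
            bs, be = e3, e3 + length
        bs = np.clip(bs, 0, contig_len)
        be = np.clip(be, 0, contig_len)
        chroms.append(np.full(ng, gene.contig))
        bstarts.append(bs)
        bends.append(be)
        names.append(np.array([f"ribo:{condition}{replicate}:{gene.gene_id}:{k}" for k in range(ng)]))
        scores.append(be - bs)
        strands_out.append(np.full(ng, gene.strand))

    if n_cont:
        contig, cs, ce = bundle.contaminant_intervals[0]
        audit["contaminant"] = n_cont
        u5 = rng.integers(cs, ce, n_cont)
        length = rng.choice(len_values, size=n_cont, p=len_probs)
        strand = np.where(rng.random(n_cont) < 0.5, "+", "-")
        bs = np.where(strand == "+", u5, u5 - length + 1)
        be = bs + length
        bs = np.clip(bs, 0, contig_len)
        be = np.clip(be, 0, contig_len)
        chroms.append(np.full(n_cont, contig))
        bstarts.append(bs)
        bends.append(be)
        names.append(np.array([f"ribo:{condition}{replicate}:rRNA:{k}" for k in range(n_cont)]))
        scores.append(be - bs)
        strands_out.append(strand)

    bed = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else np.array([], dtype=str),
            "start": np.concatenate(bstarts).astype(np.int64) if bstarts else [],
            "end": np.concatenate(bends).astype(np.int64) if bends else [],
            "name": np.concatenate(names) if names else [],
            "score": np.concatenate(scores).astype(np.int64) if scores else [],
            "strand": np.concatenate(strands_out) if strands_out else [],
        }
    )

    fastq = None
    if with_fastq:
        seq = bundle.contigs["chr"]
        fastq = []
        for row in bed.itertuples(index=False):
            frag = seq[row.start:row.end]
            if row.strand == "-":
                frag = revcomp(frag)
            fastq.append((row.name, _umi(rng, 2) + frag + _umi(rng, 5) + barcode))

    label = f"ribo_{condition}_{replicate}"
    lib = SimulatedLibrary(label, "ribo", condition, replicate, bed, fastq, audit, barcode)
    truth.audit[label] = audit
    return lib


def _simulate_coverage_library(
    bundle: GenomeBundle,
    truth: GroundTruth,
    config: SimConfig,
    assay: str,
    condition: str,
    replicate: int,
    enrichment: float,
    depth: int | None = None,
) -> SimulatedLibrary:
    depth = config.depth if depth is None else depth
    rng = _library_rng(config, assay, condition, replicate)
    w = _gene_weights(truth, bundle, config, condition, per_nt=True)
    per_gene = rng.multinomial(depth, w / w.sum())
    contig_len = len(bundle.contigs["chr"])
    lo, hi = config.rnaseq_read_length

    chroms, bstarts, bends, names, scores, strands_out = [], [], [], [], [], []
    audit: dict[str, int] = {}
    for gi, gene in enumerate(bundle.genes):
        ng = int(per_gene[gi])
        audit[gene.gene_id] = ng
        if ng == 0:
            continue
        t0, t1 = gene.transcript_interval()
        L = t1 - t0
        # peak fraction chosen so E[TSS count] / E[body per-position count]
        # equals the requested enrichment exactly
        p = (enrichment - 1.0) / (L + enrichment - 1.0) if enrichment > 1 else 0.0
        n_peak = rng.binomial(ng, p) if p > 0 else 0
        u = np.concatenate(
            [np.zeros(n_peak, dtype=np.int64), rng.integers(0, L, ng - n_peak)]
        )
        length = rng.integers(lo, hi + 1, ng)
        if gene.strand == "+":
            g5 = t0 + u
            bs, be = g5, g5 + length
        else:
            g5 = t1 - 1 - u
            bs, be = g5 - length + 1, g5 + 1
        bs = np.clip(bs, 0, contig_len)
        be = np.clip(be, 0, contig_len)
        chroms.append(np.full(ng, gene.contig))
        bstarts.append(bs)
        bends.append(be)
        names.append(np.array([f"{assay}:{condition}{replicate}:{gene.gene_id}:{k}" for k in range(ng)]))
        scores.append(be - bs)
        strands_out.append(np.full(ng, gene.strand))

    bed = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else np.array([], dtype=str),
            "start": np.concatenate(bstarts).astype(np.int64) if bstarts else [],
            "end": np.concatenate(bends).astype(np.int64) if bends else [],
            "name": np.concatenate(names) if names else [],
            "score": np.concatenate(scores).astype(np.int64) if scores else [],
            "strand": np.concatenate(strands_out) if strands_out else [],
        }
    )
    label = f"{assay}_{condition}_{replicate}"
    lib = SimulatedLibrary(label, assay, condition, replicate, bed, None, audit)
    truth.audit[label] = audit
    return lib


def simulate_rendseq(
    bundle: GenomeBundle,
    truth: GroundTruth,
    config: SimConfig,
    depth: int | None = None,
) -> SimulatedLibrary:
    """End-enriched RNA-seq: uniform body coverage plus a sharp 5'-end spike
    at each TSS, calibrated to ``config.rendseq_end_enrichment``."""
    return _simulate_coverage_library(
        bundle, truth, config, "rend", config.conditions[0], 1,
        config.rendseq_end_enrichment, depth,
    )


def simulate_rnaseq(
    bundle: GenomeBundle,
    truth: GroundTruth,
    config: SimConfig,
    condition: str = "A",
    replicate: int = 1,
    depth: int | None = None,
) -> SimulatedLibrary:
    """Uniform transcript coverage at expression-proportional rates; no frame
    structure and no end enrichment."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; expected {config.conditions}")
    return _simulate_coverage_library(
        bundle, truth, config, "rna", condition, replicate, 1.0, depth,
    )


def simulate_count_matrix(
    seed: int,
    n_genes: int = 200,
    focal_expected: float = 10_000.0,
    focal_fold: float = 36.0,
    n_replicates: int = 2,
    base_mean: float = 2_000.0,
    base_sigma: float = 0.7,
):
    """Two-condition Poisson count matrix with one focal repressed gene.

    Gene 0 has expected count ``focal_expected`` in condition A and is
    repressed ``focal_fold``-fold in condition B; all other genes are
    unchanged. Returns (counts DataFrame, library->condition map).
    """
    import pandas as pd  # local alias keeps the module import graph flat

    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(base_mean), base_sigma, n_genes)
    base[0] = focal_expected
    fold = np.ones(n_genes)
    fold[0] = 1.0 / focal_fold
    cols, conditions = {}, {}
    for cond, mult in (("A", np.ones(n_genes)), ("B", fold)):
        for rep in range(1, n_replicates + 1):
            label = f"{cond}{rep}"
            cols[label] = rng.poisson(base * mult)
            conditions[label] = cond
    counts = pd.DataFrame(cols, index=[f"g{i:04d}" for i in range(n_genes)])
    return counts, conditions


def simulate_frameshift_locus(
    efficiency: float,
    seed: int,
    upstream_nt: int = 300,
    downstream_nt: int = 600,
    depth: int = 10_000,
) -> tuple[GenomeBundle, GroundTruth, SimulatedLibrary]:
    """One two-ORF locus: upstream ORF at full rate, downstream continuation
    at ``efficiency`` times that rate. Used by the recovery analyses."""
    total = upstream_nt + downstream_nt
    config = SimConfig(
        seed=seed,
        n_genes=1,
        gene_length_mean=float(total),
        gene_length_sd=0.0,
        pseudogene_fraction=0.0,
        frameshift_loci=[
            {"gene": "g0001", "shift_position": upstream_nt, "efficiency": efficiency}
        ],
        depth=depth,
    )
    bundle, truth = simulate_genome(config)
    lib = simulate_riboseq(bundle, truth, config, condition="A", replicate=1)
    return bundle, truth, lib
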