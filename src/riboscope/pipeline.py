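"""End-to-end run orchestration from a single YAML config.

The run config names the genome, annotation and per-library alignment files
plus stage parameters; ``run_pipeline`` executes ingest -> end tracks ->
the requested analysis stages and writes TSV outputs and a machine-readable
run report (seed, thresholds in effect, read fates, per-stage outputs).
Every threshold actually used is echoed into the report: parameter
provenance matters when downstream numbers depend on curation-style cutoffs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io, ingest, profiles, quant, recoding, silhouette, tss
from .genome import GenomeBundle


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


@dataclass
class LibrarySpec:
    label: str
    assay: str  # ribo | rna | rend
    condition: str
    replicate: int
    alignments: str
    excluded: bool = False


@dataclass
class RunConfig:
    genome: str
    annotation: str
    libraries: list[LibrarySpec]
    outdir: str = "riboscope_out"
    seed: int = 0
    contaminants: str | None = None
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                obj = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            libs = [LibrarySpec(**l) for l in obj.pop("libraries")]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: bad or missing libraries table: {exc}") from exc
        labels = [l.label for l in libs]
        if len(set(labels)) != len(labels):
            raise ConfigError("library labels must be unique")
        try:
            return cls(libraries=libs, **obj)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.genome, self.annotation, self.contaminants,
                      *(l.alignments for l in self.libraries)]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"missing input paths: {missing}")


def _read_contaminants(path: str | None) -> list[tuple[str, int, int]]:
    if path is None:
        return []
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                fields = line.split("\t")
                out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; halts naming the failing stage."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "read_fates": {},
        "parameters": config.stages,
    }

    stage = "load"
    try:
        contigs = io.read_fasta(config.genome)
        genes = io.read_gff3(config.annotation, contigs)
        bundle = GenomeBundle(contigs, genes, _read_contaminants(config.contaminants))

        stage = "ingest"
        tracks: dict[str, ingest.EndTrack] = {}
        beds = {}
        active = [l for l in config.libraries if not l.excluded]
        for lib in active:
            bed = io.read_bed(lib.alignments)
            n_in = len(bed)
            bed, n_removed = ingest.filter_contaminants(bed, bundle.contaminant_intervals)
            beds[lib.label] = bed
            end_choice = "5p" if lib.assay == "rend" else "3p"
            tracks[lib.label] = ingest.build_end_track(
                bed, bundle.contig_lengths(), end_choice=end_choice,
                unambiguous_only=True,
                metadata={"assay": lib.assay, "condition": lib.condition,
                          "replicate": lib.replicate},
            )
            report["read_fates"][lib.label] = {
                "input": n_in, "contaminant": n_removed,
                "placed": tracks[lib.label].total(),
            }

        ribo = [l for l in active if l.assay == "ribo"]
        stages = config.stages

        if stages.get("phasing", True) and ribo:
            stage = "phasing"
            for lib in ribo:
                table = profiles.phase_decomposition(beds[lib.label], bundle)
                path = outdir / f"phasing.{lib.label}.tsv"
                table.per_length.to_csv(path, sep="\t")
                report["stages"].setdefault("phasing", {})[lib.label] = {
                    "fractions": [None if f != f else float(f) for f in table.summary],
                    "output": str(path),
                }

        if stages.get("metagene", True) and ribo:
            stage = "metagene"
            params = stages.get("metagene") if isinstance(stages.get("metagene"), dict) else {}
            for lib in ribo:
                for anchor in ("start", "stop"):
                    prof = profiles.metagene(
                        tracks[lib.label], bundle, anchor=anchor, **params
                    )
                    path = outdir / f"metagene.{anchor}.{lib.label}.tsv"
                    prof.to_frame().to_csv(path, sep="\t", index=False)
                    report["stages"].setdefault("metagene", {})[
                        f"{lib.label}.{anchor}"
                    ] = {"n_genes": prof.n_genes, "output": str(path)}

        sil_cfg = stages.get("silhouette")
        if sil_cfg:
            stage = "silhouette"
            state_a, state_b = sil_cfg["state_a"], sil_cfg["state_b"]
            by_state = {
                s: [tracks[l.label] for l in ribo if l.condition == s]
                for s in (state_a, state_b)
            }
            table = silhouette.compare_all(
                by_state, bundle, margin=sil_cfg.get("margin", 0.0)
            )
            path = outdir / "silhouette.tsv"
            table.to_csv(path, sep="\t", index=False)
            report["stages"]["silhouette"] = {
                "n_flagged": int(table["flagged"].sum()), "output": str(path)
            }

        rend = [l for l in active if l.assay == "rend"]
        if stages.get("tss", True) and rend:
            stage = "tss"
            params = stages.get("tss") if isinstance(stages.get("tss"), dict) else {}
            candidates = tss.call_tss(tracks[rend[0].label], bundle, **params)
            path = outdir / "tss.tsv"
            candidates.to_csv(path, sep="\t", index=False)
            summary = tss.leader_summary(candidates)
            report["stages"]["tss"] = {
                "n_candidates": int(len(candidates)),
                "class_counts": summary["class_counts"],
                "output": str(path),
            }

        if stages.get("pseudogenes", True) and ribo:
            stage = "pseudogenes"
            flags = recoding.flag_pseudogenes(bundle, tracks[ribo[0].label])
            path = outdir / "pseudogene_flags.tsv"
            recoding.flags_frame(flags).to_csv(path, sep="\t", index=False)
            report["stages"]["pseudogenes"] = {
                "n_flagged": len(flags), "output": str(path)
            }

        quant_cfg = stages.get("quant")
        if quant_cfg and ribo:
            stage = "quant"
            counts, uncounted = quant.build_count_matrix(
                {l.label: beds[l.label] for l in ribo}, bundle
            )
            counts.to_csv(outdir / "counts.tsv", sep="\t")
            fc = quant.log2_fold_change(
                counts,
                {l.label: l.condition for l in ribo},
                quant_cfg["cond_a"],
                quant_cfg["cond_b"],
            )
            path = outdir / "fold_changes.tsv"
            fc.to_csv(path, sep="\t")
            report["stages"]["quant"] = {
                "uncounted": {k: int(v) for k, v in uncounted.items()},
                "output": str(path),
            }
    except (ConfigError, KeyError) as exc:
        raise ConfigError(f"stage {stage!r}: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
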