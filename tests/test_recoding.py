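"""Pseudogene anomaly flags, ORF proposals, shift efficiency, slippery motifs."""

import numpy as np
import pytest

from riboscope import ingest, recoding, sim
from riboscope.genome import Gene, GenomeBundle
from riboscope.sim import SENSE_CODONS


def make_cds(n_codons, rng, start="ATG", stop="TAA"):
    body = "".join(rng.choice(SENSE_CODONS, n_codons - 2))
    return start + body + stop


def bundle_from_cds(cds, strand="+", pad=200, seed=0):
    from riboscope.genome import revcomp

    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    placed = cds if strand == "+" else revcomp(cds)
    seq = left + placed + right
    gene = Gene("gX", "chr", pad, pad + len(cds), strand)
    return GenomeBundle({"chr": seq}, [gene])


def track_from_local_counts(bundle, gene, local_counts):
    L = len(bundle.contigs["chr"])
    counts = {"chr": {"+": np.zeros(L), "-": np.zeros(L)}}
    vec = np.asarray(local_counts, dtype=float)
    if gene.strand == "+":
        counts["chr"]["+"][gene.start:gene.end] = vec
    else:
        counts["chr"]["-"][gene.start:gene.end] = vec[::-1]
    return ingest.EndTrack(counts, "3p")


class TestAnomalies:
    def test_internal_stop_at_codon_50_of_100(self):
        rng = np.random.default_rng(5)
        codons = ["ATG"] + list(rng.choice(SENSE_CODONS, 98)) + ["TAA"]
        codons[49] = "TAA"
        assert recoding.sequence_anomalies("".join(codons)) == ["internal_stop"]

    def test_clean_gene_unflagged(self):
        rng = np.random.default_rng(6)
        assert recoding.sequence_anomalies(make_cds(100, rng)) == []

    @pytest.mark.parametrize(
        "start,stop,expected",
        [("GTG", "TAA", ["non_ATG_start"]), ("ATG", "AAA", ["missing_stop"]),
         ("TTG", "CCC", ["non_ATG_start", "missing_stop"])],
    )
    def test_boundary_anomalies(self, start, stop, expected):
        rng = np.random.default_rng(7)
        assert recoding.sequence_anomalies(make_cds(60, rng, start, stop)) == expected

    def test_simulated_flags_match_designations_exactly(self, small_sim, ribo_track):
        bundle, truth = small_sim
        flags = recoding.flag_pseudogenes(bundle, ribo_track)
        assert {f.gene_id: f.anomalies for f in flags} == truth.pseudogene_anomalies

    def test_clean_annotation_returns_empty(self):
        cfg = sim.SimConfig(seed=51, n_genes=10, pseudogene_fraction=0.0)
        bundle, _ = sim.simulate_genome(cfg)
        L = len(bundle.contigs["chr"])
        track = ingest.EndTrack({"chr": {"+": np.zeros(L), "-": np.zeros(L)}}, "3p")
        assert recoding.flag_pseudogenes(bundle, track) == []

    def test_ranked_by_descending_footprints(self, small_sim, ribo_track):
        bundle, _ = small_sim
        flags = recoding.flag_pseudogenes(bundle, ribo_track)
        totals = [f.total_footprints for f in flags]
        assert totals == sorted(totals, reverse=True)
        assert [f.rank for f in flags] == list(range(1, len(flags) + 1))


class TestProposeOrf:
    def truncated_case(self, strand="+"):
        """120-codon locus with an internal stop after codon 59 and reads
        only over the translated first half."""
        rng = np.random.default_rng(8)
        codons = ["ATG"] + list(rng.choice(SENSE_CODONS, 118)) + ["TAA"]
        codons[59] = "TGA"
        cds = "".join(codons)
        bundle = bundle_from_cds(cds, strand=strand)
        gene = bundle.genes[0]
        local = np.zeros(len(cds))
        local[:180] = 2.0  # uniform over the truncated ORF
        return bundle, gene, track_from_local_counts(bundle, gene, local)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_recovers_truncation_point(self, strand):
        bundle, gene, track = self.truncated_case(strand)
        prop = recoding.propose_orf(gene, track, bundle)
        assert prop.uses_ancestral_start
        start_local = gene.local(prop.start if strand == "+" else prop.end - 1)
        end_local = gene.local(prop.end - 1 if strand == "+" else prop.start) + 1
        assert (start_local, end_local) == (0, 180)

    def test_agrees_with_exhaustive_enumeration(self):
        bundle, gene, track = self.truncated_case()
        seq = bundle.cds_sequence(gene)
        vec = track.gene_vector(gene)
        best, best_key = None, None
        for s, e, ancestral in recoding._candidate_orfs(seq):
            frac = vec[s:e].sum() / vec.sum()
            score = frac - 0.1 * (e - s) / len(seq)
            key = (score, ancestral, e - s, -s)
            if best_key is None or key > best_key:
                best_key, best = key, (s, e)
        prop = recoding.propose_orf(gene, track, bundle)
        assert (gene.local(prop.start), gene.local(prop.end - 1) + 1) == best

    def test_invariant_under_uniform_density_scaling(self):
        bundle, gene, track = self.truncated_case()
        p1 = recoding.propose_orf(gene, track, bundle)
        p2 = recoding.propose_orf(gene, track.scaled(7.5), bundle)
        assert (p1.start, p1.end, p1.score) == (p2.start, p2.end, pytest.approx(p2.score))

    def test_insufficient_coverage_raises(self):
        bundle, gene, _ = self.truncated_case()
        empty = track_from_local_counts(bundle, gene, np.zeros(gene.length))
        with pytest.raises(recoding.InsufficientCoverage):
            recoding.propose_orf(gene, empty, bundle)


class TestShiftEfficiency:
    def flat_case(self, up, down, L=900, shift=300):
        rng = np.random.default_rng(9)
        cds = make_cds(L // 3, rng)
        bundle = bundle_from_cds(cds)
        gene = bundle.genes[0]
        local = np.concatenate([np.full(shift, up), np.full(L - shift, down)])
        return gene, track_from_local_counts(bundle, gene, local)

    def test_identical_densities_give_one(self):
        gene, track = self.flat_case(3.0, 3.0)
        assert recoding.shift_efficiency(gene, track, 300).efficiency == pytest.approx(1.0)

    def test_zero_downstream_gives_zero(self):
        gene, track = self.flat_case(3.0, 0.0)
        assert recoding.shift_efficiency(gene, track, 300).efficiency == 0.0

    def test_zero_upstream_is_undefined(self):
        gene, track = self.flat_case(0.0, 3.0)
        est = recoding.shift_efficiency(gene, track, 300)
        assert est.efficiency is None and not est.defined

    def test_boundary_exclusion_ignores_terminal_peaks(self):
        gene, track = self.flat_case(2.0, 1.0)
        # giant artefact peaks inside the 9 nt exclusion zones
        vec = track.counts["chr"]["+"]
        vec[gene.start] = vec[gene.start + 300 + 2] = vec[gene.end - 1] = 1e6
        est = recoding.shift_efficiency(gene, track, 300)
        assert est.efficiency == pytest.approx(0.5)

    @pytest.mark.parametrize("eff", [0.05, 0.06, 0.18, 0.5])
    def test_generative_efficiency_recovered_with_small_bias(self, eff):
        bundle, truth, lib = sim.simulate_frameshift_locus(eff, seed=61, depth=60_000)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "3p")
        est = recoding.shift_efficiency(bundle.gene("g0001"), track, 300)
        assert est.efficiency == pytest.approx(eff, abs=0.01)


class TestSlippery:
    def test_classical_heptamer_detected_in_shift_context(self):
        report = recoding.detect_slippery("GCAATTTTTTTTAAGC")
        motifs = {m["motif"] for m in report.slippery}
        assert any(m.startswith("T_TTT") for m in motifs)
        assert report.homopolymer_runs  # the 8-T run
        assert report.at_rich_windows  # >=12 A/T within 13 nt

    def test_structured_sequence_without_runs_is_clean(self):
        report = recoding.detect_slippery("ACGTAGCTAGCATCGATCGTACGATCGA")
        assert report.empty

    def test_twelve_at_in_thirteen_nt_flagged(self):
        seq = "GC" + "ATATATATATAGA" + "GC"  # 12 A/T within the 13-mer
        report = recoding.detect_slippery(seq)
        assert report.at_rich_windows
        assert report.at_rich_windows[0]["at_count"] >= 12
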