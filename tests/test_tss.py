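"""TSS scores against the closed-form window definitions, calling, leaders."""

import numpy as np
import pandas as pd
import pytest

from riboscope import ingest, sim, tss
from riboscope.sim import LeaderModel, SimConfig


def brute_peak(v, n, w=100):
    total = sum(v[n + m] for m in range(-w, w + 1))
    return 0.0 if total == 0 else v[n] / (total / 200)


def brute_delta(v, n, w=100, eps=1e-3):
    up = sum(v[n + m] for m in range(-w, 0 + 1))
    down = sum(v[n + m] for m in range(1, w + 1))
    return (up + eps) / (down + eps)


class TestFormulaArithmetic:
    def test_uniform_track_peak_is_200_over_201(self):
        v = np.full(500, 7.0)
        assert tss.peak_density_profile(v)[250] == pytest.approx(200 / 201)

    def test_isolated_spike_peak_is_200(self):
        v = np.zeros(500)
        v[250] = 13.0
        assert tss.peak_density_profile(v)[250] == pytest.approx(200.0)

    def test_all_zero_window_peak_defined_as_zero(self):
        v = np.zeros(500)
        assert tss.peak_density_profile(v)[250] == 0.0

    def test_all_zero_delta_is_one(self):
        v = np.zeros(500)
        assert tss.delta_density_profile(v)[250] == pytest.approx(1.0)

    def test_sharp_onset_delta_is_tiny(self):
        # upstream empty, downstream 1/nt, nothing at n itself
        v = np.zeros(500)
        v[251:] = 1.0
        assert tss.delta_density_profile(v)[250] == pytest.approx(
            0.001 / 100.001, rel=1e-9
        )

    def test_uniform_track_delta_includes_position_itself(self):
        c = 3.0
        v = np.full(500, c)
        assert tss.delta_density_profile(v)[250] == pytest.approx(
            (101 * c + 0.001) / (100 * c + 0.001)
        )

    def test_window_truncated_by_edge_is_undefined(self):
        v = np.ones(500)
        assert np.isnan(tss.peak_density_profile(v)[50])

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.poisson(0.6, 260).astype(float)
            v[rng.integers(100, 160)] += rng.integers(0, 40)
            pk = tss.peak_density_profile(v)
            dd = tss.delta_density_profile(v)
            for n in range(100, 160):
                assert pk[n] == pytest.approx(brute_peak(v, n), rel=1e-12)
                assert dd[n] == pytest.approx(brute_delta(v, n), rel=1e-12)

    def test_minus_strand_orientation_flips_upstream(self):
        v = np.zeros(500)
        v[251:] = 1.0  # rises to the genomic right
        # on the minus strand "upstream" is the high-coordinate side
        dd_minus = tss.delta_density_profile(v, strand="-")[250]
        assert dd_minus == pytest.approx((100.0 + 0.001) / 0.001, rel=1e-9)


class TestInvariances:
    def test_peak_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(2.0, 400).astype(float)
        np.testing.assert_allclose(
            tss.peak_density_profile(v * 10), tss.peak_density_profile(v)
        )

    def test_delta_exactly_invariant_when_eps_scales_too(self):
        rng = np.random.default_rng(2)
        v = rng.poisson(2.0, 400).astype(float)
        np.testing.assert_allclose(
            tss.delta_density_profile(v * 10, eps=0.01),
            tss.delta_density_profile(v, eps=0.001),
        )

    def test_delta_asymptotically_invariant_on_dense_track(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(5.0, 400).astype(float) + 1
        np.testing.assert_allclose(
            tss.delta_density_profile(v * 10),
            tss.delta_density_profile(v),
            rtol=1e-3,
        )


class TestPrefilter:
    def make_vec(self, count_at_n, window_mean, n=250, size=500):
        v = np.zeros(size)
        v[n] = count_at_n
        pad = window_mean * 201 - count_at_n
        if pad > 0:
            v[n + 1] = pad
        return v

    def test_boundary_passes_at_exactly_5_reads_and_mean_point_one(self):
        v = self.make_vec(5, 0.1)
        assert tss.prefilter_mask(v)[250]

    def test_fails_below_5_reads_despite_dense_window(self):
        v = self.make_vec(4, 10.0)
        assert not tss.prefilter_mask(v)[250]

    def test_fails_below_mean_density(self):
        v = self.make_vec(5, 0.099)
        assert not tss.prefilter_mask(v)[250]

    def test_edge_positions_excluded(self):
        v = np.full(500, 100.0)
        mask = tss.prefilter_mask(v)
        assert not mask[:100].any() and not mask[-100:].any()
        assert mask[100:400].all()


class TestCalling:
    def spike_track(self, positions, heights, size=1000, background=1.0):
        v = np.full(size, background)
        for p, h in zip(positions, heights):
            v[p] += h
        return ingest.EndTrack({"chr": {"+": v, "-": np.zeros(size)}}, "5p")

    def bundle_with_gene(self, start=520, end=640, size=1000):
        from tests.conftest import make_toy_bundle

        return make_toy_bundle((("gA", start, end, "+"),), contig_len=size)

    def test_close_candidates_collapse_to_strongest(self):
        track = self.spike_track([498, 500], [200, 300])
        bundle = self.bundle_with_gene()
        out = tss.call_tss(track, bundle, max_delta=10.0)
        assert list(out["position"]) == [500]

    def test_tied_peaks_collapse_to_five_prime_most(self):
        track = self.spike_track([498, 500], [300, 300])
        bundle = self.bundle_with_gene()
        out = tss.call_tss(track, bundle, max_delta=10.0)
        assert list(out["position"]) == [498]

    def test_tss_at_start_codon_classified_leaderless(self):
        track = self.spike_track([520], [300])
        bundle = self.bundle_with_gene(start=520)
        out = tss.call_tss(track, bundle, max_delta=10.0)
        assert out.loc[0, "gene"] == "gA"
        assert out.loc[0, "leader_length"] == 0
        assert tss.classify_leader(0) == "leaderless"

    def test_candidate_without_downstream_gene_retained_unassigned(self):
        track = self.spike_track([500], [300])
        bundle = self.bundle_with_gene(start=520)
        out = tss.call_tss(track, bundle, max_delta=10.0, max_leader_span=10)
        assert out.loc[0, "gene"] is None

    def test_default_simulation_recovery(self):
        cfg = SimConfig(seed=29, n_genes=60, depth=80_000)
        bundle, truth = sim.simulate_genome(cfg)
        lib = sim.simulate_rendseq(bundle, truth, cfg)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "5p")
        out = tss.call_tss(track, bundle)
        called = set(out["position"])
        true_pos = set(truth.tss_positions.values())
        recall = len(called & true_pos) / len(true_pos)
        precision = len(called & true_pos) / len(called)
        assert precision >= 0.9 and recall >= 0.9

    def test_mirror_maps_candidates_with_identical_scores(self):
        cfg = SimConfig(seed=31, n_genes=20, depth=50_000)
        bundle, truth = sim.simulate_genome(cfg)
        lib = sim.simulate_rendseq(bundle, truth, cfg)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "5p")
        out = tss.call_tss(track, bundle)
        out_m = tss.call_tss(track.mirrored(), bundle.mirrored())
        L = len(bundle.contigs["chr"])
        fwd = out.sort_values("position")
        mir = out_m.assign(position=L - 1 - out_m["position"]).sort_values("position")
        np.testing.assert_array_equal(fwd["position"].values, mir["position"].values)
        np.testing.assert_allclose(fwd["peak_density"].values, mir["peak_density"].values)
        np.testing.assert_allclose(fwd["delta_density"].values, mir["delta_density"].values)

    def test_null_track_yields_no_candidates(self):
        cfg = SimConfig(seed=37, n_genes=40, depth=150_000, rendseq_end_enrichment=1.0)
        bundle, truth = sim.simulate_genome(cfg)
        lib = sim.simulate_rendseq(bundle, truth, cfg)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "5p")
        out = tss.call_tss(track, bundle)
        genome_mb = len(bundle.contigs["chr"]) / 1e6
        assert len(out) <= max(1, genome_mb)


class TestLeaderSummary:
    def test_forbidden_range_simulation_has_empty_gap(self):
        cfg = SimConfig(seed=41, n_genes=80, depth=100_000)
        bundle, truth = sim.simulate_genome(cfg)
        lib = sim.simulate_rendseq(bundle, truth, cfg)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "5p")
        out = tss.call_tss(track, bundle)
        summary = tss.leader_summary(out)
        assert summary["class_counts"]["anomalous"] == 0
        assert summary["gap_empty"]

    def test_class_proportions_recover_mixture_fraction(self):
        cfg = SimConfig(seed=43, n_genes=100, depth=150_000)
        bundle, truth = sim.simulate_genome(cfg)
        lib = sim.simulate_rendseq(bundle, truth, cfg)
        track = ingest.build_end_track(lib.bed, bundle.contig_lengths(), "5p")
        summary = tss.leader_summary(tss.call_tss(track, bundle))
        n = summary["n_assigned"]
        frac = summary["class_counts"]["leaderless"] / n
        # binomial 3-sigma band around the 0.6 mixture weight
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)

    def test_uniform_leaders_make_single_mode(self):
        cands = pd.DataFrame(
            {"gene": ["g1", "g2", "g3"], "leader_length": [40, 40, 40]}
        )
        summary = tss.leader_summary(cands)
        assert summary["histogram"] == {40: 3}
        assert summary["class_counts"] == {"leaderless": 0, "leadered": 3, "anomalous": 0}
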