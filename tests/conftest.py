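import numpy as np
import pytest

from riboscope import sim, ingest
from riboscope.genome import Gene, GenomeBundle


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    return sim.SimConfig(seed=7, n_genes=30, depth=20_000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    bundle, truth = sim.simulate_genome(small_config)
    return bundle, truth


@pytest.fixture(scope="session")
def ribo_library(small_sim, small_config):
    bundle, truth = small_sim
    return sim.simulate_riboseq(bundle, truth, small_config, "A", 1, with_fastq=True)


@pytest.fixture(scope="session")
def ribo_track(small_sim, ribo_library):
    bundle, _ = small_sim
    return ingest.build_end_track(
        ribo_library.bed, bundle.contig_lengths(), end_choice="3p"
    )


def make_toy_bundle(
    gene_specs=(("gA", 100, 160, "+"),),
    contig_len=400,
    seed=0,
) -> GenomeBundle:
    """Tiny hand-positioned bundle; each gene gets a clean ATG..stop CDS."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=contig_len)
    genes = []
    for gene_id, start, end, strand in gene_specs:
        n_codons = (end - start) // 3
        cds = "ATG" + "".join(rng.choice(sim.SENSE_CODONS, n_codons - 2)) + "TAA"
        from riboscope.genome import revcomp

        placed = cds if strand == "+" else revcomp(cds)
        seq[start:end] = list(placed)
        genes.append(Gene(gene_id, "chr", start, end, strand))
    return GenomeBundle({"chr": "".join(seq)}, genes)


@pytest.fixture
def toy_bundle():
    return make_toy_bundle()
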