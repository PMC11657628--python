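import numpy as np
import pytest

from divomics.genomic_io import GenotypeTable, ReferenceGenome
from divomics.synthetic_data import SimulationConfig, simulate_all, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale config: quick enough for per-test simulation."""
    return SimulationConfig(
        seed=7,
        n_contigs=2,
        contig_length=100_000,
        n_genes=6,
        n_loci=600,
        n_dmr=6,
        n_cnv_segments=4,
        n_input_reads=60_000,
        n_qtl=2,
        qtl_length_min=5_000,
        qtl_length_max=10_000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full default-config dataset, shared across the session."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_genome(small_config):
    genome, genes, repeats, qtls, islands, truth_genes = simulate_genome(small_config)
    return genome


def make_table(dosages, groups, contigs=None, positions=None, ref=None, alt=None):
    """Build a GenotypeTable from a (samples x loci) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_loci = dosages.shape
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        groups=list(groups),
        contig=contigs if contigs is not None else ["c1"] * n_loci,
        pos=positions if positions is not None else list(range(10, 10 + 10 * n_loci, 10)),
        ref=ref if ref is not None else ["A"] * n_loci,
        alt=alt if alt is not None else ["T"] * n_loci,
        dosage=dosages,
    )


@pytest.fixture
def toy_genome():
    return ReferenceGenome({"c1": "AACGTTACGTAACTGGCCAT", "c2": "TTTTCGTTTT"})
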