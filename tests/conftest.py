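import numpy as np
import pytest

from chimerakit.annotation_io import AnnotationIndex, GeneModel, Genome, GenomeSequence
from chimerakit.synthetic import FusionSpec, SimulationConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_index():
    """Two-contig, four-gene annotation with known boundaries and UTRs."""
    genes = [
        GeneModel("GA", "chr1", "+", [(100, 200), (300, 400), (500, 700)],
                  utr3=[(620, 700)], cds=[(100, 200), (300, 400), (500, 620)]),
        GeneModel("GB", "chr1", "+", [(1000, 1200), (1400, 1600)],
                  utr3=[(1500, 1600)], cds=[(1000, 1200), (1400, 1500)]),
        GeneModel("GC", "chr1", "-", [(5000, 5200), (5400, 5600)],
                  utr3=[(5000, 5080)], cds=[(5080, 5200), (5400, 5600)]),
        GeneModel("GD", "chr2", "+", [(200, 400), (600, 800)]),
    ]
    return AnnotationIndex(genes)


@pytest.fixture
def toy_genome(rng):
    def random_seq(n, r):
        return "".join("ACGT"[i] for i in r.integers(0, 4, n))

    r = np.random.default_rng(7)
    return Genome(
        {
            "chr1": GenomeSequence("chr1", random_seq(6000, r)),
            "chr2": GenomeSequence("chr2", random_seq(1000, r)),
        }
    )


def small_config(**overrides) -> SimulationConfig:
    """A compact full-feature simulation used across tests."""
    defaults = dict(
        seed=101,
        n_patients=8,
        genes_per_contig=15,
        contig_lengths=(120_000, 120_000),
        fusions=[
            FusionSpec("E/E", "read-through", 8, 4.0),
            FusionSpec("E/M", "intra-chromosomal", 4, 1.0),
            FusionSpec("M/E", "inter-chromosomal", 6, 1.0),
            FusionSpec("M/M", "read-through", 5, 1.0),
            FusionSpec("E/M", "inter-chromosomal", 5, 1.0, in_utr3=True),
        ],
        n_decoys=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_result(tmp_path_factory):
    """One shared small simulation with short and long reads."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_all(small_config(), out)
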