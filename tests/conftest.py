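import pytest

from occupeak.simulate import SimulationConfig, simulate_study

SMALL_KWARGS = dict(
    seed=7,
    n_chromosomes=2,
    chrom_length=400_000,
    n_genes=30,
    gene_length_min=5_000,
    gene_length_max=12_000,
    peaks_per_cell=2,
    n_up=6,
    n_down=4,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    """A small synthetic study, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_study(small_config, outdir)
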