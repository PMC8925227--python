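import pytest

from stresslnc.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-scale dataset that still exercises every planted feature."""
    return SimulationConfig(
        seed=11,
        n_chroms=4,
        chrom_length=400_000,
        n_coding_genes=30,
        n_lnc_per_class={"lincRNA": 30, "intronic": 4, "antisense": 4},
        n_decoys=24,
        n_cis_pairs=10,
        n_trans_pairs=8,
        n_mirna_sites=6,
        frac_known=0.15,
    )


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_all(small_config, outdir)
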