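import pytest

from tadresponse import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimConfig(seed=11, n_chrom=2, chrom_length=20_000_000)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_results(small_sim):
    from tadresponse import TadResponseModel

    return TadResponseModel.from_simulation(small_sim).fit(
        n_perm=999, dip_null=199, seed=7
    )
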