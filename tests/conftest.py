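import pytest

from lvsplicemap import SpliceSiteCatalog, build_vector, library_config


@pytest.fixture(scope="session")
def plv():
    return build_vector("pLV")


@pytest.fixture(scope="session")
def plv_catalog(plv):
    return SpliceSiteCatalog.from_genome(plv)


@pytest.fixture(scope="session")
def plv_sim_clean():
    """A wobble-free, truncation-free pLV library (5' ends complete)."""
    from lvsplicemap import simulate

    cfg = library_config("pLV", n_reads=600, seed=42, wobble_sd=0.0, truncation_mean=0.0)
    records, truth = simulate(cfg)
    return cfg, records, truth
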