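import numpy as np
import pytest

from ampliclock import bundled_clock, bundled_regions
from ampliclock.simdata import GenerativeClock, ReadSimConfig, simulate_reads


@pytest.fixture(scope="session")
def regions():
    return bundled_regions()


@pytest.fixture(scope="session")
def clock_model():
    return bundled_clock()


@pytest.fixture(scope="session")
def region_by_gene(regions):
    return {r.gene_name: r for r in regions}


@pytest.fixture(scope="session")
def noise_free_gen(clock_model):
    return GenerativeClock.from_model(clock_model, beta_noise_sd=0.0)


def make_region_betas(region, value=None, by_position=None):
    """Beta map for one region: constant or per-position overrides."""
    betas = {pos: (50.0 if value is None else float(value))
             for pos in region.cpg_positions}
    if by_position:
        betas.update(by_position)
    return betas


@pytest.fixture
def clean_sim():
    """Error-free simulation helper: perfect conversion, no sequencing error."""

    def _run(region, betas, depth=100, seed=0, **kwargs):
        cfg = ReadSimConfig(
            depth_per_region=depth,
            seq_error_rate=0.0,
            conversion_failure_rate=0.0,
            overconversion_rate=0.0,
            seed=seed,
            **kwargs,
        )
        return simulate_reads(region, betas, cfg, sample_id="T")

    return _run
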