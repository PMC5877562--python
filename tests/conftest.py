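"""Shared fixtures: small synthetic studies generated at test time."""

import pytest

from plastomics import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 17 kb quadripartite genome, 5 targets + 1 tier."""
    return SimulationConfig(
        seed=42,
        lsc_len=12_000,
        irb_len=3_000,
        ssc_len=2_000,
        n_target=5,
        tier_sizes=(5,),
        tier_depths=(0.03,),
        n_diagnostic=5,
        n_extended=10,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero branch lengths outside the planting step: planted variation is
    the only variation, so recovery must be exact."""
    config = SimulationConfig(
        seed=7,
        lsc_len=8_000,
        irb_len=2_000,
        ssc_len=1_500,
        n_target=4,
        tier_sizes=(4,),
        crown_length=0.0,
        tier_depths=(0.0,),
        n_diagnostic=5,
        n_extended=6,
        extended_length=0.0,
    )
    return simulate_study(config)
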