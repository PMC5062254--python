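"""Shared fixtures: a fast small-design world and the full default design.

World generation is the expensive step, so worlds are built once per
session and reused; score draws (cheap) are redrawn per test as needed.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meshreview import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CONFIG = sd.DGPConfig(
    n_proposals=30,
    n_evaluators=24,
    block_size=5,
    invitations_per_stratum=5,
    vocab_size=120,
    n_domain_terms=30,
    n_bridge_terms=30,
    corpus_size=300,
    evaluator_pubs_mean=25.0,
)


@pytest.fixture(scope="session")
def small_config() -> sd.DGPConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_world(small_config) -> sd.SyntheticWorld:
    return sd.generate_world(small_config, seed=7)


@pytest.fixture(scope="session")
def small_data(small_world, small_config):
    draw = sd.generate_scores(small_world, small_world.features, small_config, seed=0)
    return sd.assemble_analysis_table(small_world, draw.table)


@pytest.fixture(scope="session")
def default_config() -> sd.DGPConfig:
    return sd.DGPConfig()


@pytest.fixture(scope="session")
def default_world(default_config) -> sd.SyntheticWorld:
    """One full-size world (150 proposals, 142 evaluators, 2,130 pairs)."""
    return sd.generate_world(default_config, seed=1)


@pytest.fixture(scope="session")
def default_data(default_world, default_config):
    draw = sd.generate_scores(
        default_world, default_world.features, default_config, seed=0
    )
    return sd.assemble_analysis_table(default_world, draw.table)


@pytest.fixture(scope="session")
def recovery_worlds(default_config):
    """Twenty full-size worlds shared by every recovery experiment."""
    return [sd.generate_world(default_config, seed=100 + k) for k in range(20)]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2718)
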