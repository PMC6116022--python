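"""Shared fixtures.

The expensive benchmark screens (800 neutral blocks; 800+200 mixed
fixtures at three compensatory-mutation rates, plus their decoy runs)
are session-scoped so every test shares one computation.  Screens run
on the plus strand, matching the decoy-FDR protocol, which is estimated
on the plus strand and assumed equal on the minus strand.
"""

from __future__ import annotations

import numpy as np
import pytest

from strucscreen import (
    FixtureConfig,
    RunConfig,
    generate_screen_fixture,
    run_decoy_screen,
    run_screen,
)

BENCH_SEED = 42
RUN_SEED = 7


def make_run_config() -> RunConfig:
    return RunConfig(seed=RUN_SEED, strands=("+",))


@pytest.fixture(scope="session")
def small_fixture():
    """Small mixed benchmark for cheap end-to-end tests."""
    return generate_screen_fixture(
        FixtureConfig(n_neutral_blocks=60, n_implant_blocks=15), seed=1
    )


@pytest.fixture(scope="session")
def small_screen(small_fixture):
    return run_screen(
        small_fixture.blocks, small_fixture.genomes, make_run_config()
    )


@pytest.fixture(scope="session")
def mixed_fixture():
    return generate_screen_fixture(FixtureConfig(), seed=BENCH_SEED)


@pytest.fixture(scope="session")
def mixed_screen(mixed_fixture):
    return run_screen(
        mixed_fixture.blocks, mixed_fixture.genomes, make_run_config()
    )


@pytest.fixture(scope="session")
def mixed_decoy(mixed_fixture):
    return run_decoy_screen(
        mixed_fixture.blocks, mixed_fixture.genomes, make_run_config()
    )


@pytest.fixture(scope="session")
def neutral_fixture():
    return generate_screen_fixture(
        FixtureConfig(n_implant_blocks=0), seed=BENCH_SEED
    )


@pytest.fixture(scope="session")
def neutral_screen(neutral_fixture):
    return run_screen(
        neutral_fixture.blocks, neutral_fixture.genomes, make_run_config()
    )


@pytest.fixture(scope="session")
def neutral_decoy(neutral_fixture):
    return run_decoy_screen(
        neutral_fixture.blocks, neutral_fixture.genomes, make_run_config()
    )


@pytest.fixture(scope="session")
def rate_screens(mixed_screen, mixed_fixture):
    """Recall screens at compensatory rates 0.2, 0.5, 0.8 (0.5 reuses
    the default mixed screen; neutral blocks are shared bit-identically
    between the fixtures)."""
    out = {0.5: (mixed_screen, mixed_fixture)}
    for rate in (0.2, 0.8):
        fx = generate_screen_fixture(
            FixtureConfig(compensatory_rate=rate), seed=BENCH_SEED
        )
        out[rate] = (run_screen(fx.blocks, fx.genomes, make_run_config()), fx)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
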