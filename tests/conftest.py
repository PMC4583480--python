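"""Shared fixtures.

The full-scale study simulation (two libraries of 100k reads, fixed seed) is
expensive, so it runs once per session and is shared by the end-to-end and
recovery tests.
"""

from __future__ import annotations

import pytest

from trichomir.pipeline import run_synthetic
from trichomir.synthetic_data import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def default_sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1, n_reads=100_000)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory, default_sim_config):
    """Bundle, simulated libraries and pipeline results at full study scale."""
    out = tmp_path_factory.mktemp("full_run")
    return run_synthetic(out, default_sim_config)


@pytest.fixture(scope="session")
def small_bundle():
    """A reference bundle at default sizes (cheap: no read simulation)."""
    return generate_reference(SimulationConfig(seed=3))
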