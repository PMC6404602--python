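"""Shared fixtures: a small zero-noise benchmark and its pipeline run.

The heavy fixtures are session-scoped so the simulated genome and the
pipeline run on it are produced once and shared across test modules.
"""

from dataclasses import replace

import numpy as np
import pytest

from optscaf.config import PipelineConfig
from optscaf.pipeline import run_all
from optscaf.simulate import SimConfig, simulate_all


SMALL_ZERO = replace(
    SimConfig.zero_noise(1),
    n_chromosomes=2,
    chromosome_length_bp=3_000_000,
    n_chimeras=2,
    n_misplacements=3,
    n_misorientations=3,
    n_old_unplaced=2,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 6-Mb, 2-chromosome zero-noise benchmark with 2 chimeras."""
    return simulate_all(SMALL_ZERO)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline result on the small zero-noise benchmark."""
    out = tmp_path_factory.mktemp("pipe")
    return run_all(
        small_sim.scaffolds,
        small_sim.maps["DLE-1"],
        small_sim.maps["Nt.BspQI"],
        small_sim.markers,
        PipelineConfig(),
        out,
        old_assembly=small_sim.truth.old_assembly,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
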