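import numpy as np
import pytest

import brainbeam as bb

#: photon budgets for the shared result-scale runs; the collimated Gaussian
#: gets a larger budget for deep center-column statistics
RUN_BUDGETS = {
    "pencil": 1_000_000,
    "hyperboloid_gaussian": 1_000_000,
    "spatial_freq_fourier": 1_000_000,
    "ring": 1_000_000,
    "pencil_array": 1_000_000,
    "collimated_gaussian": 3_000_000,
}

RUN_SEED = 2024


@pytest.fixture(scope="session")
def head_volume():
    return bb.build_layered_volume()


@pytest.fixture(scope="session")
def props():
    return bb.default_property_table()


@pytest.fixture(scope="session")
def study_runs(head_volume, props):
    """Simulated energy volumes for the sources the result checks need."""
    runs = {}
    for tag, n in RUN_BUDGETS.items():
        runs[tag] = bb.run_simulation(
            head_volume,
            props,
            bb.SourceSpec(type_tag=tag),
            bb.SimConfig(n_photons=n, rng_seed=RUN_SEED),
        )
    return runs


@pytest.fixture(scope="session")
def small_pencil_run(head_volume, props):
    """A quick pencil-beam run for bookkeeping and identity checks."""
    return bb.run_simulation(
        head_volume,
        props,
        bb.SourceSpec(type_tag="pencil"),
        bb.SimConfig(n_photons=30_000, rng_seed=7),
    )
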