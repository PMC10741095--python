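"""Shared fixtures: small synthetic datasets and a quickly trained model."""

import numpy as np
import pytest

from etorque import bpnet, pipeline, synth
from etorque.dataio import SubjectAnthropometry


@pytest.fixture(scope="session")
def anthro() -> SubjectAnthropometry:
    return SubjectAnthropometry.reference()


@pytest.fixture(scope="session")
def small_cfg() -> synth.SynthConfig:
    """A handful of cycles — enough structure for every pipeline stage."""
    return synth.SynthConfig(n_cycles=6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, anthro):
    return synth.make_dataset(small_cfg, anthro)


@pytest.fixture(scope="session")
def trained_small(anthro):
    """A model trained on a reduced protocol, for control/serialization tests.

    Uses a lighter swarm than the full study so the fixture builds in a few
    seconds; prediction quality is still high on this easy dataset.
    """
    return pipeline.run_study(
        seed=3,
        synth_cfg=synth.SynthConfig(n_cycles=10, seed=3),
        pso_cfg=bpnet.PSOConfig(t_max=80, n_particles=40, seed=4),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
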