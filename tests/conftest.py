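"""Shared fixtures: small deterministic phantoms and sensor models."""

import numpy as np
import pytest

from hsinucdb import phantom as ph


@pytest.fixture(scope="session")
def sensor():
    return ph.SensorModel.wedge(n_spectral_bands=16)


@pytest.fixture(scope="session")
def references(sensor):
    return ph.make_references(sensor, width=80)


@pytest.fixture(scope="session")
def tumor_truth():
    """Small dense scene with several nuclei (deterministic)."""
    spec = ph.PhantomSpec(
        height=96, width=80, n_bands=16, tissue_class="tumor",
        seed=3, noise_sd=0.0, texture_sd=0.0,
    )
    return ph.make_phantom_scene(spec)


@pytest.fixture(scope="session")
def healthy_truth():
    spec = ph.PhantomSpec(
        height=128, width=128, n_bands=16, tissue_class="healthy",
        seed=7, noise_sd=0.0, texture_sd=0.0,
    )
    return ph.make_phantom_scene(spec)
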