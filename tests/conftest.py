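import numpy as np
import pandas as pd
import pytest

from socspec.io import SpectrumSet
from socspec.synthdata import (HIGHRES, LOWRES, SceneParams, generate_scene,
                               noiseless, quiet_device)


@pytest.fixture(scope="session")
def default_params():
    return SceneParams(rng_seed=1234)


@pytest.fixture(scope="session")
def quiet_highres():
    return quiet_device(HIGHRES)


@pytest.fixture(scope="session")
def quiet_lowres():
    return quiet_device(LOWRES)


@pytest.fixture(scope="session")
def noiseless_params(default_params):
    return noiseless(default_params)


@pytest.fixture(scope="session")
def small_scene():
    """A reduced but fully noisy scene for integration-style tests."""
    params = SceneParams(n_locations=30, rng_seed=77)
    return generate_scene(params)


def make_spectrum_set(wavelengths, reflectance, sample_ids=None, **meta_overrides):
    """Build a SpectrumSet with minimal metadata for unit tests."""
    reflectance = np.atleast_2d(reflectance)
    n = reflectance.shape[0]
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": ids,
        "device": meta_overrides.get("device", "highres"),
        "condition": meta_overrides.get("condition", "lab"),
        "replicate_id": meta_overrides.get("replicate_id", np.arange(n)),
        "x_m": meta_overrides.get("x_m", np.zeros(n)),
        "y_m": meta_overrides.get("y_m", np.zeros(n)),
    })
    return SpectrumSet(np.asarray(wavelengths, float), reflectance, meta)
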