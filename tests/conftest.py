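import math

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

import drykin as dk
from drykin import reference as ref


def round_sig(x: float, n: int = 3) -> float:
    """Round to n significant figures (for comparing against printed values)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


@pytest.fixture(scope="session")
def study_params():
    """The sixteen published diffusion-approach triples keyed by condition."""
    return ref.DIFFUSION_APPROACH_PARAMS


@pytest.fixture(scope="session")
def noiseless_run():
    """Factory: noiseless synthetic run for one (temperature, thickness_mm)."""

    def make(temperature=60.0, thickness_mm=2.0):
        return dk.generate_run(
            dk.SyntheticConfig(
                temperature=temperature, thickness_mm=thickness_mm, noise_sd=0.0
            )
        )

    return make


@pytest.fixture(scope="session")
def noiseless_ratio(noiseless_run):
    """Moisture-ratio series of a default noiseless run."""
    run = noiseless_run()
    return dk.moisture_ratio(dk.moisture_from_weights(run))
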