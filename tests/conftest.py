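import dataclasses

import numpy as np
import pytest

from kflux import (
    CONTROL_MEANS,
    PROTOCOLS,
    FitOptions,
    control_spec,
    generate_cohort,
)
from kflux.cohort import CONTROL_FSD


@pytest.fixture(scope="session")
def control_params():
    return CONTROL_MEANS


@pytest.fixture(scope="session")
def protocol4():
    return PROTOCOLS["#4"]


@pytest.fixture(scope="session")
def noise_free_animal():
    """One noise-free synthetic animal at control-group mean parameters."""
    spec = control_spec(
        n_animals=1,
        param_fsd={k: 0.0 for k in CONTROL_FSD},
        noise_sd=0.0,
        urine_noise_fsd=0.0,
    )
    return generate_cohort(spec)[0]


@pytest.fixture()
def fast_options():
    return FitOptions(multistart_count=1)


def make_noisy(record, noise_sd, seed):
    from kflux import add_noise

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    return dataclasses.replace(record, timecourse=add_noise(record.timecourse, noise_sd, rng))
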