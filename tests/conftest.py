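import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from evseg.config import (
    AnxietyParams,
    BoundaryParams,
    GeneratorConfig,
    PressParams,
    RecallParams,
    VideoSpec,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast 12+12-subject cohort with two short videos."""
    return GeneratorConfig(
        n_ptsd=12,
        n_control=12,
        seed=5,
        videos=[VideoSpec("vid_a", 120), VideoSpec("vid_b", 90)],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from evseg.synthetic_cohort import generate_cohort

    return generate_cohort(small_config, score=True)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One full-size (63+64) cohort, generated once per session."""
    from evseg.synthetic_cohort import generate_cohort

    return generate_cohort(default_config, score=True)
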