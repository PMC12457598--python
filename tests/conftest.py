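import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from boneage_calib import Cohort
from boneage_calib.simulate import (
    SyntheticConfig,
    default_gbad_like_config,
    generate_cohort,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_cohort() -> Cohort:
    """3 images x 3 raters, all cells filled, handmade numbers."""
    frame = pd.DataFrame(
        {
            "image_id": ["a", "b", "c"],
            "sex": ["female", "male", "female"],
            "ca_months": [100.0, 60.0, 140.0],
            "r1": [100.0, 60.0, 140.0],
            "r2": [104.0, 66.0, 147.0],
            "r3": [90.0, 57.0, 130.0],
            "ai_ba_months": [102.0, 63.0, 141.0],
            "disorder": [False, True, False],
        }
    )
    return Cohort(frame, ["r1", "r2", "r3"])


@pytest.fixture(scope="session")
def gbad_cohort():
    """One study-scale synthetic cohort with its ground truth."""
    return generate_cohort(default_gbad_like_config(seed=0))


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Identity AI, unbiased noise-free raters: every signal equals BA_true."""
    return SyntheticConfig(
        n_images=60,
        n_raters=3,
        rater_biases=(0.0, 0.0, 0.0),
        rater_sds=(0.0, 0.0, 0.0),
        ai_slope=1.0,
        ai_offset=0.0,
        ai_sd=0.0,
        ba_ca_sd=0.0,
        seed=11,
    )


def make_config(**overrides) -> SyntheticConfig:
    base = default_gbad_like_config(seed=overrides.pop("seed", 0))
    return dataclasses.replace(base, **overrides)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
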