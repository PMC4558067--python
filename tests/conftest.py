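import numpy as np
import pandas as pd
import pytest

from quadgait.io import PipelineConfig
from quadgait.pipeline import compute_study_metrics
from quadgait.simulate import (
    EffectModel,
    StudyDesign,
    default_walk_pattern,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def walk():
    """Canonical lateral-sequence walk: T=0.25 s, 5 cm strides, duty 0.6."""
    return default_walk_pattern(
        speed=20.0, stride_length=5.0, duty_factor=0.6, sway_amplitude=0.15
    )


def _noisy_effects() -> EffectModel:
    eff = EffectModel()
    eff.per_day_slopes["M"]["speed"] = -1.25
    eff.per_day_slopes["F"]["speed"] = 0.616
    eff.per_day_slopes["M"]["duty_factor"] = 0.004
    eff.mouse_intercept_sd["speed"] = 0.8
    eff.residual_sd["speed"] = 1.5
    eff.residual_sd["sway_amplitude"] = 0.02
    return eff


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study (5-8 strides/day) shared across tests."""
    design = StudyDesign(seed=7, strides_per_day=(5, 8))
    dataset = simulate_study(design, _noisy_effects())
    return design, dataset


@pytest.fixture(scope="session")
def small_study_metrics(small_study) -> pd.DataFrame:
    _, dataset = small_study
    return compute_study_metrics(
        dataset.contacts, dataset.tracks, dataset.metadata, PipelineConfig()
    )
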