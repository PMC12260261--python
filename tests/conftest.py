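import numpy as np
import pytest

from lotqa import ErrorModel, PlanParameters, generate_plan


@pytest.fixture
def sbrt_params() -> PlanParameters:
    """SBRT-archetype plan: low pitch, long beam-on, slow gantry."""
    return PlanParameters(plan_id="sbrt-01", site="sbrt", field_width_cm=2.5,
                          pitch=0.178, modulation_factor=2.0,
                          gantry_period_s=33.18, beam_on_time_s=450.93)


@pytest.fixture
def small_params() -> PlanParameters:
    """A deliberately tiny plan for fast unit tests (~20 projections)."""
    return PlanParameters(plan_id="tiny-01", site="prostate", field_width_cm=2.5,
                          pitch=0.414, modulation_factor=2.0,
                          gantry_period_s=20.0, beam_on_time_s=8.0)


@pytest.fixture
def small_plan(small_params):
    return generate_plan(small_params, seed=11)


@pytest.fixture
def quiet_model() -> ErrorModel:
    """Moderate, realistic timing errors."""
    return ErrorModel(latency_mean_ms=0.0, latency_sd_ms=0.5, jitter_sd_ms=1.0,
                      drop_probability=0.0005, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
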