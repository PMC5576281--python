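import pandas as pd
import pytest

from geolux import synthetic
from geolux.io import StudyConfig, run_study


def stationary_truth(lat, lon, start, days):
    """Daily ground-truth frame for a bird sitting still."""
    dates = pd.date_range(start, periods=days)
    return pd.DataFrame({"date": dates, "lat": lat, "lon": lon})


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions (shading and jitter off)."""
    return StudyConfig(seed=5, shading_event_rate=0.0, clock_jitter_min=0.0,
                       ndvi_noise_sd=0.0, ndvi_interannual_sd=0.0)


@pytest.fixture(scope="session")
def clean_study(clean_config):
    """Full noise-free 15-track study, fitted end to end."""
    return run_study(clean_config)


@pytest.fixture(scope="session")
def noisy_study():
    """Default (shaded, jittered) study conditions, fitted end to end."""
    return run_study(StudyConfig(seed=1))


@pytest.fixture()
def winter_series():
    """Noise-free light series for a 45-day tropical winter residency."""
    truth = stationary_truth(10.3, 1.3, "2015-11-01", 45)
    series = synthetic.simulate_light(truth, synthetic.ShadingModel(), 5,
                                      seed=11, reference_angle_deg=-1.5)
    return truth, series
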