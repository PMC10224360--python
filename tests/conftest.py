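import numpy as np
import pytest

from electrome import GeneratorConfig, OscillatoryComponent, Recording

FS = 62.5


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)


@pytest.fixture
def tone_recording():
    """600 s pure 1 Hz tone, amplitude 10 uV (power 50 uV^2)."""
    t = np.arange(round(600 * FS)) / FS
    return Recording(
        samples=10.0 * np.cos(2 * np.pi * 1.0 * t),
        fs=FS,
        plant_id="tone",
        treatment="test",
        phase="before",
    )


@pytest.fixture
def small_config():
    """A cheap cohort: 3 replicates, 5-minute phases."""
    return GeneratorConfig(
        duration_s=300.0,
        n_replicates=3,
        components=(OscillatoryComponent(center_hz=1.0, bandwidth_hz=1.0, rms_uv=10.0),),
        background_rms=5.0,
        base_seed=11,
    )
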