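import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssvep_ratio.paradigms import ParadigmSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_paradigm():
    """Small fixed-contrast paradigm for fast unit tests: 12 Hz at 240 Hz
    sampling, 2 s trials, four repetitions, five contrast levels."""
    return ParadigmSpec(
        name="tiny", stim_freq=12.0, sampling_rate=240.0, trial_duration=2.0,
        n_reps=4, contrast_levels=(0.0, 10.0, 20.0, 40.0, 69.0),
    )


@pytest.fixture
def tiny_sweep_paradigm():
    """Sweep paradigm at reduced sampling: 5.12 Hz flicker, 128 Hz, nine
    1 s bins with 1.5 s prelude/postlude."""
    levels = (0.0, 2.25, 3.5, 5.46, 8.5, 13.24, 20.62, 32.11, 50.0)
    return ParadigmSpec(
        name="tiny_sweep", stim_freq=5.12, sampling_rate=128.0,
        trial_duration=12.0, n_reps=3, contrast_levels=levels,
        sweep=True, sweep_bin_duration=1.0, prelude_postlude=1.5,
    )
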