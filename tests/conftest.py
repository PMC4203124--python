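import datetime as dt

import numpy as np
import pytest

from headcast.io import DailyWeather, Experiment, Site
from headcast.synth import SynthConfig, gen_dataset


def constant_weather(start: dt.date, n_days: int, tm: float, diurnal: float = 0.0):
    """Flat weather record: every day has the same mean temperature."""
    return [
        DailyWeather(start + dt.timedelta(days=i), tm - diurnal / 2, tm + diurnal / 2)
        for i in range(n_days)
    ]


@pytest.fixture(scope="session")
def polar_site():
    # midsummer day length >= 20 h, so the photoperiod factor saturates
    return Site("polar", 75.0)


@pytest.fixture(scope="session")
def small_dataset():
    """20 genotypes, 40 markers, 3 autumn + 2 spring sowings."""
    return gen_dataset(SynthConfig(seed=7, n_genotypes=20, n_markers=40))


@pytest.fixture(scope="session")
def recovery_dataset():
    """Noiseless all-spring panel over 2 autumn + 1 spring sowings."""
    cfg = SynthConfig(
        seed=3,
        n_genotypes=50,
        n_markers=20,
        winter_fraction=0.0,
        noise_sd_days=0.0,
        missing_rate=0.0,
        autumn_sowings=(("CF", 2000), ("LM", 2001)),
        spring_sowings=(("CF", 2002),),
    )
    return gen_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_recovery_dataset():
    cfg = SynthConfig(
        seed=3,
        n_genotypes=50,
        n_markers=20,
        winter_fraction=0.0,
        noise_sd_days=1.5,
        missing_rate=0.0,
        autumn_sowings=(("CF", 2000), ("LM", 2001)),
        spring_sowings=(("CF", 2002),),
    )
    return gen_dataset(cfg)
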