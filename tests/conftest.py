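import numpy as np
import pandas as pd
import pytest

import cardionet as cn
from cardionet.simulate import SimulationConfig


@pytest.fixture(scope="session")
def rest_subject():
    """One preprocessed default-REST subject (N=300)."""
    s = cn.generate_subject(cn.default_rest_config(), seed=42)
    return cn.standardize(cn.highpass_detrend(s), "unit_variance")


@pytest.fixture(scope="session")
def null_config():
    """Four mutually independent AR processes (no couplings)."""
    return SimulationConfig(
        self_dynamics={"R": (0.0, -0.64), "H": (0.5,), "M": (0.5,), "C": (0.5,)}
    )


def make_null_series(seed, null_config=None):
    cfg = null_config or SimulationConfig(
        self_dynamics={"R": (0.0, -0.64), "H": (0.5,), "M": (0.5,), "C": (0.5,)}
    )
    return cn.standardize(cn.generate_subject(cfg, seed=seed), "unit_variance")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject paired REST/HUT cohort, preprocessed."""
    cohort = cn.generate_cohort(
        cn.default_rest_config(), cn.default_hut_config(), 6, master_seed=7
    )
    return [
        tuple(cn.standardize(cn.highpass_detrend(s), "unit_variance") for s in pair)
        for pair in cohort
    ]


@pytest.fixture(scope="session")
def white_noise_series():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.standard_normal((300, 4)), columns=["R", "H", "M", "C"])
    return cn.BeatSeries(df)
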