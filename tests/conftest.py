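import warnings

import numpy as np
import pytest

from pvasync import (
    ScenarioConfig,
    generate_ventilated_breath,
    superimpose_effort,
)

warnings.filterwarnings("ignore", message="no breath onsets")
warnings.filterwarnings("ignore", message="moving-average window")


def noise_free_config(scenario, **over):
    over.setdefault("noise_sd_pressure", 0.0)
    over.setdefault("noise_sd_flow", 0.0)
    over.setdefault("amplitude_jitter", 0.0)
    over.setdefault("n_breaths", 1)
    over.setdefault("seed", 1)
    return ScenarioConfig(scenario=scenario, **over)


@pytest.fixture(scope="session")
def clean_vc_breath():
    """Noise-free volume-controlled ventilated breath (canonical loop)."""
    return generate_ventilated_breath(noise_free_config("none"))


@pytest.fixture(scope="session")
def clean_pc_breath():
    return generate_ventilated_breath(noise_free_config("none", mode="PC"))


@pytest.fixture(scope="session")
def scenario_breath_pairs():
    """Noise-free (ventilated, asynchronous) pair per asynchrony type."""
    pairs = {}
    for sc in ("reverse_triggering", "premature_cycling", "double_triggering"):
        cfg = noise_free_config(sc)
        vent = generate_ventilated_breath(cfg)
        pairs[sc] = (cfg, vent, superimpose_effort(vent, cfg))
    return pairs


def add_noise(breath, seed, sd_pressure=0.2, sd_flow=0.01):
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    return replace(
        breath,
        pressure=breath.pressure + rng.normal(0.0, sd_pressure, breath.n),
        flow=breath.flow + rng.normal(0.0, sd_flow, breath.n),
    )
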