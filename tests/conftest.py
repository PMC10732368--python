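import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bimanual_adapt as ba

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def evident_participant():
    """One fully simulated evident-group participant (shared, read-only)."""
    learner = ba.default_learner_for_group("evident")
    return ba.simulate_participant("evident", participant=1, seed=11,
                                   learner=learner)


@pytest.fixture(scope="session")
def evident_gen_profiles(evident_participant):
    profiles = ba.extract_clamp_profiles(evident_participant)
    return [p for p in profiles if p.phase == "generalization"]


@pytest.fixture(scope="session")
def noise_free_conditions():
    """Noise-free velocity profiles for the three evident trained
    conditions, zero-padded onto per-condition common grids."""
    out = {}
    for label in ("b_sf", "b_mm", "b_fs"):
        cond = ba.CONDITIONS[label]
        vl = ba.generate_velocity_profile(cond.left)
        vr = ba.generate_velocity_profile(cond.right)
        n = max(len(vl), len(vr))
        out[label] = (np.pad(vl, (0, n - len(vl))),
                      np.pad(vr, (0, n - len(vr))))
    return out
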