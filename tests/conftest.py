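import numpy as np
import pytest
from hypothesis import settings

import pulsekernel as pk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# ground-truth kernel shapes used across recovery tests: uniform, ramps,
# a late-humped profile and a steeply early one
KERNEL_SHAPES = {
    "flat": np.ones(7),
    "linear_down": np.linspace(1.5, 0.5, 7),
    "linear_up": np.linspace(0.5, 1.5, 7),
    "late_humped": np.array([0.1, 0.2, 0.3, 0.45, 0.55, 0.5, 0.35]),
    "early_steep": np.array([1.2, 1.0, 0.5, 0.2, 0.1, 0.05, 0.05]),
}

PROBE_SENSITIVITY = 16.0  # kernel norm of the near-deterministic probe observer


@pytest.fixture(scope="session")
def default_config():
    return pk.StimulusConfig()


def make_linear_cohort(shape, n_trials, seed, sensitivity=PROBE_SENSITIVITY, **cfg_kw):
    """Session of trials with choices from a linear observer of known kernel."""
    rng = np.random.default_rng(seed)
    cfg = pk.StimulusConfig(**cfg_kw)
    trials = pk.generate_session(cfg, n_trials, rng)
    shape = np.asarray(shape, dtype=float)
    kernel = sensitivity * shape / np.linalg.norm(shape)
    choices = pk.simulate_linear_choices(
        trials, pk.LinearObserver(kernel=kernel), rng
    )
    return pk.attach_choices(trials, choices), kernel


@pytest.fixture(scope="session")
def small_fitted_session():
    """200-trial fixture with choices, shared by the optimizer-oracle tests."""
    trials, kernel = make_linear_cohort(
        np.linspace(2.0, 0.5, 7), 200, seed=42, sensitivity=3.0
    )
    return trials, kernel
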