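"""Model observers that turn pulse sequences into binary choices.

These simulators provide ground truth for parameter-recovery tests of the
estimation stages:

* ``LinearObserver`` — the generative inverse of the kernel-regression
  model: P(rightward) = lapse + (1 - 2 lapse) * logistic(kernel . pulses + bias).
* ``AccumulatorObserver`` — discrete-pulse evidence accumulation with an
  absorbing bound, leak and per-pulse diffusion noise. A tight bound
  produces early temporal weighting (pulses after absorption are ignored);
  leak produces late weighting (earlier evidence decays away).
* extrema detection — choose the direction of the single strongest pulse,
  ignoring the rest; the control strategy the consistency analysis rules out.

All simulators take an explicit numpy Generator; none touch global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from scipy.special import expit

from .stimulus import TrialRecord, pulse_matrix

__all__ = [
    "LinearObserver",
    "AccumulatorObserver",
    "simulate_linear_choices",
    "simulate_accumulator_choices",
    "simulate_extrema_choices",
    "attach_choices",
]


@dataclass(frozen=True)
class LinearObserver:
    """Static linear-kernel observer with a symmetric lapse rate."""

    kernel: np.ndarray
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "kernel", np.asarray(self.kernel, dtype=float))
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


@dataclass(frozen=True)
class AccumulatorObserver:
    """Sequential accumulator: leak, absorbing bound, per-pulse noise.

    ``bound=np.inf, leak=0, noise_sd=0`` is the perfect integrator.
    """

    gain: float = 1.0
    bound: float = math.inf
    leak: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("bound must be > 0")
        if self.leak < 0:
            raise ValueError("leak must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sign_choice(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map signed decision variables to {0, 1}; exact zeros break randomly."""
    choices = (values > 0).astype(int)
    ties = values == 0
    if ties.any():
        choices[ties] = rng.integers(0, 2, size=int(ties.sum()))
    return choices


def simulate_linear_choices(
    trials: Sequence[TrialRecord],
    obs: LinearObserver,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli choices from the lapse-compressed logistic readout."""
    X = pulse_matrix(trials)
    if X.shape[1] != len(obs.kernel):
        raise ValueError(
            f"kernel length {len(obs.kernel)} does not match "
            f"{X.shape[1]} pulses per trial"
        )
    eta = X @ obs.kernel + obs.bias
    p = obs.lapse + (1.0 - 2.0 * obs.lapse) * expit(eta)
    return (rng.random(len(trials)) < p).astype(int)


def simulate_accumulator_choices(
    trials: Sequence[TrialRecord],
    obs: AccumulatorObserver,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choices from pulse-by-pulse bounded, leaky accumulation.

    Per pulse: state <- state * (1 - leak) + gain * pulse + noise. Once
    |state| reaches the bound the state is absorbed at its sign and later
    pulses are ignored. The choice is the sign of the final (or absorbed)
    state; an exactly zero final state is resolved at random.
    """
    X = pulse_matrix(trials)
    n_trials, n_pulses = X.shape
    noise = (
        rng.normal(0.0, obs.noise_sd, size=X.shape)
        if obs.noise_sd > 0
        else np.zeros_like(X)
    )
    state = np.zeros(n_trials)
    absorbed = np.zeros(n_trials, dtype=bool)
    for i in range(n_pulses):
        live = ~absorbed
        state[live] = (
            state[live] * (1.0 - obs.leak)
            + obs.gain * X[live, i]
            + noise[live, i]
        )
        hit = live & (np.abs(state) >= obs.bound)
        state[hit] = np.sign(state[hit]) * obs.bound
        absorbed |= hit
    return _sign_choice(state, rng)


def simulate_extrema_choices(
    trials: Sequence[TrialRecord],
    rng: np.random.Generator,
) -> np.ndarray:
    """Choices that follow the single strongest pulse in each trial.

    The strongest pulse is the one with the largest absolute element
    count; ties go to the earliest pulse. A zero strongest pulse (an
    all-zero trial) is resolved at random.
    """
    counts = np.vstack([t.pulse_element_counts for t in trials])
    idx = np.argmax(np.abs(counts), axis=1)  # argmax takes the earliest tie
    strongest = counts[np.arange(len(trials)), idx]
    return _sign_choice(strongest.astype(float), rng)


def attach_choices(
    trials: Sequence[TrialRecord], choices: np.ndarray
) -> list[TrialRecord]:
    """Return trials with choices filled in and correctness scored."""
    if len(trials) != len(choices):
        raise ValueError("one choice per trial required")
    return [t.with_choice(int(c)) for t, c in zip(trials, choices)]
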