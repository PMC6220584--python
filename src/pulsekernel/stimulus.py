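"""Pulse-based motion stimulus generator.

Each trial presents a short sequence of motion "pulses". A pulse's signed
motion strength is the proportion of coherently drifting elements in a grid
of Gabor patches (sign = direction, negative = leftward). Strengths are
drawn i.i.d. from a Gaussian ``N(mu_k(i), sigma)`` where ``k`` indexes one
of five generating distributions (strong left, weak left, zero-mean, weak
right, strong right) and the per-pulse mean ``mu_k(i)`` may vary over time:

* ``flat``  — the mean is constant over pulses (stationary baseline);
* ``late``  — the mean starts at 0 on pulse 1 and rises to ``mu_k`` by the
  final pulse along a logistic transition;
* ``early`` — the exact time-reverse of ``late``.

Because the stimulus is physically composed of discrete elements, each
drawn strength is converted to a signed integer element count (rounded
half-away-from-zero, clipped to the grid size); the realized strength is
count / n_elements. Reward follows the sign of the realized pulse sum, not
the generating distribution, so every pulse is informative.

Sessions may include "frozen-seed" trials: one fixed pulse sequence whose
element counts sum to exactly zero, repeated identically and rewarded at
random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusConfig",
    "ConditionProfile",
    "TrialRecord",
    "make_condition_profile",
    "sample_trial",
    "generate_session",
]

CONDITIONS = ("flat", "early", "late")

DEFAULT_MU_SET = (-0.50, -0.10, 0.0, 0.10, 0.50)


class StimulusConfigError(ValueError):
    """Invalid stimulus configuration."""


class GenerationError(RuntimeError):
    """Stimulus generation failed (e.g., impossible frozen-seed constraint)."""


@dataclass(frozen=True)
class StimulusConfig:
    """Generative design of a session's motion stimulus.

    Parameters
    ----------
    n_pulses : int
        Number of consecutive motion pulses per trial (default 7).
    pulse_duration_ms : float
        Duration of one pulse in milliseconds (150 for the standard design;
        100 in the short variant).
    n_elements : int
        Number of Gabor elements in the grid (default 19); element counts
        are integers in ``[-n_elements, n_elements]``.
    mu_set : tuple of float
        Signed means (as proportions) of the five generating distributions.
    sigma : float
        Gaussian SD of pulse strength, as a proportion (default 0.15).
    condition : str
        One of ``flat``, ``early``, ``late``.
    transition_midpoint : float
        Pulse index at which the logistic transition crosses its midpoint.
    transition_slope : float
        Logistic scale parameter (pulse-index units) of the transition.
    frozen_seed_fraction : float
        Fraction of trials replaced by the session's fixed zero-sum sequence.
    trial_type_probabilities : tuple of float
        Sampling probabilities over ``mu_set`` (must sum to 1).
    """

    n_pulses: int = 7
    pulse_duration_ms: float = 150.0
    n_elements: int = 19
    mu_set: tuple = DEFAULT_MU_SET
    sigma: float = 0.15
    condition: str = "flat"
    transition_midpoint: float = 4.0
    transition_slope: float = 0.3
    frozen_seed_fraction: float = 0.0
    trial_type_probabilities: Optional[tuple] = None

    def __post_init__(self):
        if self.n_pulses < 1:
            raise StimulusConfigError("n_pulses must be >= 1")
        if self.sigma < 0:
            raise StimulusConfigError("sigma must be >= 0")
        if self.condition not in CONDITIONS:
            raise StimulusConfigError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if any(abs(m) > 1 for m in self.mu_set):
            raise StimulusConfigError("mu_set values must lie in [-1, 1]")
        if not 0 <= self.frozen_seed_fraction <= 1:
            raise StimulusConfigError("frozen_seed_fraction must lie in [0, 1]")
        if self.trial_type_probabilities is None:
            p = (1.0 / len(self.mu_set),) * len(self.mu_set)
            object.__setattr__(self, "trial_type_probabilities", p)
        p = self.trial_type_probabilities
        if len(p) != len(self.mu_set):
            raise StimulusConfigError(
                "trial_type_probabilities must match mu_set length"
            )
        if any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise StimulusConfigError("trial_type_probabilities must be a simplex")

    @property
    def total_duration_ms(self) -> float:
        """Total stimulus duration (pulses x pulse duration)."""
        return self.n_pulses * self.pulse_duration_ms


@dataclass(frozen=True)
class ConditionProfile:
    """Per-pulse generating means mu_k(i), i = 1..n_pulses."""

    per_pulse_means: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "per_pulse_means", np.asarray(self.per_pulse_means, dtype=float)
        )


@dataclass
class TrialRecord:
    """One behavioral trial: realized stimulus plus (optionally) the choice.

    ``pulse_strengths`` are the realized, post-rounding proportions
    (``pulse_element_counts / n_elements``); ``net_strength`` is their sum.
    ``rewarded_direction`` is the sign of ``net_strength``, assigned
    randomly (+/-1) when the sum is exactly zero. ``choice`` uses 1 for
    rightward and 0 for leftward and is None until an observer (or a real
    subject) provides it.
    """

    session_id: str
    subject_id: str
    condition: str
    trial_index: int
    distribution_mu: float
    pulse_strengths: np.ndarray
    pulse_element_counts: np.ndarray
    net_strength: float
    rewarded_direction: int
    frozen_seed: bool = False
    choice: Optional[int] = None
    correct: Optional[int] = None

    def with_choice(self, choice: int) -> "TrialRecord":
        """Return a copy with the choice filled in and correctness scored."""
        correct = int((1 if choice == 1 else -1) == self.rewarded_direction)
        new = replace(self)
        new.choice = int(choice)
        new.correct = correct
        return new


def _logistic_transition(config: StimulusConfig) -> np.ndarray:
    """Endpoint-rescaled logistic ramp t(i) with t(1) = 0, t(n) = 1."""
    i = np.arange(1, config.n_pulses + 1, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(i - config.transition_midpoint) / config.transition_slope))
    if config.n_pulses == 1:
        return np.zeros(1)
    return (t - t[0]) / (t[-1] - t[0])


def make_condition_profile(config: StimulusConfig, mu: float) -> ConditionProfile:
    """Per-pulse means for one generating distribution under the condition.

    ``flat`` holds the mean at ``mu`` on every pulse. ``late`` ramps the
    mean from exactly 0 on pulse 1 to exactly ``mu`` on the final pulse
    along a logistic transition (midpoint/slope from the config), affinely
    rescaled so the endpoints are met exactly. ``early`` is the time
    reverse of ``late``. The zero-mean distribution is all-zero in every
    condition by construction.
    """
    if mu not in config.mu_set:
        raise StimulusConfigError(f"mu={mu} is not in the configured mu_set")
    if config.condition == "flat":
        means = np.full(config.n_pulses, mu, dtype=float)
    elif config.condition == "late":
        means = mu * _logistic_transition(config)
    elif config.condition == "early":
        means = mu * _logistic_transition(config)[::-1]
    else:  # pragma: no cover - guarded by StimulusConfig
        raise StimulusConfigError(f"unknown condition {config.condition!r}")
    return ConditionProfile(means)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (sign-symmetric)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _draw_counts(
    means: np.ndarray, config: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    strengths = rng.normal(means, config.sigma)
    counts = _round_half_away(strengths * config.n_elements)
    return np.clip(counts, -config.n_elements, config.n_elements).astype(int)


def sample_trial(
    profile: ConditionProfile,
    config: StimulusConfig,
    rng: np.random.Generator,
    *,
    distribution_mu: float = 0.0,
    session_id: str = "sim",
    subject_id: str = "sim",
    trial_index: int = 0,
) -> TrialRecord:
    """Draw one trial's pulse sequence from the given profile.

    Each pulse strength is drawn independently from
    ``N(per_pulse_mean, sigma)``, converted to a signed element count by
    rounding ``strength * n_elements`` half-away-from-zero and clipping to
    the grid, and realized as ``count / n_elements``. The rewarded
    direction is the sign of the realized sum (random for an exact zero).
    """
    means = profile.per_pulse_means
    if len(means) != config.n_pulses:
        raise StimulusConfigError("profile length must equal config.n_pulses")
    counts = _draw_counts(means, config, rng)
    strengths = counts / config.n_elements
    # summing counts first keeps an exactly-zero sequence exactly zero
    net = float(counts.sum()) / config.n_elements
    if counts.sum() != 0:
        rewarded = int(np.sign(net))
    else:
        rewarded = int(rng.choice([-1, 1]))
    return TrialRecord(
        session_id=session_id,
        subject_id=subject_id,
        condition=config.condition,
        trial_index=trial_index,
        distribution_mu=distribution_mu,
        pulse_strengths=strengths,
        pulse_element_counts=counts,
        net_strength=net,
        rewarded_direction=rewarded,
    )


def _make_frozen_sequence(
    config: StimulusConfig, rng: np.random.Generator, max_tries: int = 100_000
) -> np.ndarray:
    """Rejection-sample a zero-mean pulse sequence whose counts sum to 0."""
    zero_means = np.zeros(config.n_pulses)
    for _ in range(max_tries):
        counts = _draw_counts(zero_means, config, rng)
        if counts.sum() == 0:
            return counts
    raise GenerationError(
        "could not construct a frozen-seed sequence with an exactly zero sum"
    )


def generate_session(
    config: StimulusConfig,
    n_trials: int,
    rng: np.random.Generator,
    *,
    session_id: str = "sim",
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Generate a full session of stimulus trials (choices not yet assigned).

    Per trial, a generating distribution is drawn from
    ``trial_type_probabilities``. A ``frozen_seed_fraction`` of trials
    (rounded to a count, positions drawn without replacement) reuse a
    single fixed zero-sum sequence; those trials are flagged and rewarded
    at random.
    """
    if n_trials < 1:
        raise StimulusConfigError("n_trials must be >= 1")
    n_frozen = int(round(config.frozen_seed_fraction * n_trials))
    frozen_idx: set[int] = set()
    frozen_counts = None
    frozen_rewards = None
    if n_frozen > 0:
        frozen_counts = _make_frozen_sequence(config, rng)
        frozen_idx = set(rng.choice(n_trials, size=n_frozen, replace=False).tolist())
        frozen_rewards = rng.choice([-1, 1], size=n_frozen)

    profiles = {mu: make_condition_profile(config, mu) for mu in config.mu_set}
    mus = rng.choice(config.mu_set, size=n_trials, p=config.trial_type_probabilities)

    trials: list[TrialRecord] = []
    k_frozen = 0
    for t in range(n_trials):
        if t in frozen_idx:
            strengths = frozen_counts / config.n_elements
            rec = TrialRecord(
                session_id=session_id,
                subject_id=subject_id,
                condition=config.condition,
                trial_index=t,
                distribution_mu=0.0,
                pulse_strengths=strengths,
                pulse_element_counts=frozen_counts.copy(),
                net_strength=float(strengths.sum()),
                rewarded_direction=int(frozen_rewards[k_frozen]),
                frozen_seed=True,
            )
            k_frozen += 1
        else:
            mu = float(mus[t])
            rec = sample_trial(
                profiles[mu],
                config,
                rng,
                distribution_mu=mu,
                session_id=session_id,
                subject_id=subject_id,
                trial_index=t,
            )
        trials.append(rec)
    return trials


def pulse_matrix(trials: Sequence[TrialRecord]) -> np.ndarray:
    """Stack realized pulse strengths into an (n_trials, n_pulses) array."""
    return np.vstack([t.pulse_strengths for t in trials])
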