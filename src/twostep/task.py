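"""Generative structure of the two-step task.

A first-stage choice between two stimuli leads probabilistically
(common 70% / rare 30%) to one of two second-stage stimulus pairs; each
of the four second-stage stimuli pays a probabilistic outcome (a £1 gain
in the reward valence, a £1 loss in the punishment valence) whose
probability drifts slowly and independently between 0.25 and 0.75 over
trials, following a reflected Gaussian random walk.

The common mapping is the identity: first-stage stimulus ``A`` leads to
second-stage state ``S1`` with probability ``p_common`` and first-stage
stimulus ``B`` to ``S2``; it is fixed across trials and subjects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .data import PUNISHMENT, REWARD, VALENCES

__all__ = [
    "TaskConfig",
    "OutcomeSchedule",
    "init_outcome_probs",
    "step_outcome_prob",
    "generate_schedule",
    "sample_transition",
    "sample_outcome",
    "session_labels",
]


@dataclass
class TaskConfig:
    """Full generative specification of one task valence.

    Parameters
    ----------
    valence : {"reward", "punishment"}
        Which task version; sets the default ``outcome_magnitude``
        (+1 for reward, -1 for punishment).
    n_trials : int
        Trials per valence (default 201).
    n_sessions : int
        Number of contiguous sessions the trials are split into
        (default 3); block sizes differ by at most one trial.
    p_common : float
        Probability that a first-stage choice leads to its linked
        second-stage state (default 0.7).
    outcome_low, outcome_high : float
        Bounds of the drifting outcome probabilities (defaults 0.25, 0.75).
    walk_sd : float
        Standard deviation of the per-trial Gaussian increment of each
        outcome probability (default 0.025); increments are reflected at
        the bounds.
    outcome_magnitude : float, optional
        Value of a delivered outcome; derived from ``valence`` if omitted.
    seed : int, optional
        Seed for the outcome-probability walk when no explicit rng is given.
    """

    valence: str = REWARD
    n_trials: int = 201
    n_sessions: int = 3
    p_common: float = 0.7
    outcome_low: float = 0.25
    outcome_high: float = 0.75
    walk_sd: float = 0.025
    outcome_magnitude: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ValueError(f"valence must be one of {VALENCES}")
        if self.n_trials < 1 or self.n_sessions < 1:
            raise ValueError("n_trials and n_sessions must be positive")
        if self.n_sessions > self.n_trials:
            raise ValueError("more sessions than trials")
        if not 0.0 < self.p_common < 1.0:
            raise ValueError("p_common must lie strictly inside (0, 1)")
        if not 0.0 <= self.outcome_low <= self.outcome_high <= 1.0:
            raise ValueError("need 0 <= outcome_low <= outcome_high <= 1")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be nonnegative")
        if self.outcome_magnitude is None:
            self.outcome_magnitude = 1.0 if self.valence == REWARD else -1.0

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def session_labels(config: TaskConfig) -> np.ndarray:
    """Session index per trial: contiguous blocks with sizes differing <= 1.

    With the 201-trial, 3-session default this yields three blocks of 67.
    """
    blocks = np.array_split(np.arange(config.n_trials), config.n_sessions)
    out = np.empty(config.n_trials, dtype=np.int64)
    for i, b in enumerate(blocks):
        out[b] = i
    return out


@dataclass
class OutcomeSchedule:
    """Per-trial outcome probabilities for the four second-stage stimuli.

    ``probs`` has shape ``(n_trials, 4)``; column ``2*state + choice``
    holds the probability that stimulus ``choice`` in second-stage state
    ``state`` delivers the outcome on that trial.  The four walks evolve
    independently.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (n_trials, 4)")

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, trial: int, state2: int, choice2: int) -> float:
        return float(self.probs[trial, 2 * state2 + choice2])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"p_{s}{c}" for s in ("S1", "S2") for c in ("a", "b")]
        df = pd.DataFrame(self.probs, columns=cols)
        df.insert(0, "trial", np.arange(self.n_trials))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OutcomeSchedule":
        df = pd.read_csv(path)
        return cls(df.drop(columns=["trial"]).to_numpy())


def init_outcome_probs(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial outcome probabilities: four independent uniforms in the bounds."""
    return rng.uniform(config.outcome_low, config.outcome_high, size=4)


def _reflect(x: float, low: float, high: float) -> float:
    """Fold x back into [low, high] by reflection at the boundaries."""
    if low == high:
        return low
    width = high - low
    # triangular-wave fold, exact for any overshoot
    y = (x - low) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return low + y


def step_outcome_prob(p: float, walk_sd: float, low: float, high: float,
                      rng: np.random.Generator) -> float:
    """One Gaussian random-walk step of an outcome probability.

    The proposed value ``p + N(0, walk_sd)`` is reflected at ``low`` and
    ``high`` so the walk's stationary distribution is not inflated at the
    boundaries.
    """
    if walk_sd < 0:
        raise ValueError("walk_sd must be nonnegative")
    if not low <= p <= high:
        raise ValueError("p must lie within [low, high]")
    return _reflect(p + rng.normal(0.0, walk_sd), low, high)


def generate_schedule(config: TaskConfig, rng: np.random.Generator | None = None
                      ) -> OutcomeSchedule:
    """Generate a full outcome-probability schedule for one task valence.

    Each of the four columns starts uniform within the bounds and performs
    an independent reflected Gaussian walk; walks continue across session
    boundaries.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    probs = np.empty((config.n_trials, 4))
    probs[0] = init_outcome_probs(config, rng)
    for t in range(1, config.n_trials):
        for j in range(4):
            probs[t, j] = step_outcome_prob(
                probs[t - 1, j], config.walk_sd,
                config.outcome_low, config.outcome_high, rng,
            )
    return OutcomeSchedule(probs)


def sample_transition(choice1: int, p_common: float,
                      rng: np.random.Generator) -> Tuple[int, int]:
    """Sample the second-stage state for a first-stage choice.

    Returns ``(state2, transition)`` with ``transition`` coded 0 = common,
    1 = rare.  The common mapping is the identity (choice 0 -> state 0).
    """
    if choice1 not in (0, 1):
        raise ValueError("choice1 must be 0 or 1")
    common = rng.random() < p_common
    state2 = choice1 if common else 1 - choice1
    return state2, (0 if common else 1)


def sample_outcome(state2: int, choice2: int, schedule: OutcomeSchedule,
                   trial: int, magnitude: float,
                   rng: np.random.Generator) -> float:
    """Sample the trial outcome: ``magnitude`` with the scheduled probability, else 0."""
    if not 0 <= trial < schedule.n_trials:
        raise IndexError(f"trial {trial} outside schedule of {schedule.n_trials}")
    p = schedule.prob(trial, state2, choice2)
    return magnitude if rng.random() < p else 0.0
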