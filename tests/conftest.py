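"""Shared fixtures: hand-built trial logs and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from twostep import AgentParams, SubjectDataset, TaskConfig, simulate_subject


def make_dataset(choice1, transition, outcome, choice2=None, omitted=None,
                 valence="reward", subject_id="hand", group="G1") -> SubjectDataset:
    """Build a dataset from per-trial sequences; state2 follows the
    common-transition identity mapping."""
    choice1 = np.asarray(choice1)
    transition = np.asarray(transition)
    n = len(choice1)
    state2 = np.where(transition == 0, choice1, 1 - choice1)
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        valence=valence,
        session=np.zeros(n, dtype=int),
        choice1=choice1,
        transition=transition,
        state2=state2,
        choice2=np.zeros(n, dtype=int) if choice2 is None else np.asarray(choice2),
        outcome=np.asarray(outcome, dtype=float),
        omitted=np.zeros(n, dtype=bool) if omitted is None else np.asarray(omitted),
    )


@pytest.fixture
def hand_dataset() -> SubjectDataset:
    """Five reward-valence trials whose 2x2 stay table is enumerable by hand.

    Pairs (t, t+1), classified by trial t:
      t0 (better, common) -> stay;  t1 (worse, rare) -> shift;
      t2 (worse, common) -> stay;   t3 (better, rare) -> shift.
    """
    return make_dataset(
        choice1=[0, 0, 1, 1, 0],
        transition=[0, 1, 0, 1, 0],
        outcome=[1, 0, 0, 1, 1],
    )


@pytest.fixture(scope="session")
def sim_dataset() -> SubjectDataset:
    """One hybrid agent on the default reward task (201 trials)."""
    params = AgentParams(alpha=0.5, beta=5.0, rho=0.2, omega=0.6)
    return simulate_subject(params, TaskConfig(valence="reward"), seed=11)


@pytest.fixture(scope="session")
def sim_pair():
    """One agent's joint reward + punishment logs under shared parameters."""
    params = AgentParams(alpha=0.5, beta=5.0, rho=0.2, omega=0.6)
    rng = np.random.default_rng(42)
    return [
        simulate_subject(params, TaskConfig(valence=v), seed=rng, subject_id="s0")
        for v in ("reward", "punishment")
    ]
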