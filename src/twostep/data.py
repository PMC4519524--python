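"""Trial-log containers and CSV serialisation.

The unit of analysis is one subject's trial log for one task valence
(:class:`SubjectDataset`).  Internally trials are stored as flat numpy
arrays with integer codings; the CSV interface uses the human-readable
labels (``A``/``B`` for first-stage stimuli, ``S1``/``S2`` for
second-stage states, ``a``/``b`` for second-stage stimuli,
``common``/``rare`` for transitions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

REWARD = "reward"
PUNISHMENT = "punishment"
VALENCES = (REWARD, PUNISHMENT)

CHOICE1_LABELS = ("A", "B")
STATE2_LABELS = ("S1", "S2")
CHOICE2_LABELS = ("a", "b")
TRANSITION_LABELS = ("common", "rare")  # code 0 = common, 1 = rare

CSV_COLUMNS = [
    "subject_id",
    "group",
    "valence",
    "session",
    "trial",
    "choice1",
    "transition",
    "state2",
    "choice2",
    "outcome",
    "omitted",
]


@dataclass(frozen=True)
class TrialRecord:
    """A single two-step trial (0-based ``trial_index``)."""

    trial_index: int
    session: int
    choice1: int  # 0 = A, 1 = B
    transition: int  # 0 = common, 1 = rare
    state2: int  # 0 = S1, 1 = S2
    choice2: int  # 0 = a, 1 = b
    outcome: float
    omitted: bool = False


@dataclass
class SubjectDataset:
    """One subject's trial log for one task valence.

    Parameters are stored as columnar numpy arrays, one entry per trial in
    trial order.  ``true_params`` carries the generating agent parameters
    when the data are simulated; ``choice_logp`` optionally carries the
    log-probabilities the simulator assigned to the emitted first- and
    second-stage choices (shape ``(n_trials, 2)``).
    """

    subject_id: str
    group: str
    valence: str
    session: np.ndarray
    choice1: np.ndarray
    transition: np.ndarray
    state2: np.ndarray
    choice2: np.ndarray
    outcome: np.ndarray
    omitted: np.ndarray
    true_params: Any = None
    choice_logp: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.choice1)
        self.session = np.asarray(self.session, dtype=np.int64)
        self.choice1 = np.asarray(self.choice1, dtype=np.int64)
        self.transition = np.asarray(self.transition, dtype=np.int64)
        self.state2 = np.asarray(self.state2, dtype=np.int64)
        self.choice2 = np.asarray(self.choice2, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.float64)
        self.omitted = np.asarray(self.omitted, dtype=bool)
        for name in ("session", "transition", "state2", "choice2", "outcome", "omitted"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length mismatch with choice1")
        if self.valence not in VALENCES:
            raise ValueError(f"valence must be one of {VALENCES}, got {self.valence!r}")

    @property
    def n_trials(self) -> int:
        return len(self.choice1)

    def trials(self) -> Iterable[TrialRecord]:
        """Iterate trials as :class:`TrialRecord` objects."""
        for t in range(self.n_trials):
            yield TrialRecord(
                trial_index=t,
                session=int(self.session[t]),
                choice1=int(self.choice1[t]),
                transition=int(self.transition[t]),
                state2=int(self.state2[t]),
                choice2=int(self.choice2[t]),
                outcome=float(self.outcome[t]),
                omitted=bool(self.omitted[t]),
            )

    def to_frame(self) -> pd.DataFrame:
        """Long per-trial DataFrame using the label-based CSV dialect."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "valence": self.valence,
                "session": self.session,
                "trial": np.arange(self.n_trials),
                "choice1": np.take(CHOICE1_LABELS, self.choice1),
                "transition": np.take(TRANSITION_LABELS, self.transition),
                "state2": np.take(STATE2_LABELS, self.state2),
                "choice2": np.take(CHOICE2_LABELS, self.choice2),
                "outcome": self.outcome,
                "omitted": self.omitted.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, true_params: Any = None) -> "SubjectDataset":
        """Build a dataset from one subject/valence slice of a trial-log frame."""
        df = df.sort_values("trial")
        if df["trial"].duplicated().any():
            raise ValueError("duplicate trial indices in subject frame")
        for col, labels in (
            ("choice1", CHOICE1_LABELS),
            ("transition", TRANSITION_LABELS),
            ("state2", STATE2_LABELS),
            ("choice2", CHOICE2_LABELS),
        ):
            bad = ~df[col].isin(labels)
            if bad.any():
                raise ValueError(f"unknown {col} label(s): {sorted(df.loc[bad, col].unique())}")
        sid = str(df["subject_id"].iloc[0])
        return cls(
            subject_id=sid,
            group=str(df["group"].iloc[0]),
            valence=str(df["valence"].iloc[0]),
            session=df["session"].to_numpy(),
            choice1=np.searchsorted(CHOICE1_LABELS, df["choice1"].to_numpy()),
            transition=(df["transition"].to_numpy() == "rare").astype(np.int64),
            state2=(df["state2"].to_numpy() == "S2").astype(np.int64),
            choice2=(df["choice2"].to_numpy() == "b").astype(np.int64),
            outcome=df["outcome"].to_numpy(dtype=float),
            omitted=df["omitted"].to_numpy().astype(bool),
            true_params=true_params,
        )


def datasets_to_frame(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Concatenate datasets into one long trial-log frame."""
    if not datasets:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)[CSV_COLUMNS]


def write_csv(datasets: Sequence[SubjectDataset], path: str | Path,
              sidecar: bool = True) -> None:
    """Write trial logs as CSV; true parameters go to a ``*.params.json`` sidecar."""
    path = Path(path)
    datasets_to_frame(datasets).to_csv(path, index=False)
    if sidecar:
        params = {
            f"{d.subject_id}/{d.valence}": dataclasses.asdict(d.true_params)
            for d in datasets
            if d.true_params is not None
        }
        if params:
            path.with_suffix(".params.json").write_text(json.dumps(params, indent=1))


def read_csv(path: str | Path) -> list[SubjectDataset]:
    """Read a trial-log CSV (and its parameter sidecar, if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial-log CSV missing columns: {sorted(missing)}")
    sidecar = path.with_suffix(".params.json")
    truths: dict[str, Any] = {}
    if sidecar.exists():
        from .agents import AgentParams  # local import: avoid cycle

        truths = {k: AgentParams(**v) for k, v in json.loads(sidecar.read_text()).items()}
    out = []
    for (sid, valence), sub in df.groupby(["subject_id", "valence"], sort=True):
        out.append(SubjectDataset.from_frame(sub, true_params=truths.get(f"{sid}/{valence}")))
    return out
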