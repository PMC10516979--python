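"""Two-armed probabilistic bandit environment.

The task presents two stimuli on every trial. The "better" stimulus (labelled
``A``) pays a win with probability 2/3, the worse one (``B``) with probability
1/3; the outcome of every trial is a win (+1) or a loss (-1). A session is 75
trials of one feedback condition (social or non-social). Stimulus colour and
left/right position are counterbalancing metadata only and never enter the
computation: stimulus identity is abstracted to {A better, B worse}.

Outcomes are drawn on-line per trial, conditional on the actual choice; this
is distributionally equivalent to pre-generated reward sequences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "Condition",
    "Group",
    "TaskOrder",
    "TaskConfig",
    "TrialRecord",
    "SessionLog",
    "draw_outcome",
    "simulate_session",
    "fixed_policy",
    "session_rng",
    "write_trials_csv",
    "read_trials_csv",
    "TRIALS_CSV_COLUMNS",
]


class Stimulus(str, enum.Enum):
    """The two choice options; ``A`` is always the better-rewarded stimulus."""

    A = "A"
    B = "B"

    @property
    def other(self) -> "Stimulus":
        return Stimulus.B if self is Stimulus.A else Stimulus.A


class Condition(str, enum.Enum):
    SOCIAL = "social"
    NONSOCIAL = "nonsocial"


class Group(str, enum.Enum):
    PATIENT = "patient"
    CONTROL = "control"


class TaskOrder(str, enum.Enum):
    """Condition order: SN = social first, NS = non-social first."""

    SN = "SN"
    NS = "NS"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one bandit session.

    Defaults are the standard design: 75 trials, win probabilities 2/3 for
    the better and 1/3 for the worse stimulus.
    """

    n_trials: int = 75
    p_reward_correct: float = 2.0 / 3.0
    p_reward_incorrect: float = 1.0 / 3.0
    correct_side: str = "left"
    condition: Condition = Condition.NONSOCIAL

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (0.0 <= self.p_reward_incorrect < self.p_reward_correct <= 1.0):
            raise ValueError(
                "require 0 <= p_reward_incorrect < p_reward_correct <= 1, got "
                f"{self.p_reward_incorrect} and {self.p_reward_correct}"
            )
        if self.correct_side not in ("left", "right"):
            raise ValueError(f"correct_side must be 'left' or 'right', got {self.correct_side!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One choice/outcome/reaction-time event.

    ``outcome`` uses the ±1 reward coding: +1 win, -1 loss.
    """

    participant_id: str
    group: Group
    condition: Condition
    task_order: TaskOrder
    trial_index: int  # 1-based
    choice: Stimulus
    is_correct: bool
    outcome: int
    rt_ms: float

    def __post_init__(self) -> None:
        if self.outcome not in (-1, 1):
            raise ValueError(f"outcome must be +1 or -1, got {self.outcome}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if not (self.rt_ms > 0):
            raise ValueError(f"rt_ms must be positive, got {self.rt_ms}")


@dataclass
class SessionLog:
    """Ordered trials for one participant in one condition."""

    participant_id: str
    group: Group
    condition: Condition
    task_order: TaskOrder
    records: list[TrialRecord] = field(default_factory=list)
    rng_seed: str = ""

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records, start=1):
            if rec.trial_index != i:
                raise ValueError(
                    f"trial_index must be 1..n in order; record {i} has {rec.trial_index}"
                )
            if (
                rec.participant_id != self.participant_id
                or rec.group != self.group
                or rec.condition != self.condition
                or rec.task_order != self.task_order
            ):
                raise ValueError(f"record {i} metadata differs from session metadata")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def choices(self) -> list[Stimulus]:
        return [r.choice for r in self.records]

    @property
    def outcomes(self) -> list[int]:
        return [r.outcome for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "group": [r.group.value for r in self.records],
                "condition": [r.condition.value for r in self.records],
                "task_order": [r.task_order.value for r in self.records],
                "trial": [r.trial_index for r in self.records],
                "choice": [r.choice.value for r in self.records],
                "is_correct": [r.is_correct for r in self.records],
                "outcome": [r.outcome for r in self.records],
                "rt_ms": [r.rt_ms for r in self.records],
            }
        )


class AgentPolicy(Protocol):
    """Contract for agents driving :func:`simulate_session`."""

    def choose(self, rng: np.random.Generator) -> Stimulus: ...

    def observe(self, choice: Stimulus, outcome: int) -> None: ...


def session_rng(master_seed: int, *counters: int) -> np.random.Generator:
    """Derive a named, reproducible per-session RNG from a master seed.

    Uses numpy's SeedSequence spawn-key mechanism with the given counters
    (e.g. participant index, condition index), so cohorts are reproducible
    and sessions statistically independent.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(counters)))


def draw_outcome(choice: Stimulus, config: TaskConfig, rng: np.random.Generator) -> int:
    """Draw the ±1 outcome of one trial given the chosen stimulus."""
    if not isinstance(choice, Stimulus):
        raise TypeError(f"choice must be a Stimulus, got {choice!r}")
    p_win = config.p_reward_correct if choice is Stimulus.A else config.p_reward_incorrect
    return 1 if rng.random() < p_win else -1


def simulate_session(
    agent: AgentPolicy,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "sim",
    group: Group = Group.CONTROL,
    task_order: TaskOrder = TaskOrder.NS,
    rt_sampler: Callable[[int, np.random.Generator], float] | None = None,
    rng_seed: str = "",
) -> SessionLog:
    """Run one agent through one session and return the trial log.

    The agent's ``choose`` is called each trial (it may consume randomness
    from ``rng``) and ``observe`` is called with the realized outcome so
    stateful agents can learn. With a fixed seed, agent and config the log is
    bit-reproducible. ``rt_sampler(trial_index, rng) -> ms`` supplies
    reaction times; defaults to a constant 1000 ms placeholder.
    """
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        choice = agent.choose(rng)
        if not isinstance(choice, Stimulus):
            raise ValueError(f"agent returned invalid stimulus {choice!r} at trial {t}")
        outcome = draw_outcome(choice, config, rng)
        rt = 1000.0 if rt_sampler is None else float(rt_sampler(t, rng))
        records.append(
            TrialRecord(
                participant_id=participant_id,
                group=group,
                condition=config.condition,
                task_order=task_order,
                trial_index=t,
                choice=choice,
                is_correct=choice is Stimulus.A,
                outcome=outcome,
                rt_ms=rt,
            )
        )
        agent.observe(choice, outcome)
    return SessionLog(
        participant_id=participant_id,
        group=group,
        condition=config.condition,
        task_order=task_order,
        records=records,
        rng_seed=rng_seed,
    )


class _FixedAgent:
    def __init__(self, rule: Callable[[int, np.random.Generator], Stimulus]):
        self._rule = rule
        self._t = 0

    def choose(self, rng: np.random.Generator) -> Stimulus:
        c = self._rule(self._t, rng)
        self._t += 1
        return c

    def observe(self, choice: Stimulus, outcome: int) -> None:
        pass


def fixed_policy(kind: str, p: float | None = None) -> AgentPolicy:
    """Reference agents: ``always_correct``, ``always_incorrect``,
    ``uniform_random``, ``biased`` (choose A with probability ``p``) and
    ``alternating`` (switch stimulus every trial, starting at A)."""
    if kind == "always_correct":
        return _FixedAgent(lambda t, rng: Stimulus.A)
    if kind == "always_incorrect":
        return _FixedAgent(lambda t, rng: Stimulus.B)
    if kind == "uniform_random":
        return _FixedAgent(lambda t, rng: Stimulus.A if rng.random() < 0.5 else Stimulus.B)
    if kind == "biased":
        if p is None or not (0.0 <= p <= 1.0):
            raise ValueError(f"biased policy requires p in [0, 1], got {p}")
        return _FixedAgent(lambda t, rng: Stimulus.A if rng.random() < p else Stimulus.B)
    if kind == "alternating":
        return _FixedAgent(lambda t, rng: Stimulus.A if t % 2 == 0 else Stimulus.B)
    raise ValueError(f"unknown fixed policy kind {kind!r}")


TRIALS_CSV_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "task_order",
    "trial",
    "choice",
    "is_correct",
    "outcome",
    "rt_ms",
]


def write_trials_csv(logs: Sequence[SessionLog], path) -> None:
    """Serialize sessions as tidy CSV, one row per trial (UTF-8, '.' decimals)."""
    frames = [log.to_frame() for log in logs]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRIALS_CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials_csv(path) -> list[SessionLog]:
    """Load sessions from the tidy trial CSV; validates schema and invariants."""
    df = pd.read_csv(path)
    missing = [c for c in TRIALS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials CSV missing columns: {missing}")
    return sessions_from_frame(df)


def sessions_from_frame(df: pd.DataFrame) -> list[SessionLog]:
    """Split a tidy trials table into per-session logs (participant × condition)."""
    logs = []
    for (pid, cond), sub in df.groupby(["participant_id", "condition"], sort=True):
        sub = sub.sort_values("trial")
        group = Group(sub["group"].iloc[0])
        order = TaskOrder(sub["task_order"].iloc[0])
        records = [
            TrialRecord(
                participant_id=str(pid),
                group=group,
                condition=Condition(cond),
                task_order=order,
                trial_index=int(row.trial),
                choice=Stimulus(row.choice),
                is_correct=bool(row.is_correct),
                outcome=int(row.outcome),
                rt_ms=float(row.rt_ms),
            )
            for row in sub.itertuples()
        ]
        logs.append(
            SessionLog(
                participant_id=str(pid),
                group=group,
                condition=Condition(cond),
                task_order=order,
                records=records,
            )
        )
    return logs
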