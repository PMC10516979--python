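import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socialbandit.task_engine import (
    Condition,
    Group,
    SessionLog,
    Stimulus,
    TaskOrder,
    TrialRecord,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_log(
    choices,
    outcomes,
    rts=None,
    participant_id="p001",
    group=Group.CONTROL,
    condition=Condition.NONSOCIAL,
    task_order=TaskOrder.NS,
) -> SessionLog:
    """Build a session log from explicit choice/outcome sequences."""
    if rts is None:
        rts = [1000.0] * len(choices)
    records = [
        TrialRecord(
            participant_id=participant_id,
            group=group,
            condition=condition,
            task_order=task_order,
            trial_index=t + 1,
            choice=Stimulus(c) if not isinstance(c, Stimulus) else c,
            is_correct=(Stimulus(c) if not isinstance(c, Stimulus) else c) is Stimulus.A,
            outcome=o,
            rt_ms=r,
        )
        for t, (c, o, r) in enumerate(zip(choices, outcomes, rts))
    ]
    return SessionLog(
        participant_id=participant_id,
        group=group,
        condition=condition,
        task_order=task_order,
        records=records,
    )


def random_log(rng: np.random.Generator, n_trials: int = 10) -> SessionLog:
    """A log with uniformly random choices and outcomes (not from any model)."""
    choices = ["A" if rng.random() < 0.5 else "B" for _ in range(n_trials)]
    outcomes = [1 if rng.random() < 0.5 else -1 for _ in range(n_trials)]
    return make_log(choices, outcomes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
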