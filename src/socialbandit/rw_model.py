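"""Rescorla–Wagner delta-rule learner with SoftMax choice.

The single-update model: after choosing stimulus c at trial t and receiving
reward r ∈ {+1, −1},

    V(c)_{t+1} = V(c)_t + α · (r_t − V(c)_t)

with learning rate α ∈ [0, 1]; only the chosen option's value is updated.
Both values start at 0 (the agent is ignorant at trial 1). Values map to
choice probabilities through the SoftMax

    P(c) = exp(β V(c)) / (exp(β V(c)) + exp(β V(nc)))

where the inverse temperature β ≥ 0 sets the exploration–exploitation
balance: β = 0 is uniform random choice, large β is near-greedy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task_engine import SessionLog, Stimulus

__all__ = [
    "BETA_MAX",
    "AgentParams",
    "ValueState",
    "UpdateResult",
    "delta_update",
    "softmax_prob",
    "session_nll",
    "rw_policy",
    "RWAgent",
]

# softmax saturates well below this for |ΔV| <= 2, so larger β are
# behaviourally indistinguishable on ±1 rewards
BETA_MAX = 20.0

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class AgentParams:
    """Learning rate α ∈ [0, 1] and inverse temperature β ∈ [0, beta_max]."""

    alpha: float
    beta: float
    beta_max: float = BETA_MAX

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= self.beta_max):
            raise ValueError(f"beta must be in [0, {self.beta_max}], got {self.beta}")


@dataclass
class ValueState:
    """Expected values V(c) of the two stimuli; both start at 0."""

    v: dict[Stimulus, float] = field(
        default_factory=lambda: {Stimulus.A: 0.0, Stimulus.B: 0.0}
    )

    def value(self, stim: Stimulus) -> float:
        return self.v[stim]


@dataclass(frozen=True)
class UpdateResult:
    new_value: float
    prediction_error: float


def delta_update(
    state: ValueState, choice: Stimulus, outcome: int, alpha: float
) -> UpdateResult:
    """Apply the delta rule to the chosen stimulus's value, in place.

    The unchosen stimulus is untouched (single-update model). Rewards must
    be coded ±1; a 0/1-coded log is a hard error to guard against reward
    miscoding.
    """
    if outcome not in (-1, 1):
        raise ValueError(f"outcome must be +1 or -1 (±1 reward coding), got {outcome}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    old = state.v[choice]
    delta = outcome - old
    new = old + alpha * delta
    state.v[choice] = new
    return UpdateResult(new_value=new, prediction_error=delta)


def softmax_prob(state: ValueState, choice: Stimulus, beta: float) -> float:
    """Probability of the given choice under the two-option SoftMax.

    Computed with max-subtraction so large β·V are numerically safe.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    vc = state.v[choice]
    vn = state.v[choice.other]
    if not (math.isfinite(vc) and math.isfinite(vn)):
        raise ValueError(f"non-finite values V={state.v}")
    m = max(beta * vc, beta * vn)
    ec = math.exp(beta * vc - m)
    en = math.exp(beta * vn - m)
    return ec / (ec + en)


def session_nll(log: SessionLog, params: AgentParams) -> float:
    """Negative log-likelihood of a session under (α, β).

    Walks the trials in order, accumulating −ln P(choice_t) from the SoftMax
    and then updating the chosen value with the observed outcome. The first
    trial is included (both values 0, so it contributes ln 2). Probabilities
    are floored at 1e−300 before the log; with the stable SoftMax this never
    binds for β ≤ BETA_MAX.
    """
    if len(log) == 0:
        raise ValueError("cannot compute likelihood of an empty session")
    choices = np.fromiter(
        (0 if c is Stimulus.A else 1 for c in log.choices), dtype=np.int64, count=len(log)
    )
    outcomes = np.fromiter(log.outcomes, dtype=np.int64, count=len(log))
    return _nll_arrays(choices, outcomes, params.alpha, params.beta)


def _nll_arrays(
    choices: np.ndarray, outcomes: np.ndarray, alpha: float, beta: float
) -> float:
    """Fast inner loop over integer-coded trials (0 = A, 1 = B)."""
    v = [0.0, 0.0]
    nll = 0.0
    for c, r in zip(choices.tolist(), outcomes.tolist()):
        d = beta * (v[c] - v[1 - c])
        # logistic of the value difference, stable in both tails
        if d >= 0:
            p = 1.0 / (1.0 + math.exp(-d))
        else:
            e = math.exp(d)
            p = e / (1.0 + e)
        nll -= math.log(max(p, _LOG_FLOOR))
        v[c] += alpha * (r - v[c])
    return nll


class RWAgent:
    """Stateful Rescorla–Wagner agent usable with ``simulate_session``."""

    def __init__(self, params: AgentParams):
        self.params = params
        self.state = ValueState()

    def choose(self, rng: np.random.Generator) -> Stimulus:
        p_a = softmax_prob(self.state, Stimulus.A, self.params.beta)
        return Stimulus.A if rng.random() < p_a else Stimulus.B

    def observe(self, choice: Stimulus, outcome: int) -> None:
        delta_update(self.state, choice, outcome, self.params.alpha)


def rw_policy(params: AgentParams) -> RWAgent:
    """Fresh RW agent (values at 0) for simulation."""
    return RWAgent(params)
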