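"""Maximum-likelihood fitting, AIC model comparison, and recovery studies.

Each session (one participant × one condition) is fitted independently, so
every participant gets one (α, β) pair per condition. Candidate models:

* ``rw_single_update`` — the 2-parameter delta-rule/SoftMax learner;
* ``random_choice``    — 0 parameters, p = 1/2 each trial (the engagement
  control: it should lose to the learner on real learners' data);
* ``biased_choice``    — 1 parameter, a fixed side bias (guards the random
  comparison against participants who simply prefer one stimulus);
* ``rw_dual_update``   — optional variant in which the unchosen option's
  value additionally decays toward 0 at rate α. Not part of the default
  comparison set; a stand-in for "alternative learning model" slots only.

Models are compared with AIC = 2k + 2·NLL.

The likelihood surface of (α, β) has a known ridge (high α / low β trades
off against low α / high β), so the optimizer is a bounded local search
restarted from multiple points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rw_model import BETA_MAX, AgentParams, _nll_arrays, rw_policy, session_nll
from .task_engine import SessionLog, Stimulus, TaskConfig, simulate_session

__all__ = [
    "FitResult",
    "RecoveryReport",
    "fit_rw",
    "fit_random",
    "fit_biased",
    "compare_models",
    "parameter_recovery",
    "model_recovery",
    "fit_sessions",
]

_N_PARAMS = {"rw_single_update": 2, "random_choice": 0, "biased_choice": 1, "rw_dual_update": 2}


@dataclass(frozen=True)
class FitResult:
    """One model fitted to one session."""

    model_name: str
    params: dict[str, float]
    nll: float
    aic: float
    n_trials: int
    participant_id: str
    condition: str
    n_starts: int = 1
    converged: bool = True
    best_start: tuple[float, ...] = ()

    @property
    def k(self) -> int:
        return _N_PARAMS[self.model_name]


def _session_arrays(log: SessionLog) -> tuple[np.ndarray, np.ndarray]:
    choices = np.fromiter(
        (0 if c is Stimulus.A else 1 for c in log.choices), dtype=np.int64, count=len(log)
    )
    outcomes = np.fromiter(log.outcomes, dtype=np.int64, count=len(log))
    return choices, outcomes


def fit_rw(
    log: SessionLog,
    n_starts: int = 10,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, BETA_MAX)),
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit (α, β) by bounded multi-start maximum likelihood.

    The first start is fixed at (0.5, 1.0); the remaining ``n_starts − 1``
    are drawn uniformly inside the bounds from ``rng``, making the fit
    deterministic given the seed. Returns the best local optimum found.
    """
    if len(log) < 2:
        raise ValueError("need at least 2 trials to fit the learning model")
    if n_starts < 1:
        raise ValueError(f"n_starts must be >= 1, got {n_starts}")
    if rng is None:
        rng = np.random.default_rng(0)
    choices, outcomes = _session_arrays(log)

    def objective(x: np.ndarray) -> float:
        return _nll_arrays(choices, outcomes, float(x[0]), float(x[1]))

    (a_lo, a_hi), (b_lo, b_hi) = bounds
    # fixed starts first: the centre, then low-β corners where a separate
    # shallow optimum often hides on short noisy sessions; the rest random
    fixed = [(0.5, 1.0), (0.9, 0.3), (0.1, 0.3), (0.5, 5.0)]
    starts = [
        (min(max(a, a_lo), a_hi), min(max(b, b_lo), b_hi)) for a, b in fixed[:n_starts]
    ]
    for _ in range(n_starts - len(starts)):
        starts.append((rng.uniform(a_lo, a_hi), rng.uniform(b_lo, b_hi)))

    best = None
    best_start: tuple[float, ...] = ()
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(a_lo, a_hi), (b_lo, b_hi)],
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
            best_start = tuple(float(v) for v in x0)
    assert best is not None
    if not any_converged:
        warnings.warn(
            f"fit_rw: no start converged for session {log.participant_id}/{log.condition.value}; "
            "returning best incumbent",
            RuntimeWarning,
        )
    alpha = float(np.clip(best.x[0], a_lo, a_hi))
    beta = float(np.clip(best.x[1], b_lo, b_hi))
    nll = float(best.fun)
    return FitResult(
        model_name="rw_single_update",
        params={"alpha": alpha, "beta": beta},
        nll=nll,
        aic=2 * 2 + 2 * nll,
        n_trials=len(log),
        participant_id=log.participant_id,
        condition=log.condition.value,
        n_starts=n_starts,
        converged=any_converged,
        best_start=best_start,
    )


def _nll_dual(choices: np.ndarray, outcomes: np.ndarray, alpha: float, beta: float) -> float:
    """Dual-update likelihood: the unchosen value also decays toward 0 at α."""
    v = [0.0, 0.0]
    nll = 0.0
    for c, r in zip(choices.tolist(), outcomes.tolist()):
        d = beta * (v[c] - v[1 - c])
        if d >= 0:
            p = 1.0 / (1.0 + math.exp(-d))
        else:
            e = math.exp(d)
            p = e / (1.0 + e)
        nll -= math.log(max(p, 1e-300))
        v[c] += alpha * (r - v[c])
        v[1 - c] -= alpha * v[1 - c]
    return nll


def fit_rw_dual(
    log: SessionLog,
    n_starts: int = 10,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, BETA_MAX)),
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Optional 2-parameter variant in which the unchosen option's value
    decays toward 0 at rate α.

    A generic alternative-model slot, not a calibrated competitor; it is
    excluded from the default comparison set.
    """
    if len(log) < 2:
        raise ValueError("need at least 2 trials to fit the learning model")
    if rng is None:
        rng = np.random.default_rng(0)
    choices, outcomes = _session_arrays(log)
    (a_lo, a_hi), (b_lo, b_hi) = bounds
    best = None
    best_start: tuple[float, ...] = ()
    any_converged = False
    starts = [(0.5, 1.0)] + [
        (rng.uniform(a_lo, a_hi), rng.uniform(b_lo, b_hi)) for _ in range(n_starts - 1)
    ]
    for x0 in starts:
        res = optimize.minimize(
            lambda x: _nll_dual(choices, outcomes, float(x[0]), float(x[1])),
            np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(a_lo, a_hi), (b_lo, b_hi)],
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_start = res, tuple(float(v) for v in x0)
    nll = float(best.fun)
    return FitResult(
        model_name="rw_dual_update",
        params={"alpha": float(best.x[0]), "beta": float(best.x[1])},
        nll=nll,
        aic=2 * 2 + 2 * nll,
        n_trials=len(log),
        participant_id=log.participant_id,
        condition=log.condition.value,
        n_starts=n_starts,
        converged=any_converged,
        best_start=best_start,
    )


def fit_random(log: SessionLog) -> FitResult:
    """Zero-parameter random-choice control: p = 1/2 every trial."""
    if len(log) == 0:
        raise ValueError("empty session")
    nll = len(log) * math.log(2.0)
    return FitResult(
        model_name="random_choice",
        params={},
        nll=nll,
        aic=2 * nll,
        n_trials=len(log),
        participant_id=log.participant_id,
        condition=log.condition.value,
    )


def fit_biased(log: SessionLog) -> FitResult:
    """One-parameter Bernoulli side-bias model; the MLE is the A-choice rate."""
    if len(log) == 0:
        raise ValueError("empty session")
    n = len(log)
    n_a = sum(1 for c in log.choices if c is Stimulus.A)
    p_hat = min(max(n_a / n, 1e-9), 1.0 - 1e-9)
    nll = -(n_a * math.log(p_hat) + (n - n_a) * math.log(1.0 - p_hat))
    return FitResult(
        model_name="biased_choice",
        params={"p_a": p_hat},
        nll=nll,
        aic=2 * 1 + 2 * nll,
        n_trials=len(log),
        participant_id=log.participant_id,
        condition=log.condition.value,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of one session by AIC (ascending), with ΔAIC to the best.

    Ties are broken by fewer free parameters, then by model name, so the
    ranking is deterministic.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    keys = {(f.participant_id, f.condition, f.n_trials) for f in fits}
    if len(keys) != 1:
        raise ValueError(f"fits come from different sessions: {sorted(keys)}")
    rows = sorted(fits, key=lambda f: (f.aic, f.k, f.model_name))
    best_aic = rows[0].aic
    return pd.DataFrame(
        {
            "model": [f.model_name for f in rows],
            "k": [f.k for f in rows],
            "nll": [f.nll for f in rows],
            "aic": [f.aic for f in rows],
            "delta_aic": [f.aic - best_aic for f in rows],
        }
    )


@dataclass
class RecoveryReport:
    """Simulate-and-refit summary for the fitting pipeline."""

    true_alpha: np.ndarray
    true_beta: np.ndarray
    est_alpha: np.ndarray
    est_beta: np.ndarray
    n_agents: int
    n_trials: int
    seed: int
    degenerate_prior: bool = False
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)
    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            t = getattr(self, f"true_{name}")
            e = getattr(self, f"est_{name}")
            if len(t) != len(e) or len(t) != self.n_agents:
                raise ValueError("true/recovered arrays must both have length n_agents")
            if np.ptp(t) > 0:
                rho, p = stats.spearmanr(t, e)
                self.spearman[name] = (float(rho), float(p))
            else:
                self.spearman[name] = (float("nan"), float("nan"))
            self.bias[name] = float(np.mean(e - t))
            self.rmse[name] = float(np.sqrt(np.mean((e - t) ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent": np.arange(self.n_agents),
                "true_alpha": self.true_alpha,
                "true_beta": self.true_beta,
                "est_alpha": self.est_alpha,
                "est_beta": self.est_beta,
            }
        )

    def summary(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "degenerate_prior": self.degenerate_prior,
            "spearman_alpha": self.spearman["alpha"][0],
            "spearman_alpha_p": self.spearman["alpha"][1],
            "spearman_beta": self.spearman["beta"][0],
            "spearman_beta_p": self.spearman["beta"][1],
            "bias_alpha": self.bias["alpha"],
            "bias_beta": self.bias["beta"],
            "rmse_alpha": self.rmse["alpha"],
            "rmse_beta": self.rmse["beta"],
        }


def parameter_recovery(
    n_agents: int,
    prior: dict[str, tuple[float, float]] | None = None,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    n_starts: int = 10,
    seed_label: int = 0,
) -> RecoveryReport:
    """Simulate agents with known (α, β), refit, and quantify agreement.

    ``prior`` gives the uniform sampling ranges, default α ~ U(0.1, 0.9),
    β ~ U(0.5, 5). Zero-width ranges are allowed but flagged in the report.
    """
    if n_agents < 10:
        raise ValueError(f"n_agents must be >= 10, got {n_agents}")
    prior = prior or {"alpha": (0.1, 0.9), "beta": (0.5, 5.0)}
    config = config or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    degenerate = any(hi <= lo for lo, hi in prior.values())

    true_a = rng.uniform(*prior["alpha"], size=n_agents)
    true_b = rng.uniform(*prior["beta"], size=n_agents)
    est_a = np.empty(n_agents)
    est_b = np.empty(n_agents)
    for i in range(n_agents):
        agent = rw_policy(AgentParams(float(true_a[i]), float(true_b[i])))
        log = simulate_session(agent, config, rng, participant_id=f"recov{i:03d}")
        fit = fit_rw(log, n_starts=n_starts, rng=rng)
        est_a[i] = fit.params["alpha"]
        est_b[i] = fit.params["beta"]
    return RecoveryReport(
        true_alpha=true_a,
        true_beta=true_b,
        est_alpha=est_a,
        est_beta=est_b,
        n_agents=n_agents,
        n_trials=config.n_trials,
        seed=seed_label,
        degenerate_prior=degenerate,
    )


def model_recovery(
    n_agents: int,
    generating_models: list[tuple[str, AgentParams | None]],
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    n_starts: int = 10,
) -> pd.DataFrame:
    """Confusion matrix of generating model × best-AIC model.

    Each generator ("rw" with params, or "random") simulates ``n_agents``
    sessions; each session is fitted with the default candidate set
    (rw_single_update vs random_choice) and classified by lowest AIC.
    Rows sum to ``n_agents``.
    """
    if len(generating_models) < 2:
        raise ValueError("need at least 2 generating models")
    config = config or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    from .task_engine import fixed_policy

    candidates = ["rw_single_update", "random_choice"]
    counts = {name: {c: 0 for c in candidates} for name, _ in generating_models}
    for gen_name, gen_params in generating_models:
        for i in range(n_agents):
            if gen_name.startswith("rw"):
                assert gen_params is not None
                agent = rw_policy(gen_params)
            elif gen_name == "random":
                agent = fixed_policy("uniform_random")
            else:
                raise ValueError(f"unknown generating model {gen_name!r}")
            log = simulate_session(agent, config, rng, participant_id=f"{gen_name}{i:03d}")
            fits = [fit_rw(log, n_starts=n_starts, rng=rng), fit_random(log)]
            winner = compare_models(fits)["model"].iloc[0]
            counts[gen_name][winner] += 1
    return pd.DataFrame(counts).T[candidates]


def fit_sessions(
    logs: list[SessionLog],
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fit the default candidate set to every session; tidy results table.

    Columns: participant_id, group, condition, model, alpha, beta, nll, aic,
    converged — one row per session × model.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for log in logs:
        for fit in (fit_rw(log, n_starts=n_starts, rng=rng), fit_random(log), fit_biased(log)):
            rows.append(
                {
                    "participant_id": log.participant_id,
                    "group": log.group.value,
                    "condition": log.condition.value,
                    "model": fit.model_name,
                    "alpha": fit.params.get("alpha", np.nan),
                    "beta": fit.params.get("beta", np.nan),
                    "nll": fit.nll,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
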