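"""Synthetic study cohorts for the social / non-social bandit design.

Generates complete datasets — trial logs, reaction times, affective
ratings, and a manifest of the true generating parameters — with the
structure the analysis pipeline assumes:

* two groups (35 patient-like, 37 control-like participants);
* two conditions per participant (social, non-social), 75 trials each,
  in counterbalanced order (every second participant per group is
  social-first);
* choices produced by Rescorla–Wagner/SoftMax agents whose (α, β) are
  drawn per participant; the social condition multiplies β by a per-group
  factor (default 0.6 for controls — social feedback shifts controls
  toward exploration — and 1.0 for patients, i.e. no condition effect);
* lognormal reaction times whose log-location decreases linearly over
  blocks and is larger (slower, more variable) in the social condition;
* 1–7 Likert affective ratings from a discretized clipped normal around
  per-group × item means.

α is condition-invariant by default, mirroring a condition effect on the
exploration–exploitation balance only, not on the update rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rw_model import AgentParams, BETA_MAX, rw_policy
from .task_engine import (
    Condition,
    Group,
    SessionLog,
    TaskConfig,
    TaskOrder,
    session_rng,
    simulate_session,
    write_trials_csv,
)

__all__ = ["RTParams", "CohortConfig", "Cohort", "generate_cohort", "generate_null_cohort"]

# qualitative group x item pattern of affective ratings: wins and win-feedback
# pleasant (> 4), losses unpleasant (< 4); controls rate non-social feedback
# higher than patients do
DEFAULT_RATING_MEANS = {
    "patient": {
        "win_social": 4.84,
        "win_nonsocial": 4.84,
        "lose_social": 3.52,
        "lose_nonsocial": 3.25,
        "feedback_social": 5.35,
        "feedback_nonsocial": 5.09,
    },
    "control": {
        "win_social": 5.44,
        "win_nonsocial": 5.42,
        "lose_social": 3.08,
        "lose_nonsocial": 2.91,
        "feedback_social": 5.47,
        "feedback_nonsocial": 5.64,
    },
}


@dataclass(frozen=True)
class RTParams:
    """Lognormal reaction-time model (milliseconds).

    ``meanlog`` is the log-location of the non-social condition in block 1
    (exp(6.8) ≈ 0.9 s, realistic for an online two-choice task);
    ``block_slope`` is subtracted per block (responses speed up);
    ``social_shift`` is added to the location and ``sdlog_social`` exceeds
    ``sdlog_nonsocial`` (social feedback slows responses and makes them
    more variable).
    """

    meanlog: float = 6.8
    social_shift: float = 0.15
    block_slope: float = 0.04
    sdlog_nonsocial: float = 0.35
    sdlog_social: float = 0.45
    block_size: int = 15


@dataclass(frozen=True)
class CohortConfig:
    n_patient: int = 35
    n_control: int = 37
    task: TaskConfig = field(default_factory=TaskConfig)
    alpha_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"patient": (0.3, 0.9), "control": (0.3, 0.9)}
    )
    beta_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"patient": (1.0, 5.0), "control": (1.0, 5.0)}
    )
    beta_social_multiplier: dict[str, float] = field(
        default_factory=lambda: {"patient": 1.0, "control": 0.6}
    )
    rt: RTParams = field(default_factory=RTParams)
    rating_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_RATING_MEANS.items()}
    )
    rating_sd: float = 1.2
    # participants dropped from the second condition per group (dropout path)
    n_dropout: dict[str, int] = field(default_factory=lambda: {"patient": 0, "control": 0})
    master_seed: int = 0
    null: bool = False

    def __post_init__(self) -> None:
        for g in ("patient", "control"):
            a_lo, a_hi = self.alpha_range[g]
            b_lo, b_hi = self.beta_range[g]
            if not (0.0 <= a_lo <= a_hi <= 1.0):
                raise ValueError(f"alpha_range for {g} outside [0, 1]: {(a_lo, a_hi)}")
            if not (0.0 <= b_lo <= b_hi <= BETA_MAX):
                raise ValueError(f"beta_range for {g} outside [0, {BETA_MAX}]: {(b_lo, b_hi)}")
            if self.beta_social_multiplier[g] <= 0:
                raise ValueError("beta_social_multiplier must be > 0")


@dataclass
class Cohort:
    logs: list[SessionLog]
    trials: pd.DataFrame
    ratings: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        """Write trials.csv, ratings.csv and manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trials_csv(self.logs, outdir / "trials.csv")
        self.ratings.to_csv(outdir / "ratings.csv", index=False, encoding="utf-8")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _rt_sampler(params: RTParams, condition: Condition):
    social = condition is Condition.SOCIAL
    loc0 = params.meanlog + (params.social_shift if social else 0.0)
    sdlog = params.sdlog_social if social else params.sdlog_nonsocial

    def sample(trial_index: int, rng: np.random.Generator) -> float:
        block = (trial_index - 1) // params.block_size  # 0-based
        return float(rng.lognormal(loc0 - params.block_slope * block, sdlog))

    return sample


def _draw_rating(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), 1, 7))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    Per participant: (α, β_base) is drawn uniformly from the group's
    ranges; the social condition uses β_base × the group multiplier. Both
    conditions are simulated in the assigned counterbalanced order
    (alternating SN/NS within group). All randomness descends from
    ``master_seed`` via per-(participant, condition) spawn keys, so the
    same seed reproduces the cohort byte-for-byte.
    """
    config = config or CohortConfig()
    logs: list[SessionLog] = []
    rating_rows = []
    participants = []

    p_counter = 0
    for group, n in ((Group.PATIENT, config.n_patient), (Group.CONTROL, config.n_control)):
        gname = group.value
        drop_from = n - config.n_dropout[gname]  # last participants lose their 2nd condition
        for i in range(n):
            pid = f"{gname[0]}{i + 1:03d}"
            order = TaskOrder.SN if i % 2 == 0 else TaskOrder.NS
            prng = session_rng(config.master_seed, p_counter, 99)
            a_lo, a_hi = config.alpha_range[gname]
            b_lo, b_hi = config.beta_range[gname]
            alpha = float(prng.uniform(a_lo, a_hi))
            beta_base = float(prng.uniform(b_lo, b_hi))
            conditions = (
                (Condition.SOCIAL, Condition.NONSOCIAL)
                if order is TaskOrder.SN
                else (Condition.NONSOCIAL, Condition.SOCIAL)
            )
            dropped = i >= drop_from
            true_params = {}
            for j, cond in enumerate(conditions):
                if dropped and j == 1:
                    continue
                mult = config.beta_social_multiplier[gname] if cond is Condition.SOCIAL else 1.0
                beta = min(beta_base * mult, BETA_MAX)
                true_params[cond.value] = {"alpha": alpha, "beta": beta}
                agent = rw_policy(AgentParams(alpha, beta))
                task = dataclasses.replace(config.task, condition=cond)
                rng = session_rng(config.master_seed, p_counter, j)
                log = simulate_session(
                    agent,
                    task,
                    rng,
                    participant_id=pid,
                    group=group,
                    task_order=order,
                    rt_sampler=_rt_sampler(config.rt, cond),
                    rng_seed=f"{config.master_seed}:{p_counter}:{j}",
                )
                logs.append(log)
            rat_rng = session_rng(config.master_seed, p_counter, 98)
            for item, mean in config.rating_means[gname].items():
                rating_rows.append(
                    {
                        "participant_id": pid,
                        "group": gname,
                        "item": item,
                        "rating": _draw_rating(rat_rng, mean, config.rating_sd),
                    }
                )
            participants.append(
                {
                    "participant_id": pid,
                    "group": gname,
                    "task_order": order.value,
                    "dropped_second_condition": dropped,
                    "true_params": true_params,
                }
            )
            p_counter += 1

    trials = pd.concat([log.to_frame() for log in logs], ignore_index=True)
    ratings = pd.DataFrame(rating_rows)
    manifest = {
        "null": config.null,
        "master_seed": config.master_seed,
        "n_patient": config.n_patient,
        "n_control": config.n_control,
        "n_trials": config.task.n_trials,
        "beta_social_multiplier": dict(config.beta_social_multiplier),
        "alpha_range": {g: list(r) for g, r in config.alpha_range.items()},
        "beta_range": {g: list(r) for g, r in config.beta_range.items()},
        "participants": participants,
    }
    return Cohort(logs=logs, trials=trials, ratings=ratings, manifest=manifest)


def generate_null_cohort(config: CohortConfig | None = None) -> Cohort:
    """Cohort with every group/condition effect switched off.

    β multipliers are 1 for both groups, parameter ranges and rating means
    are shared (control values), and the RT social shift is removed. Used
    for type-I-error calibration of the group statistics.
    """
    config = config or CohortConfig()
    shared_alpha = config.alpha_range["control"]
    shared_beta = config.beta_range["control"]
    shared_means = {g: dict(config.rating_means["control"]) for g in ("patient", "control")}
    null_cfg = dataclasses.replace(
        config,
        alpha_range={"patient": shared_alpha, "control": shared_alpha},
        beta_range={"patient": shared_beta, "control": shared_beta},
        beta_social_multiplier={"patient": 1.0, "control": 1.0},
        rating_means=shared_means,
        rt=dataclasses.replace(config.rt, social_shift=0.0, sdlog_social=config.rt.sdlog_nonsocial),
        null=True,
    )
    return generate_cohort(null_cfg)
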