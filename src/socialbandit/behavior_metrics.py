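"""Directly observable choice-behavior variables and QC.

Per session (and per block of 15 trials):

* %correct      — share of trials choosing the better stimulus;
* %volatility   — share of trial-to-trial transitions that are switches;
* %switch-win   — share of win trials followed by a switch;
* %switch-lose  — share of loss trials followed by a switch (lose-shift);
* RT median and MAD (median absolute deviation, unscaled).

Sessions in which one stimulus was chosen on strictly more than 90% of
trials are flagged for exclusion (the participant never explored both
options). Percentages are square-root transformed on the proportion scale
before parametric statistics, which approximately normalizes them.

Block-scope switch metrics use only within-block transitions by default, so
block summaries are mutually independent; set ``cross_block=True`` to count
the transition into each block against the previous block's last trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_engine import SessionLog, Stimulus

__all__ = [
    "BehaviorSummary",
    "assign_blocks",
    "pct_correct",
    "pct_volatility",
    "pct_switch_after",
    "rt_summary",
    "qc_exclude",
    "sqrt_transform",
    "session_summary",
    "summarize_sessions",
]

DEFAULT_BLOCK_SIZE = 15
QC_THRESHOLD = 0.90


@dataclass(frozen=True)
class BehaviorSummary:
    """Choice and RT summaries for one scope (whole session or one block)."""

    participant_id: str
    group: str
    condition: str
    block: int  # 0 = whole session
    n_trials: int
    pct_correct: float
    pct_volatility: float
    pct_switch_win: float
    pct_switch_lose: float
    rt_median_ms: float
    rt_mad_ms: float
    excluded: bool = False
    exclusion_reason: str = ""


def assign_blocks(log: SessionLog, block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Contiguous 1-based block index per trial: 1–15 → 1, …, 61–75 → 5.

    A trailing partial block is kept and flagged with a warning.
    """
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    n = len(log)
    if n % block_size != 0:
        warnings.warn(
            f"{n} trials not divisible by block size {block_size}; trailing partial block",
            UserWarning,
        )
    return np.arange(n) // block_size + 1


def _scope_records(log: SessionLog, scope: slice | None):
    recs = log.records if scope is None else log.records[scope]
    return recs


def pct_correct(log: SessionLog, scope: slice | None = None) -> float:
    """Percentage of trials in scope choosing the better stimulus."""
    recs = _scope_records(log, scope)
    if not recs:
        raise ValueError("empty scope")
    return 100.0 * sum(r.is_correct for r in recs) / len(recs)


def pct_volatility(log: SessionLog, scope: slice | None = None) -> float:
    """Percentage of within-scope transitions where the choice switched.

    Returns NaN (missing) for scopes with fewer than 2 trials.
    """
    recs = _scope_records(log, scope)
    if len(recs) < 2:
        return float("nan")
    switches = sum(recs[t + 1].choice != recs[t].choice for t in range(len(recs) - 1))
    return 100.0 * switches / (len(recs) - 1)


def pct_switch_after(
    log: SessionLog, outcome_filter: str, scope: slice | None = None
) -> float:
    """Percentage of win (or loss) trials followed by a switch on the next trial.

    Only trials whose successor is inside the scope count; with no
    qualifying trials the value is missing (NaN), never 0.
    """
    if outcome_filter not in ("win", "lose"):
        raise ValueError(f"outcome_filter must be 'win' or 'lose', got {outcome_filter!r}")
    target = 1 if outcome_filter == "win" else -1
    recs = _scope_records(log, scope)
    num = den = 0
    for t in range(len(recs) - 1):
        if recs[t].outcome == target:
            den += 1
            if recs[t + 1].choice != recs[t].choice:
                num += 1
    return float("nan") if den == 0 else 100.0 * num / den


def rt_summary(log: SessionLog, scope: slice | None = None) -> tuple[float, float]:
    """(median, MAD) of reaction times in ms.

    The MAD is the raw median absolute deviation from the median, without
    the 1.4826 normal-consistency factor.
    """
    recs = _scope_records(log, scope)
    if not recs:
        raise ValueError("empty scope")
    rts = np.array([r.rt_ms for r in recs])
    med = float(np.median(rts))
    mad = float(np.median(np.abs(rts - med)))
    return med, mad


def qc_exclude(log: SessionLog) -> tuple[bool, str]:
    """Flag sessions with > 90% of choices on one stimulus (strictly).

    Such participants never meaningfully explored both options, so their
    learning parameters are unidentifiable.
    """
    if len(log) == 0:
        raise ValueError("empty session")
    n = len(log)
    n_a = sum(1 for c in log.choices if c is Stimulus.A)
    frac = max(n_a, n - n_a) / n
    if frac > QC_THRESHOLD:
        dominant = "A" if n_a >= n - n_a else "B"
        return True, f"{100 * frac:.2f}% choices of stimulus {dominant} (> 90%)"
    return False, ""


def sqrt_transform(values) -> np.ndarray:
    """Square root on the proportion scale (percentages are divided by 100).

    Order-preserving; negative input is a hard error.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("sqrt_transform requires non-negative input")
    return np.sqrt(arr / 100.0)


def session_summary(
    log: SessionLog,
    block_size: int = DEFAULT_BLOCK_SIZE,
    cross_block: bool = False,
) -> list[BehaviorSummary]:
    """All metrics for one session: one whole-session row (block 0) plus one
    row per block."""
    excluded, reason = qc_exclude(log)
    rows = []

    def build(block: int, scope: slice | None) -> BehaviorSummary:
        med, mad = rt_summary(log, scope)
        recs = _scope_records(log, scope)
        if cross_block and scope is not None and scope.start and scope.start > 0:
            # widen by one trial so the block's first transition is counted
            wide = slice(scope.start - 1, scope.stop)
            vol = pct_volatility(log, wide)
            sw = pct_switch_after(log, "win", wide)
            sl = pct_switch_after(log, "lose", wide)
        else:
            vol = pct_volatility(log, scope)
            sw = pct_switch_after(log, "win", scope)
            sl = pct_switch_after(log, "lose", scope)
        return BehaviorSummary(
            participant_id=log.participant_id,
            group=log.group.value,
            condition=log.condition.value,
            block=block,
            n_trials=len(recs),
            pct_correct=pct_correct(log, scope),
            pct_volatility=vol,
            pct_switch_win=sw,
            pct_switch_lose=sl,
            rt_median_ms=med,
            rt_mad_ms=mad,
            excluded=excluded,
            exclusion_reason=reason,
        )

    rows.append(build(0, None))
    blocks = assign_blocks(log, block_size)
    for b in range(1, int(blocks.max()) + 1):
        idx = np.flatnonzero(blocks == b)
        rows.append(build(b, slice(int(idx[0]), int(idx[-1]) + 1)))
    return rows


def summarize_sessions(
    logs: list[SessionLog],
    block_size: int = DEFAULT_BLOCK_SIZE,
    cross_block: bool = False,
) -> pd.DataFrame:
    """Tidy table of BehaviorSummary rows for many sessions."""
    rows = []
    for log in logs:
        rows.extend(session_summary(log, block_size=block_size, cross_block=cross_block))
    return pd.DataFrame([r.__dict__ for r in rows])
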