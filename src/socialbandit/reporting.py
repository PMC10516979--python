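"""Pipeline assembly: QC → behavior metrics → fitting → group statistics.

Turns a set of session logs (plus optional ratings) into the tidy result
tables and a markdown report with the standard figures of this design:
blocked %correct learning curves by group × condition, and %correct / β
crossbar-style group × condition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_metrics, fitting, group_stats
from .task_engine import SessionLog

__all__ = ["AnalysisResult", "analyze_sessions", "write_report"]


@dataclass
class AnalysisResult:
    behavior: pd.DataFrame  # per session x block metric rows
    fits: pd.DataFrame  # per session x model fit rows
    contrasts: dict[str, pd.DataFrame]  # metric -> within-group condition contrast
    ratings_tests: pd.DataFrame | None
    exclusions: pd.DataFrame
    n_sessions: int
    seed: int


def analyze_sessions(
    logs: list[SessionLog],
    ratings: pd.DataFrame | None = None,
    seed: int = 0,
    n_starts: int = 10,
    n_boot: int = 10_000,
) -> AnalysisResult:
    """Run the full analysis pipeline on session logs.

    QC-excluded sessions (> 90% one-stimulus choices) are dropped from
    fitting and statistics but listed in the exclusions table.
    """
    rng = np.random.default_rng(seed)
    excl_rows = []
    kept = []
    for log in logs:
        excluded, reason = behavior_metrics.qc_exclude(log)
        if excluded:
            excl_rows.append(
                {
                    "participant_id": log.participant_id,
                    "group": log.group.value,
                    "condition": log.condition.value,
                    "reason": reason,
                }
            )
        else:
            kept.append(log)
    exclusions = pd.DataFrame(excl_rows, columns=["participant_id", "group", "condition", "reason"])

    behavior = behavior_metrics.summarize_sessions(kept)
    fits = fitting.fit_sessions(kept, n_starts=n_starts, rng=rng)

    contrasts: dict[str, pd.DataFrame] = {}
    rw = fits[fits["model"] == "rw_single_update"]
    for metric, table in (
        ("beta", rw.rename(columns={"participant_id": "participant", "beta": "value"})),
        ("alpha", rw.rename(columns={"participant_id": "participant", "alpha": "value"})),
    ):
        contrasts[metric] = group_stats.condition_contrast(
            table[["participant", "group", "condition", "value"]],
            n_boot=n_boot,
            rng=np.random.default_rng(seed + 1),
        )
    session_rows = behavior[behavior["block"] == 0]
    pct = session_rows.rename(
        columns={"participant_id": "participant", "pct_correct": "value"}
    )[["participant", "group", "condition", "value"]]
    contrasts["pct_correct"] = group_stats.condition_contrast(
        pct, n_boot=n_boot, rng=np.random.default_rng(seed + 2)
    )

    ratings_tests = None
    if ratings is not None and len(ratings):
        ratings_tests = group_stats.ratings_vs_neutral(ratings)

    return AnalysisResult(
        behavior=behavior,
        fits=fits,
        contrasts=contrasts,
        ratings_tests=ratings_tests,
        exclusions=exclusions,
        n_sessions=len(kept),
        seed=seed,
    )


def _fmt(df: pd.DataFrame) -> str:
    return df.round(4).to_markdown(index=False) if hasattr(df, "to_markdown") else str(df)


def write_report(result: AnalysisResult, outdir, figures: bool = True) -> Path:
    """Write CSV tables, a markdown report, and (optionally) figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.behavior.to_csv(outdir / "behavior.csv", index=False)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    for name, df in result.contrasts.items():
        df.to_csv(outdir / f"contrast_{name}.csv", index=False)
    if result.ratings_tests is not None:
        result.ratings_tests.to_csv(outdir / "ratings_tests.csv", index=False)

    rw = result.fits[result.fits["model"] == "rw_single_update"]
    param_tbl = (
        rw.groupby(["group", "condition"])[["alpha", "beta"]]
        .median()
        .reset_index()
        .rename(columns={"alpha": "alpha_median", "beta": "beta_median"})
    )
    session_rows = result.behavior[result.behavior["block"] == 0]
    beh_tbl = (
        session_rows.groupby(["group", "condition"])[
            ["pct_correct", "pct_volatility", "pct_switch_win", "pct_switch_lose"]
        ]
        .mean()
        .reset_index()
    )

    lines = [
        "# Bandit-task analysis report",
        "",
        f"Sessions analyzed: {result.n_sessions} "
        f"(excluded: {len(result.exclusions)}); seed: {result.seed}",
        "",
        "## QC exclusions",
        "",
        _fmt(result.exclusions) if len(result.exclusions) else "None.",
        "",
        "## Choice behavior (session means by group × condition)",
        "",
        _fmt(beh_tbl),
        "",
        "## Fitted learning parameters (medians by group × condition)",
        "",
        _fmt(param_tbl),
        "",
        "## Within-group condition contrasts (nonsocial − social, Bonferroni ×2)",
        "",
    ]
    for name, df in result.contrasts.items():
        lines += [f"### {name}", "", _fmt(df), ""]
    if result.ratings_tests is not None:
        lines += ["## Affective ratings vs the neutral anchor (4)", "", _fmt(result.ratings_tests), ""]

    if figures:
        fig_paths = _write_figures(result, outdir)
        lines += ["## Figures", ""] + [f"![{p.stem}]({p.name})" for p in fig_paths] + [""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def _write_figures(result: AnalysisResult, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    blocks = result.behavior[result.behavior["block"] > 0]

    fig, ax = plt.subplots(figsize=(6, 4))
    for (grp, cond), sub in blocks.groupby(["group", "condition"]):
        curve = sub.groupby("block")["pct_correct"].mean()
        ax.plot(curve.index, curve.values, marker="o", label=f"{grp} / {cond}")
    ax.axhline(50, ls="--", c="gray", lw=1)
    ax.set_xlabel("block (15 trials)")
    ax.set_ylabel("% correct")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "pct_correct_blocks.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    rw = result.fits[result.fits["model"] == "rw_single_update"]
    for col, fname in (("beta", "beta_by_group_condition.png"), ("alpha", "alpha_by_group_condition.png")):
        fig, ax = plt.subplots(figsize=(5, 4))
        cells = list(rw.groupby(["group", "condition"])[col])
        ax.boxplot([vals.values for _, vals in cells], tick_labels=[f"{g}\n{c}" for (g, c), _ in cells])
        ax.set_ylabel(col)
        fig.tight_layout()
        p = outdir / fname
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
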