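"""Group- and condition-level statistics.

The package's own inferential surface consists of the simple tests reported
alongside the mixed models: one-sample t-tests of 1–7 affective ratings
against the neutral anchor 4, paired Wilcoxon signed-rank tests (used for
learning rates, whose distribution resists normalization), and within-group
paired condition contrasts with bootstrap CIs and Bonferroni correction.

The Wilcoxon test reports V = sum of the ranks of positive differences.
Zero differences are dropped, tied absolute differences get average ranks,
and the two-sided p-value comes from full enumeration of the 2^n sign
assignments for n ≤ 12 and from a normal approximation with continuity and
tie correction for larger n.

Full linear mixed-effects modelling (condition × block × order × group with
covariates) is a standard procedure, not this package's contribution; it is
delegated to statsmodels through :func:`mixed_model_hook` and labelled as
such.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "one_sample_t",
    "wilcoxon_paired",
    "condition_contrast",
    "mixed_model_hook",
    "ratings_vs_neutral",
    "RATING_ITEMS",
    "NEUTRAL_ANCHOR",
]

RATING_ITEMS = [
    "win_social",
    "win_nonsocial",
    "lose_social",
    "lose_nonsocial",
    "feedback_social",
    "feedback_nonsocial",
]
NEUTRAL_ANCHOR = 4.0
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df_or_n: float
    p: float
    effect_size: float = float("nan")
    note: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")


def one_sample_t(ratings, mu0: float = NEUTRAL_ANCHOR) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    t = (mean − mu0) / (sd / √n) with the n−1 df Student distribution;
    the effect size is Cohen's d = (mean − mu0) / sd. Zero-variance input
    yields an error result (p = NaN) with an explanatory note.
    """
    x = np.asarray(ratings, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0.0:
        # degenerate limits: no variation means no evidence against the null
        # when the mean sits on mu0, and overwhelming evidence when it doesn't
        same = mean == mu0
        return TestResult(
            test="one_sample_t",
            statistic=0.0 if same else float("inf") * float(np.sign(mean - mu0)),
            df_or_n=n - 1,
            p=1.0 if same else 0.0,
            note="zero variance: t-test degenerate",
        )
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    d = (mean - mu0) / sd
    return TestResult(test="one_sample_t", statistic=float(t), df_or_n=n - 1, p=float(p), effect_size=float(d))


def _signed_rank_exact_p(ranks: np.ndarray, v_obs: float) -> float:
    """Two-sided p by enumerating all sign assignments of the given ranks."""
    n = len(ranks)
    total = ranks.sum()
    vs = np.empty(2**n)
    for i, signs in enumerate(itertools.product((0.0, 1.0), repeat=n)):
        vs[i] = float(np.dot(signs, ranks))
    p_le = np.mean(vs <= v_obs + 1e-12)
    p_ge = np.mean(vs >= v_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(x, y) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test of x vs y.

    The statistic is V, the sum of ranks of positive differences d = x − y.
    Effect size is the matched-pairs rank-biserial correlation,
    r = 2V / (n(n+1)/2) − 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples must have equal length, got {x.shape} vs {y.shape}")
    d = x - y
    d = d[d != 0.0]  # drop zero differences (common convention)
    n = d.size
    if n == 0:
        return TestResult(
            test="wilcoxon_paired",
            statistic=float("nan"),
            df_or_n=0,
            p=float("nan"),
            note="all differences zero: test undefined",
        )
    ranks = stats.rankdata(np.abs(d))  # average ranks for ties
    v = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(ranks, v)
    else:
        mu = total / 2.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction on the rank variance
        _, counts = np.unique(np.abs(d), return_counts=True)
        sigma2 -= np.sum(counts**3 - counts) / 48.0
        sigma = np.sqrt(sigma2)
        # continuity correction toward the mean
        z = (v - mu - 0.5 * np.sign(v - mu)) / sigma if sigma > 0 else 0.0
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    r_rb = 2.0 * v / total - 1.0
    return TestResult(test="wilcoxon_paired", statistic=v, df_or_n=n, p=p, effect_size=float(r_rb))


def condition_contrast(
    per_participant: pd.DataFrame,
    value_col: str = "value",
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Within-group paired condition contrasts (nonsocial − social).

    ``per_participant`` is long-format with columns participant, group,
    condition, and the value column; each participant contributes at most
    one value per condition. Participants with only one condition are
    dropped (their count is logged). Per group the output reports the paired
    mean difference, a seeded percentile bootstrap CI, paired t and Wilcoxon
    tests, and Bonferroni-corrected p-values across the two groups.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    required = {"participant", "group", "condition", value_col}
    missing = required - set(per_participant.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = per_participant.groupby(["participant", "condition"]).size()
    if (dup > 1).any():
        raise ValueError("each participant may contribute at most one value per condition")

    rows = []
    for grp, sub in per_participant.groupby("group", sort=True):
        wide = sub.pivot(index="participant", columns="condition", values=value_col)
        if not {"social", "nonsocial"} <= set(wide.columns):
            wide = wide.reindex(columns=["social", "nonsocial"])
        complete = wide.dropna(subset=["social", "nonsocial"])
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            warnings.warn(
                f"group {grp}: dropped {n_dropped} participant(s) with one condition only",
                UserWarning,
            )
        diffs = (complete["nonsocial"] - complete["social"]).to_numpy(dtype=float)
        n = diffs.size
        if n == 0:
            continue
        boot_means = np.array(
            [np.mean(rng.choice(diffs, size=n, replace=True)) for _ in range(n_boot)]
        )
        ci_lo, ci_hi = np.percentile(boot_means, [2.5, 97.5])
        t_res = (
            one_sample_t(diffs, mu0=0.0)
            if n >= 2
            else TestResult("one_sample_t", float("nan"), n, float("nan"))
        )
        w_res = wilcoxon_paired(
            complete["nonsocial"].to_numpy(), complete["social"].to_numpy()
        )
        rows.append(
            {
                "group": grp,
                "n": n,
                "n_dropped": n_dropped,
                "mean_diff": float(np.mean(diffs)),
                "ci_low": float(ci_lo),
                "ci_high": float(ci_hi),
                "t_stat": t_res.statistic,
                "t_p": t_res.p,
                "wilcoxon_V": w_res.statistic,
                "wilcoxon_p": w_res.p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(out)  # Bonferroni across the groups tested
    out["t_p_bonf"] = np.minimum(1.0, out["t_p"] * m)
    out["wilcoxon_p_bonf"] = np.minimum(1.0, out["wilcoxon_p"] * m)
    return out


def ratings_vs_neutral(ratings: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-tests of each group × item rating against the neutral 4.

    ``ratings`` is long-format with columns participant_id, group, item,
    rating (integers 1–7). Uncorrected two-sided tests, per the convention
    for these preliminary affect checks.
    """
    rows = []
    for (grp, item), sub in ratings.groupby(["group", "item"], sort=True):
        res = one_sample_t(sub["rating"].to_numpy(), mu0=NEUTRAL_ANCHOR)
        rows.append(
            {
                "group": grp,
                "item": item,
                "n": len(sub),
                "mean": float(sub["rating"].mean()),
                "t": res.statistic,
                "df": res.df_or_n,
                "p": res.p,
                "cohens_d": res.effect_size,
            }
        )
    return pd.DataFrame(rows)


def mixed_model_hook(
    table: pd.DataFrame,
    formula: str,
    group_col: str = "participant",
) -> dict:
    """Delegate a linear mixed model (random intercept per participant).

    Passes the long-format table and formula to statsmodels' MixedLM. The
    returned summary is labelled ``delegated``: the inference is the
    library's, not this package's. If the routine is unavailable or fails
    to converge the hook degrades gracefully to the paired condition
    contrast with a warning.
    """
    if "~" not in formula:
        raise ValueError(f"malformed formula {formula!r}")
    try:
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=table, groups=table[group_col])
            fit = model.fit()
        return {
            "delegated": True,
            "engine": "statsmodels.MixedLM",
            "formula": formula,
            "params": fit.params.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "converged": bool(fit.converged),
        }
    except Exception as err:  # pragma: no cover - environment-dependent path
        warnings.warn(
            f"mixed-model routine unavailable ({err}); falling back to paired contrasts",
            UserWarning,
        )
        value_col = formula.split("~")[0].strip()
        fallback = condition_contrast(
            table.rename(columns={group_col: "participant"}), value_col=value_col
        )
        return {"delegated": False, "fallback": "condition_contrast", "result": fallback}
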