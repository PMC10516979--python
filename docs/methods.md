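# Methods

## Task model

The environment is a static two-armed bandit: stimulus A pays +1 with
probability 2/3 (−1 otherwise), stimulus B with probability 1/3, for 75
trials per session. Outcomes are drawn on-line per trial conditional on
the actual choice; this is distributionally equivalent to pre-generating
a reward sequence per arm and requires no bookkeeping. Stimulus identity
is abstracted to {A = better, B = worse}; left/right position and colour
counterbalancing are metadata only and never enter any computation.

All randomness descends from a single master seed through numpy
`SeedSequence` spawn keys `(participant_counter, stream_index)` — one
stream per session, one for each participant's parameter draw, one for
ratings — so cohorts are bit-reproducible and sessions are statistically
independent.

## Learning model and likelihood

The single-update Rescorla–Wagner rule with SoftMax choice (see README
for the equations). Implementation choices:

* **Rewards are coded ±1**, and a 0/1-coded outcome raises a hard error:
  the two codings give different value dynamics and silently accepting
  the wrong one is the classic bug in this model class.
* **Both values start at 0**, so the first trial always contributes
  ln 2 to the negative log-likelihood. The first trial is *included* in
  the likelihood; this keeps NLL comparable across models (the random
  control also pays ln 2 per trial).
* **Numerics.** The per-trial choice probability is computed as a
  logistic of β·(V(c) − V(nc)), stable in both tails; probabilities are
  floored at 1e−300 before the log (with the stable form this never
  binds for β ≤ 20). With ±1 rewards and α ∈ [0, 1], values are confined
  to [−1, 1], so β·ΔV ≤ 2β.
* **β is capped at 20** during fitting: at |ΔV| ≤ 2 the SoftMax is
  already effectively deterministic well below that, so larger values
  are behaviourally indistinguishable and only destabilize the
  optimizer. The cap is configurable.

## Fitting

Per-session (participant × condition) maximum likelihood with
L-BFGS-B under bounds α ∈ [0, 1], β ∈ [0, 20], multi-start. The (α, β)
likelihood surface has a known ridge — high α with low β mimics low α
with high β on short sessions — and, on noisy data, a separate shallow
optimum near the low-β boundary. The start list is therefore: the
centre (0.5, 1.0), three fixed covering points (0.9, 0.3), (0.1, 0.3),
(0.5, 5.0), then uniform random draws up to `n_starts` (default 10),
all seeded. The best local optimum wins; if no start reports
convergence, the best incumbent is returned with `converged=False` and
a warning.

Model comparison uses AIC = 2k + 2·NLL with k = 2 (learner), 1 (side
bias), 0 (random). Ties are broken by fewer parameters, then model
name, making rankings deterministic. AICc/BIC are deliberately not
offered; with n = 75 and k ≤ 2 the small-sample correction is
negligible and a single criterion keeps comparisons unambiguous.

An optional dual-update variant (unchosen value decays toward 0) exists
as a model slot but is excluded from default comparisons; it is a
generic alternative, not a calibrated competitor.

**Recovery.** `parameter_recovery` simulates agents with known (α, β)
drawn from α ~ U(0.1, 0.9), β ~ U(0.5, 5), refits each session, and
reports Spearman rank correlations, bias and RMSE per parameter. At the
study's 75 trials the design is identifiable: rank correlations around
0.6 (α) and 0.8 (β) at n = 100 agents; RMSE shrinks with longer
sessions, as the consistency test asserts. `model_recovery` builds the
generating-model × best-AIC confusion matrix; a β = 0 learner is
correctly absorbed by the random model via the parameter penalty.

## Behavior metrics

Percentages are computed per session and per block of 15 trials (5
blocks). Switch metrics condition on the *previous* trial's outcome:
%switch-win (lose) is the share of win (loss) trials whose successor
shows a different choice. Their denominators partition the n − 1
transitions, so %volatility equals their denominator-weighted average —
an internal consistency identity the tests assert. Scopes with no
qualifying trials yield missing values, never 0. Block-scope switch
metrics use only within-block transitions by default (blocks stay
independent analysis units); `cross_block=True` counts the transition
into each block against the previous block's last trial.

RT dispersion is the **raw** median absolute deviation (no 1.4826
consistency factor): the quantity of interest is dispersion itself, not
a normal-σ estimate.

QC: a session is excluded iff one stimulus was chosen on strictly more
than 90% of trials (at 75 trials: 68 identical choices exclude, 67 do
not) — such participants never explored both options, leaving α and β
unidentifiable. An "inattention" exclusion beyond this rule is not
operationalized here.

The square-root transform used before parametric statistics is applied
on the proportion (0–1) scale. The scale choice does not affect any
monotone inference; it is fixed for reproducibility.

## Group statistics

* **One-sample t** against the neutral rating anchor 4, two-sided, with
  Cohen's d. Zero-variance input degenerates to p = 1 (mean on the
  anchor) or p = 0 (off it), flagged with a note rather than crashing
  batch analyses.
* **Paired Wilcoxon signed-rank**, V = sum of ranks of positive
  differences of x − y. Zero differences are dropped; tied absolute
  differences receive average ranks. The two-sided p comes from full
  enumeration of the 2^n sign assignments for n ≤ 12 and from the
  normal approximation with continuity and tie corrections above. The
  implementation is independent of scipy's and is cross-checked against
  it in the tests.
* **Condition contrasts**: within each group, the paired nonsocial −
  social difference with a seeded 10,000-resample percentile bootstrap
  CI, paired t and Wilcoxon, Bonferroni-corrected across the groups
  tested. Participants with only one condition are dropped with a
  logged count.
* **Mixed models** (condition × block × order × group with covariates)
  are a standard procedure delegated to statsmodels' MixedLM behind
  `mixed_model_hook`; the output is labelled `delegated` and degrades
  to the paired contrasts if the routine is unavailable.

## Synthetic cohort

The generator emulates the study design: 35 patient-like and 37
control-like participants, two 75-trial conditions each in exactly
alternating SN/NS order within group.

Defaults (chosen once, as a realistic regime for this task class):

| knob | default | rationale |
|---|---|---|
| α range | U(0.3, 0.9), both groups | brackets typical fitted medians (~0.6–0.75) for this task length |
| β range | U(1.0, 5.0), both groups | engaged but stochastic choice; matches the √β scale of typical fits |
| β social multiplier | control 0.6, patient 1.0 | the design's hypothesized effect: social feedback shifts controls toward exploration; no effect in patients |
| RT model | lognormal, log-loc 6.8 (≈ 0.9 s), −0.04/block, +0.15 social; sdlog 0.35/0.45 | responses speed up across blocks and are slower and more variable under social feedback |
| ratings | clipped discretized normal, sd 1.2, group × item means with wins/win-feedback > 4, losses < 4 | the qualitative affect pattern of such designs |

The condition effect lives on β only; α is condition-invariant by
default, mirroring a shift in the exploration–exploitation balance
rather than in the update rate. `generate_null_cohort` switches every
group/condition effect off (shared ranges, multipliers 1, symmetric
RTs and ratings) for type-I-error calibration. A dropout knob can
remove the second condition for a configurable number of participants
to exercise the contrast-dropping path; it is off by default.

**What the generator does not emulate:** within-session parameter
drift, attention lapses, order-dependent carryover beyond the
counterbalancing, RT–choice coupling (RTs are independent of choice
difficulty), and item-level rating correlations. Passing tests
therefore validate the *machinery* — likelihoods, estimators,
statistics, pipeline plumbing — under the model's own assumptions, not
the truth of those assumptions for human data.

## Problem sizes

The validation studies use sizes that make their Monte-Carlo error
small relative to the asserted margins while keeping the full suite
fast: 10,000 outcome draws for reward-probability calibration, 500
sessions for chance-level behavior, 100 agents for parameter recovery,
200 sessions for model comparison, one full-size cohort (72
participants × 2 conditions) for the end-to-end contrast, and 2,000
replicates for test calibration.

## Known limitations

* Per-session ML estimates at 75 trials are noisy (RMSE ≈ 0.19 for α,
  ≈ 1.3 for β at the default prior); no hierarchical shrinkage is
  applied, by design.
* The %correct consequence of the β condition effect is small (~5
  percentage points at the default effect size), so the paired
  %correct contrast has limited power at n ≈ 35 per group; the β
  contrast is the sensitive readout, and the end-to-end test asserts
  %correct directionally.
* The side-bias model guards the random-model comparison but is not a
  serious psychological model.
* Exact Wilcoxon enumeration is O(2^n) and capped at n = 12; beyond
  that the corrected normal approximation is used.
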