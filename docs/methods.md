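# Methods

This note documents the generative model, the analysis procedures, the
defaults, and the design decisions taken where the literature leaves the
details open. Notation follows the package API (`TaskConfig`,
`AgentParams(alpha, beta, rho, omega, lam)`).

## Task engine

One valence of the task is a 201-trial, three-session two-step paradigm:
a binary first-stage choice leads with probability `p_common = 0.7` to
its linked second-stage state (identity mapping, fixed across trials and
subjects), otherwise to the other state; each of the four second-stage
stimuli pays `outcome_magnitude` (+1 reward valence, −1 punishment) with
a probability that drifts inside [0.25, 0.75]. The two valences share
every structural parameter and differ only in the outcome magnitude and
the valence label; stimulus identity, colour sets and screen-side
randomisation are not modelled.

Unstated details were fixed as follows:

* **Walk step.** Each outcome probability takes an independent Gaussian
  step per trial with `walk_sd = 0.025`, the conventional value for this
  task lineage. At ~0.025/trial the walk traverses the permitted range a
  few times over 201 trials — slow enough to reward learning, fast
  enough that continued learning pays.
* **Boundary handling.** Steps are *reflected* at 0.25/0.75 (triangular
  fold, exact for any overshoot) rather than truncated, so the walk's
  stationary distribution is not inflated at the bounds.
* **Initial probabilities** are drawn uniformly inside the bounds,
  seeded.
* **Sessions** are contiguous near-equal blocks (67/67/67 by default);
  outcome walks continue across session boundaries.
* **Schedules per subject.** Whether outcome walks were frozen across
  subjects in the original design is unknowable from the text; both
  modes exist (`shared_schedules`), with per-subject regeneration the
  default since it makes subjects statistically independent.

## Hybrid agent

State–action values start at zero. After each completed trial the
model-free (SARSA) updates are

```
δ₁ = Q₂(s₂,c₂) − Q₁(c₁);  Q₁(c₁) += α δ₁
δ₂ = r − Q₂(s₂,c₂);       Q₂(s₂,c₂) += α δ₂;  Q₁(c₁) += α λ δ₂
```

and the model-based first-stage values recompute
`Q_MB(a) = 0.7·max_c Q₂(linked(a),c) + 0.3·max_c Q₂(other(a),c)` from the
*true* transition probabilities (subjects are instructed on the task
structure, so no transition learning is modelled). First-stage choice is
softmax in `β·[ω·Q_MB + (1−ω)·Q_MF] + ρ·1[repeat]`; second-stage choice
is softmax in `β·Q₂(s₂,·)` with no perseveration term.

Conventions forced by the four-free-parameter family (α, β, ρ, ω):

* **λ is a fixed constant, 1.0** — the first-stage value directly
  credits the final outcome. It is configurable but never fitted.
* **One β shared across stages.**
* **ρ** is an additive softmax bonus on the previous first-stage choice;
  on trial 1 and after an omission the reference resets and the bonus is
  zero.

The exact formulation of the original supplementary model (eligibility
handling, stage-2 perseveration) is not public; these choices follow the
standard conventions of the task lineage and are what the likelihood,
the simulator, the tests and the documentation all consistently use.
The simulator records the log-probability of every emitted choice, and a
test asserts the likelihood module reproduces those terms to 1e−10 —
simulator and likelihood cannot drift apart.

## Synthetic study scenario

The generator emulates a 22 + 22 two-group design, both valences per
subject, 201 trials each. Per-subject parameters are drawn per valence
from truncated normals (α, ω on [0, 1]; β on [0, ∞); ρ untruncated) and
clipped to their domains. Defaults:

| group | valence | α | β | ρ | ω |
|---|---|---|---|---|---|
| BAL | both | 0.45 ± 0.15 | 5.0 ± 1.5 | 0.15 ± 0.3 | 0.50 ± 0.12 |
| TD | reward | 0.45 ± 0.15 | 5.0 ± 1.5 | 0.15 ± 0.3 | 0.05 ± 0.05 |
| TD | punishment | 0.45 ± 0.15 | 5.0 ± 1.5 | 0.15 ± 0.3 | 0.95 ± 0.05 |

Rationale: the control group expresses an even mixture of strategies (ω
near 0.5), the standard finding for healthy volunteers on this task. The
depleted group's choice behaviour is, at this sample size, statistically
indistinguishable from the pure strategies — purely model-free under
reward, purely model-based under punishment — so its ω sits near the
corresponding pole with low heterogeneity. The power argument: a
residual strategy weight w leaves a stay-probability contrast of roughly
w times the pure-strategy contrast, while the per-subject noise floor
(≈100 trial pairs per cell) is fixed; at n = 22 a residual weight below
≈0.1 is usually undetectable at α = 0.05, and the near-pole means place
the *expected* residual weight in that region. Because the residual
model-free trace under punishment is small but not zero, a minority of
replicate studies still classify the TD punishment condition as "mixed"
— the replication test therefore asserts the full four-cell pattern in a
majority, not all, of 20 seeded replicates. Remaining means/SDs are
typical hybrid-fit magnitudes for this task family.

Simulated data contain no omissions (the format and every analysis
support them; there is simply no mechanism generating them), no reaction
times, and no session effects: passing tests show the pipeline's
statistical machinery is correct and well-powered under the modelled
heterogeneity, not that real subjects satisfy the hybrid model, nor
anything about attrition, fatigue or timing phenomena.

## Factorial analysis

Stay probability per subject is tabulated over consecutive non-omitted
trial pairs, classified by the earlier trial's transition and outcome
category. The **better/worse** outcome coding unifies valences (reward
and avoided loss are "better"), which lets one fully crossed design
carry the four-way valence × outcome × transition × group ANOVA.
Subjects with an empty cell are excluded listwise (logged); the arcsine
transform `arcsin(√p)` is applied to all stay probabilities before ANOVA
(uniform application, rather than gating each variable on a normality
test, keeps the pipeline deterministic; `normality_screen` is available
to report Shapiro–Wilk alongside).

The mixed-design ANOVA handles one optional between factor and any
number of **two-level** within factors. Every within effect has one
numerator degree of freedom, so each reduces exactly to a per-subject
contrast score; effects are tested by one-way ANOVA machinery on those
scores, reproducing the classical subject-nested error strata (within
effects on F(1, N−a); group effects on F(a−1, N−a)). Sphericity is
automatic with two-level factors; no corrections are implemented, and
factors with more than two levels are rejected rather than approximated.
Degenerate inputs: if an error stratum has zero variance the effect is
reported as F = 0 (p = 1) when it also has zero effect variance,
otherwise F = ∞ (p = 0). Correctness is pinned by three independent
references in the test suite: a textbook sums-of-squares oracle (exact
to 1e−10), a subject-label permutation test, and pingouin.

Signature classification at `alpha_level = 0.05`: *model_free* if only
the outcome main effect is significant, *model_based* if only the
outcome × transition interaction, *mixed* if both, *neither* otherwise.

## Fitting, model selection, group comparison

Per-subject maximum likelihood over both stage choices of every
non-omitted trial (`n_obs = 2 × trials`). Optimisation runs L-BFGS-B in
an unconstrained space — logit for α and ω, log for β, identity for ρ —
from 20 seeded uniform restarts (box: α, ω ∈ [0.01, 0.99]; β ∈ [0.1,
20]; ρ ∈ [−2, 2] on the natural scale). β is capped at 20 because beyond
that the likelihood plateaus for 201-trial data. Standard errors come
from a finite-difference Hessian at the optimum and are reported as NaN
when it is singular or the estimate sits on a bound.

**Log-evidence** is the BIC surrogate `−nll − (k/2)·ln n_obs`; the
original selection method is unspecified, and BIC is the standard choice
in this literature (an AIC is also exposed on the results object).
**Random-effects model selection** estimates a Dirichlet posterior over
population model frequencies by the usual variational scheme
(responsibilities ∝ exp(log-evidence + digamma terms), α updated to
prior + summed responsibilities; uniform prior α₀ = 1), with exceedance
probabilities from 10⁶ seeded Dirichlet draws. **Group comparison** of
fitted parameters applies a square-root transform to parameters flagged
non-normal by Shapiro–Wilk in either group (`sign(x)·√|x|` for the
unbounded ρ), then a one-way MANOVA (Wilks' Λ via statsmodels) plus
univariate one-way F per parameter; a singular covariance falls back to
univariate-only, flagged.

Hierarchical/empirical-Bayes estimation across subjects is deliberately
out of scope: parameters are fitted per subject.

## Validation harnesses and problem sizes

* **Signature recovery**: cohorts of 200 pure agents (ω = 0 and ω = 1)
  must show only the outcome main effect and only the interaction,
  respectively.
* **Parameter recovery**: 100 subjects, truths uniform over α ∈ [0.05,
  0.95], β ∈ [1, 10], ρ ∈ [−0.5, 1], ω ∈ [0.05, 0.95], two valences
  fitted jointly (804 decisions); fitted ω must correlate ≥ 0.7 with
  truth with |bias| ≤ 0.1 (observed correlations are substantially
  higher).
* **Model recovery**: 20-subject cohorts generated under each family at
  identifiable settings (decisive β; for the hybrid cohort ω ∈ [0.4,
  0.8], ρ ∈ [0.1, 0.6]) with both valences per subject — the study's
  per-subject data volume — so the BIC penalty does not mask the two
  extra parameters; the generating family must win with exceedance
  > 0.95.
* **Qualitative replication**: 20 replicate 22 + 22 studies under the
  default scenario; the majority must classify TD as model-free under
  reward and model-based under punishment with BAL mixed in both.

These sizes were chosen as the smallest at which each property is
comfortably identified.

## Known limitations

* The ANOVA is restricted to two-level within factors (exact there); no
  Greenhouse–Geisser machinery.
* BIC log-evidence penalises dimensionality more bluntly than a full
  Laplace approximation; with ~800 decisions per subject the ranking is
  insensitive to this, but a Laplace hook would sharpen small-data use.
* The agent family assumes stationary parameters within a session block
  and no transition learning; real subjects may do both.
* Omission flags are honoured throughout but never generated; analyses
  of omission counts and reaction times are out of scope.
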