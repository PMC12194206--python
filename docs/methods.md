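# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the known limits of what the package's validation
demonstrates.

## Model and likelihood

The decision model is a Wiener diffusion with constant drift `v`, unit
noise, absorbing boundaries at 0 ("left") and `a` ("right"), and starting
point `z = w·a`. RT decomposes as `RT = DT + Ter`. Condition codes enter
linearly: side `S ∈ {−1,+1}`, orientation `O ∈ {0,1}` and, in
labels-present arms, label validity `L ∈ {0,1}` modulate the drift
(`v = v_base + v_s·S + v_so·S·O [+ v_sl·S·L + v_sol·S·O·L]`), and labels
may shift the non-decision time (`Ter = T0 + Tl·L`). `a` and `w` are
constant within participant — both are set before the stimulus appears,
and observers cannot condition them on covariates they have not yet seen.
The control variant has 6 free parameters, the labels variant 9. The
model is identified only up to the noise scale, so `s = 1` throughout and
drift rates read as signal-to-noise ratios.

The per-trial likelihood is the WFPT density at the boundary matching the
choice (upper = right), evaluated at `t = RT − Ter`. The density is
computed from the zero-drift unit-boundary density `f₀(τ, w)`
(`τ = t/a²`) via

    f_lower(t | v, a, w) = (1/a²)·exp(−v·a·w − v²t/2)·f₀(t/a², w),

with the upper boundary by reflection (`w → 1−w`, `v → −v`). `f₀` has
two complementary expansions — a small-time image sum and a large-time
eigenfunction series — and each call uses whichever needs fewer terms for
an absolute tolerance `err = 1e-7` (the standard per-call truncation
bounds). The test suite verifies that the two branches agree to ~1e-11
and that lower+upper densities integrate to 1 to ~1e-12 across a grid of
`v ∈ [−2, 2]`, `a ∈ [0.5, 2]`, `w ∈ [0.2, 0.8]`.

Numerical guards: decision times at or below `t_floor = 1e-5 s`
(i.e. RT ≤ Ter) and densities below `density_floor = 1e-10` contribute
`log(1e-10)` to the log-likelihood. The floor keeps the optimizer finite
when a candidate `Ter` overtakes a fast RT; it also caps the leverage any
single far-tail trial can exert on the fit. Both values are package
choices; results are insensitive to them within an order of magnitude
because floored trials are rare at the optimum.

## Fitting

Each participant is fit independently by minimising the negative total
log-likelihood of their responded trials with L-BFGS-B under box bounds:
drift coefficients in [−8, 8], `a ∈ [0.1, 5]`, `w ∈ [0.05, 0.95]`,
`Tl ∈ [−0.5, 0.5]`, and `T0 ∈ [0, min RT over L=0 trials]`. The T0 cap
deserves a remark: the density has no support at `RT ≤ Ter`, but with a
negative valid-label shift `Tl`, valid-trial RTs extend below `T0`, so
capping `T0` at the *global* minimum RT systematically biases `T0`
downward by about `|Tl|` and `a` upward in compensation. Capping at the
minimum over invalid/control trials removes the bias (verified: with the
per-condition cap, zero-heterogeneity fits converge on the generating
values as trials grow, with vanishing bias); the valid-trial support
constraint `RT > T0 + Tl` is enforced by the density floor, plus a
quadratic penalty keeping `T0 + Tl ≥ 0`.

The optimizer restarts from 10 jittered initial points (uniform draws
from plausible interior windows of the bounds), keeping the best local
optimum. Restart seeds come from a nested spawn of the user seed, so
results are bit-reproducible given (data, seed), the best likelihood over
the first k starts is non-decreasing in k, and batch fits equal
individual fits regardless of table order. Trials are summed in a
canonical sort order because floating-point addition is
order-dependent.

Non-responses (RT beyond the 4 s deadline) are excluded from the
likelihood rather than entered as censored observations: at the parameter
scales of this task they are rare, and the simpler likelihood matches how
such data are usually analysed. Participants with fewer than 20 responded
trials are refused.

## Synthetic data generator

`simulate.DesignSpec` reproduces the behavioral studies' structure: three
arms (control without labels and two labels-present arms), default group
sizes 113/105/103, 72 trials per participant — 36 upright / 36 inverted,
labels-present arms fully crossed 18 per orientation×label cell, the
familiar side left/right balanced within every cell — randomized order
per participant, and a 4000 ms response deadline. Exposure-duration
subgroups, display identity, and black/white counterbalancing are not
modeled; no model parameter depends on them.

`simulate.PopulationSpec` draws per-participant true parameters from
truncated normals. The default means sit at the group-level magnitudes
characteristic of this task: thresholds near `a ≈ 0.78`, a control drift
structure of about 0.80 toward the correct side for inverted and +0.17
more for upright displays, valid-label drift increments of about 0.45
(inverted) and 0.82 (upright), a slight rightward start bias
(`w ≈ 0.52`), baseline non-decision time 0.5 s and a −40 ms valid-label
shift. The default SDs encode the substantial between-participant
heterogeneity such data show (drift coefficients 0.45–0.6; `a` 0.15; `w`
0.05; `T0` 0.10 s; `Tl` 0.06 s), back-computed from typical group-level
t-statistics and effect sizes for cohorts of ~100. These defaults were
fixed once, before any recovery experiment was run, and define the
conditions under which all validation results below are reported.

Trials are simulated by Euler–Maruyama with step `dt = 1e-4 s`, plus a
Brownian-bridge test for undetected within-step boundary crossings
(`P(cross) = exp(−2·d₀·d₁/dt)` for end distances d₀, d₁ to a boundary).
Naive Euler widens boundaries effectively by ≈ 0.58·√dt, a first-passage
bias of the same order as the distribution-level tolerances used here;
the bridge correction removes the leading term. With it, 10⁵ simulated
RTs pass a Kolmogorov–Smirnov test against the WFPT-implied conditional
CDF (p ≈ 0.3–0.5), and simulated choice frequencies and mean decision
times match the closed forms within Monte-Carlo error. What passing these
checks shows is internal consistency — simulator and likelihood describe
the same process; it does not certify the diffusion model as a correct
account of any real dataset.

## Identifiability at the single-session design

Per-trial Fisher information for a drift coefficient equals the mean
decision time. At this task's parameter scale (`a ≈ 0.78` caps the mean
decision time at `a²/4 ≈ 0.15 s`), one 18-trial design cell carries
information ≈ 18 × 0.14 ≈ 2.5, i.e. a cell-drift SE of ≈ 0.63; with the
0/1 covariate coding, the three-way coefficient `v_sol` is a four-cell
contrast with SE ≈ 1.3. Against population SDs of 0.45–0.6 this bounds
the attainable true-vs-fitted correlation for drift coefficients at 72
trials to roughly 0.4–0.65 regardless of estimator, while structural
parameters recover tightly (measured at 100 participants: `a` ≈ 0.94,
`T0` ≈ 0.997, `Tl` ≈ 0.98). The fits sit at this information bound:
zero-heterogeneity errors shrink as 1/√n with vanishing bias, and drift
correlations climb toward 1 as trials per participant grow
(72 → 288 → 1152). Two practical corollaries, both visible in the
validation outputs: individual-participant drift estimates at 72 trials
are noisy and carry a finite-sample bias of order +0.1–0.3 in the
richly-parameterized cells (group-mean contrasts inherit a share of it,
though CIs cover the generating effects), and group-level contrasts —
not individual estimates — are the quantities this design supports.

## Group analysis choices

* Condition drift rates toward the correct side follow from the drift
  equation at `S = +1`: upright-valid `v_s+v_so+v_sl+v_sol`,
  inverted-valid `v_s+v_sl`, upright-invalid `v_s+v_so`,
  inverted-invalid `v_s` (control: `v_s+v_so` / `v_s`).
* Increments over control are independent-groups comparisons of those
  per-participant condition drifts: pooled-variance t-test, t-based 95%
  CI, Cohen's d. Study-level "valid" means average each participant's
  upright-valid and inverted-valid drifts before averaging across
  participants.
* The 2×2 mixed ANOVA (between = study, within = orientation) uses the
  classical partition via `pingouin.mixed_anova`, validated in the tests
  against hand-computed sums of squares; with two levels per factor and
  complete cells the usual SS types coincide. Effect size is partial
  eta-squared.
* The fastest-RT contrast takes, per participant and label condition, the
  mean of the fastest ⌈0.20·n⌉ responded RTs; non-decision-time shifts
  move this statistic almost one-for-one while drift effects barely do.
* The quantile diagnostic splits each participant's responded RTs per
  condition at their own quartiles and compares participant-level bin
  means (RT and accuracy) against bins of trials simulated at that
  participant's fitted parameters (≈10⁴ draws per condition across the
  cohort), with Welch t-tests across participants and a 3-SE flag
  criterion. Aggregating at the participant level keeps
  between-participant variability in the test's denominator; per-trial
  tests would flag mere estimation error at large trial counts. In the
  contamination probe (5% of RTs replaced by uniform 2–4 s draws,
  emulating lapses the single-stage model cannot produce), parameters are
  estimated from the uncontaminated responding and the contaminated set
  is diagnosed against them: the last quantile bin flags (|t| ≥ 4) and
  the first three stay clean. Refitting on heavily contaminated data
  instead partially absorbs the tail into the parameters and dilutes the
  localized signal — the known non-robustness of ML estimation to
  outliers.

## Problem sizes

Validation runs use: the 45-point parameter grid for density invariants;
10⁵ trials for the simulator/likelihood KS check; 100 participants × 72
trials (10 optimizer starts each) for recovery; 50+50 participants for
the end-to-end effect-recovery experiment; 24 participants for the
contamination probe; and 2×10⁴ resamples for the permutation/bootstrap
oracles in the tests. These sizes make every check rerunnable on a single
core in minutes while keeping Monte-Carlo error well below the
tolerances asserted.

## Known limitations

* No across-trial variability parameters (sv, st, sz): the model fitted
  here has none, matching the analysis it implements.
* No censored-likelihood treatment of non-responses.
* The diffusion assumes a single integrated accumulation stage with fixed
  boundaries; the quantile diagnostic exists precisely to reveal where
  that assumption strains (typically the slowest correct responses).
* The synthetic population is a convenience for validation: real cohorts
  need not be normal in any parameter, and passing recovery or
  self-consistency checks under the generator says nothing about model
  adequacy for a particular empirical dataset.
* Drift-coefficient identifiability at the 72-trial single-session design
  is information-limited (see above); studies needing tight individual
  drift estimates require more trials per participant.
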