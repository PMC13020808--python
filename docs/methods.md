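# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the package's validation can show.

## 1. The task and its coalition-game benchmark

A trial shows two players' performances $(p_1, p_2)$ — counts of correct
prime-number judgments out of 20 — a collective task criterion, a threshold
$T$ (blank for the simple criterion) and the pot to allocate.  The three
criteria induce monotone two-player coalition games:

| criterion   | coalition value $v(S)$                         | block instruction |
|-------------|------------------------------------------------|-------------------|
| simple      | proportional: $v \cdot \sum_{i\in S} p_i / (p_1+p_2)$ | "no goal"   |
| additive    | pot if $\sum_{i \in S} p_i \ge T$, else 0      | "mutual reach"    |
| disjunctive | pot if $\max_{i \in S} p_i \ge T$, else 0      | "one reaches"     |

Threshold comparisons are inclusive ($\ge$), matching the worked
"mutual correct responses ≥ 5" reading.  $v(\emptyset)=0$ by the standard
normalization.  Money is held as exact rationals at 0.01-yen resolution so
Shapley efficiency ($\varphi_1+\varphi_2 = v(\{1,2\})$) is checked exactly,
not to float tolerance.  For two players the Shapley value has the closed
form $\varphi_1 = \tfrac12 v(\{1\}) + \tfrac12 (v(\{1,2\}) - v(\{2\}))$; the
test suite verifies it against explicit enumeration over both join orders
on 1,000+ random monotone games.  Threshold games yield ratios in
$\{0, \tfrac12, 1\}$, giving the three contribution structures
(*player 2 only* / *both* / *player 1 only*); simple trials are always
classified *both* since nothing gates the reward.

## 2. Design generator

Layouts: `exp1` (384 trials, 4 sessions, conditions SforS/OforO), `exp2`
(216 trials, 6 sessions, same conditions), `exp3` (4 crossed
source×recipient conditions; trial counts are not pinned by the
two-condition layouts, so the default keeps exp2's 36 trials per cell,
giving 432 trials in 6 sessions).  Every (condition × criterion) cell
receives equal counts, and each session contains one mini-block per cell in
a seed-permuted order.

The stimulus set is shared across conditions (same `stimulus_id`), enabling
exact trial-wise matching.  Performance pairs are drawn from a discrete
grid (default 0..20, the per-trial judgment count) and *mirrored*: every
stimulus $(a,b)$ has a partner $(b,a)$ with the same threshold and pot, so
the reward list's mean relative performance is exactly 0.5.  Loss trials
(default 20%, configurable) are flagged at the mirror-pair level — keeping
the reward subset symmetric — carry a negative pot, and are excluded from
all analyses.  Reward trials of the goal criteria are sampled conditional
on reaching the goal (there is otherwise nothing to allocate), and each
criterion's reward set is re-sampled until all three contribution
structures occur (bounded retries; an infeasible grid raises).

Defaults chosen where the task description leaves them open: thresholds
$\{3,\dots,8\}$; pots $\{6, 8, 10, 12\}$ yen for goal criteria; simple-trial
pot = 1 yen per correct response; decision time limits (8 s / 6 s) stored as
metadata only.  The number-list generator samples 20 primes, 10 even
non-primes and 10 odd non-primes from $[1, 1000]$ (primality via sympy) and
is deterministic given its seed.

## 3. Synthetic allocators

There is no participant-level generative account to copy, so the agent
model is this module's own design commitment, built to be *recoverable* by
the analysis model rather than to claim mechanism.  Self-bias enters on the
log-odds scale — the same scale as the ZOIB logit link — which keeps
recovery well-posed:

$$\operatorname{logit}(\mu) = \operatorname{logit}\bigl(w r + (1-w)/2\bigr)
  + \underbrace{(b_0 + b_{svo} z + b_{contrib} \mathbb{1}[\text{p2 only}])}_{\text{self-bias}}
  \cdot \mathbb{1}[\text{gate}]$$

with $r$ the trial's relative performance, $w = w_{\text{perf}} -
\Delta w_{\text{self}} \cdot \mathbb{1}[\text{gate}]$ the performance
weight, and the gate following the *recipient* of the allocation
(conditions SforS/OforS), not the performance source — the crossed-design
conclusion; a `bias_gating="source"` switch exists for sensitivity runs.
The blend is clipped to $(10^{-6}, 1-10^{-6})$ before the logit.
Responses mirror the analysis family: boundary with probability `zoi`
(1 with conditional probability `coi`), otherwise
$\mathrm{Beta}(\mu\phi, (1-\mu)\phi)$, then rounding to the 0.1-yen slider
grid with player 2 receiving the exact remainder.  Miss trials are dropped
at a configurable rate (default 0.96%, the scanner-experiment-like value).

Default population regime (means ± SDs, truncated to supports): SVO angle
25° ± 14° (angles standardized within-cohort before entering the model);
$b_0 = 0.2 \pm 0.1$ — an odds ratio of $e^{0.2} \approx 1.22$, the
qualitative regime the analysis must detect; $b_{svo} = -0.15 \pm 0.05$ per
SD of SVO; $w_{\text{perf}} = 0.85 \pm 0.05$;
$\Delta w_{\text{self}} = 0.15 \pm 0.05$; $b_{contrib} = 0.2 \pm 0.1$;
$\phi = 30 \pm 5$; zoi $= 0.05$, coi $= 0.5$.
`CohortDistribution.null()` switches every bias mechanism off, producing a
player-exchangeable cohort for calibration.

What the generator does *not* emulate: learning or adaptation across
trials, reaction times, inequity-aversion heterogeneity beyond the single
SVO axis, and any dependence of noise on condition.  Passing recovery tests
therefore show that the pipeline detects effects of the stated form and
size under clean conditions — not that human data satisfy the agent model.

## 4. The ZOIB mixed model

Density: $P(y{=}0) = \text{zoi}(1-\text{coi})$, $P(y{=}1) =
\text{zoi}\cdot\text{coi}$, interior $\propto (1-\text{zoi}) \cdot
\mathrm{Beta}(y; \mu\phi, (1-\mu)\phi)$; normalization is verified by
quadrature to $10^{-6}$.  The inflation parts are intercept-only
(the standard default when only $\mu$ is conditioned), and $\phi$ is a
scalar — both documented simplifications of the family.

The five standard analyses shipped in the pipeline are

1. `relative_allocation ~ self_relevance * criterion + (1|participant_id)`
2. `relative_allocation ~ self_relevance * criterion * svo_z + (1|participant_id)`
3. `relative_allocation ~ relative_performance * self_relevance + relative_performance * criterion + (1|participant_id)`
4. `bias ~ contribution_category + (1|participant_id)`
5. `bias ~ contribution_category * svo_z + (1|participant_id)`

Analysis 1 is the self-relevance × criterion model described in prose (the
printed formula for it duplicates analysis 3's; the prose version is
implemented).  SVO scores are standardized before entry.  Treatment coding
uses the self-irrelevant condition, the simple criterion and the "both"
category as reference levels.  The matched self-allocation bias lives in
$[-1, 1]$; the model maps it affinely onto $[0,1]$ ($y \mapsto (y+1)/2$,
boundary masses at $\pm 1$ becoming the inflation masses) since the family
is only defined there — contrasts keep their signs under this monotone map.
For the crossed design the bias table does not privilege one difference:
`self_allocation_bias(records, "SforS", "SforO")` and
`(..., "SforS", "OforS")` expose the recipient- and source-matched
contrasts explicitly.

**Estimation.**  Random intercepts are marginalized per participant with a
one-dimensional Laplace approximation (vectorized Newton on the conditional
modes; the trigamma function needed for curvatures is computed by
recurrence + asymptotic series, accurate to ~$10^{-11}$).  The resulting
marginal posterior over $(\beta, \log\phi, \operatorname{logit}\text{zoi},
\operatorname{logit}\text{coi}, \log\sigma_u)$ is maximized with L-BFGS;
the default engine draws from the Gaussian (Laplace) approximation at the
mode, with the Hessian from central finite differences and its negative
inverse eigenvalue-floored at $10^{-8}$ for positive definiteness.  The
MCMC engine runs an affine-invariant ensemble sampler on the same marginal
posterior; walker series are treated as chains for split-R-hat, any value
above 1.05 flags the fit (`converged=False`, never silent).  Default
iterations 3,000 with warmup 1,000 — the warmup is deliberately longer than
the reported 100, which is treated as a setting, not a constraint.

**Priors** (declared and fixed): $\beta \sim N(0, 2.5)$ on the logit scale,
$\log\phi \sim N(\log 10, 1.5)$, inflation logits $\sim N(0,2)$,
$\sigma_u \sim$ half-$N(0,1)$.  These are weakly informative at the scale
of allocation shares; the parameter-recovery harness doubles as a
prior-sensitivity check in the effect-size regime of interest.

**Post-hoc machinery.**  Marginal means are computed emmeans-style: a
reference grid over all categorical factors with numeric covariates at
their sample means, averaged on the link scale with equal weights over
non-requested factors; pairwise contrasts are formed on the logit scale and
exponentiated to odds ratios.  Trends of a numeric covariate use a central
finite difference on the linear predictor (exact for linear terms).  All
intervals are highest-posterior-density intervals (shortest interval over
sorted draws; ties resolved toward the lower bound), 95% by default.
Pointwise log-likelihoods condition on random-intercept draws
(conditional Laplace mean plus Gaussian noise per posterior draw), and
model comparison uses PSIS-LOO via arviz, reporting
$\Delta \text{elpd} = \sum_i (\text{elpd}^A_i - \text{elpd}^B_i)$ with
SE $= \sqrt{n \cdot \operatorname{var}(\text{diff}_i)}$ (identically zero
for a model against itself).  Because the Laplace engine yields draws,
PSIS-LOO applies to both engines and no cross-validation fallback is
needed.

## 5. Validation design and problem sizes

The recovery harness simulates 20 replicate cohorts of 40 participants on
the exp2 layout (about 170 analyzable trials per participant after loss and
miss exclusion) and requires the full sign-and-significance pattern —
(i) self vs other odds ratio above 1 with 95% HPD excluding 1,
(ii) negative SVO trend only in the self-relevant margin,
(iii) a positive other-minus-self performance-slope difference, and
(iv) the "player 2 only" category showing the largest bias with both
pairwise HPDs excluding equality — in at least 18 of 20 replicates.  The
SVO check is evaluated at the self-relevance margin (trends by recipient,
averaged over criteria) rather than per criterion cell: the headline claim
lives at that margin, and requiring three simultaneous null checks per
replicate would fail ~14% of truly-well-calibrated replicates by
construction.  The null-cohort calibration check uses 99% HPD intervals
jointly across the four headline estimates, a pre-specified family-wise
choice (~4% type-I) for a single-replicate pass/fail test.  Cohort sizes
were chosen as typical for this literature and to keep a full fit in
seconds on one CPU.

## 6. Known limitations

- The inflation parts are intercept-only and precision is homogeneous;
  condition-dependent boundary behavior would be absorbed into $\mu$.
- The Laplace marginal underestimates skew in $\sigma_u$'s posterior when
  groups are few; the MCMC engine is the check for such cases.
- The ensemble sampler's walker-as-chain R-hat is conservative at short
  chain lengths; expect flags below ~1,500 iterations even on well-behaved
  posteriors.
- The agent model is a stand-in validated by pattern reproduction and
  parameter recovery only; no claim is made that it is the participants'
  decision mechanism.
- `exp3` trial counts and loss-trial magnitudes are package defaults, not
  reconstructed facts.
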