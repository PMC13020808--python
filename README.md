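# shapalloc

**Shapley-benchmarked reward allocation: task design, agent simulation, and
hierarchical zero-one-inflated beta inference.**

When two people earn a joint reward through a collective task, how should —
and how *do* — they split it?  `shapalloc` is a reusable, tested pipeline for
studying *performance-based social allocation*: a modified dictator game in
which an allocator divides a pot between two players whose performances
(counts of correct prime-number judgments) and a collective task criterion
jointly determine the outcome.  The package targets researchers in
behavioral game theory and social decision-making who want to

- generate the task (number lists, symmetric trial lists, block orders) for
  two-condition and crossed source×recipient layouts;
- score each trial's *objective* contribution benchmark with the Shapley
  value of the induced two-player coalition game;
- simulate cohorts of allocating agents with known self-bias,
  social-preference (SVO) linkage and performance weighting; and
- fit the field's analysis model — hierarchical zero-one-inflated beta
  (ZOIB) regression — and recover those generative effects.

## The core machinery

**Coalition games.**  A reward trial with performances $(p_1, p_2)$,
threshold $T$ and pot $v$ induces a monotone game: under the *additive*
criterion a coalition $S$ wins iff $\sum_{i \in S} p_i \ge T$; under the
*disjunctive* criterion iff $\max_{i \in S} p_i \ge T$; the *simple*
criterion pays proportionally to total correct responses.  The two-player
Shapley value

$$\varphi_1 = \tfrac12 v(\{1\}) + \tfrac12\bigl(v(\{1,2\}) - v(\{2\})\bigr)$$

splits the pot by average marginal contribution; for threshold games the
ratio $\varphi_1 / v(\{1,2\})$ is exactly $1$, $\tfrac12$ or $0$, which
classifies every trial as *player 1 only*, *both*, or *player 2 only*.

**Inference.**  Relative allocation $y \in [0,1]$ (player 1's share) is
modeled as

$$y_{ij} \sim \mathrm{ZOIB}(\mu_{ij}, \phi, \mathrm{zoi}, \mathrm{coi}),
\qquad \operatorname{logit}(\mu_{ij}) = x_{ij}^\top \beta + u_j,
\qquad u_j \sim \mathcal N(0, \sigma_u^2),$$

a mixture of point masses at 0 and 1 with a beta density inside.  Formulas
use the familiar mixed-model syntax
(`y ~ a * b + (1|participant_id)`); random intercepts are integrated out by
a per-participant Laplace approximation, and the posterior over the
remaining parameters is summarized either by a Gaussian approximation at
the MAP (`engine="laplace"`, seconds) or by ensemble MCMC
(`engine="mcmc"`, with R-hat diagnostics).  Results objects provide
estimated marginal means and trends with pairwise contrasts (odds ratios,
slope differences) and 95% highest-posterior-density intervals, plus
PSIS-LOO model comparison.

## Worked example

```python
from shapalloc import (TrialSpec, characteristic_function, shapley_values,
                       shapley_ratio, contribution_category,
                       simulate_cohort, CohortDistribution, ZOIBModel)

# One trial: additive criterion, performances 2 and 3, threshold 5, pot 10.
t = TrialSpec("additive", p1=2, p2=3, threshold=5, pot=10)
g = characteristic_function(t)   # v({1}) = 0, v({2}) = 0, v({1,2}) = 10
shapley_values(g)                # (5, 5): neither player wins alone
shapley_ratio(t)                 # 1/2  ->  category "both"

# Simulate 40 participants with the default biased regime, then fit.
records, truth = simulate_cohort(40, CohortDistribution(), seed=1)
fit = ZOIBModel.from_formula(
    "relative_allocation ~ self_relevance * criterion * svo_z + (1|participant_id)",
    records).fit(seed=1)
print(fit.marginal_means({"self_relevance": ["self", "other"]}).contrasts)
print(fit.marginal_slopes("svo_z", ["self_relevance"]).slopes)
```

Output:

```
    contrast  odds_ratio   log_or    lower    upper
self / other    1.171458 0.158032 1.118767 1.226248
 cell     slope     lower     upper
other  0.003716 -0.030424  0.034130
 self -0.165988 -0.200142 -0.136148
```

Read: when the allocator is also a recipient ("self"), the odds of
allocating to player 1 rise by ~17% relative to the spectator condition
(HPD excludes 1) — a self-allocation bias; and more prosocial agents
(higher standardized SVO angle, `svo_z`) show *less* of it, but only in the
self-relevant cells — both patterns the cohort was generated with
(`truth` holds each agent's parameters for recovery checks).

A full pipeline run (design → simulate → score → fit → report) is available
from the shell:

```bash
shapalloc all --seed 1 --out runs/demo --experiment exp2
```

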