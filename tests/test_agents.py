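"""Synthetic allocating agents: latent means, sampling, cohort simulation."""

import numpy as np
import pytest

from shapalloc.agents import (
    AgentParams,
    CohortDistribution,
    agent_target_ratio,
    sample_allocation,
    simulate_cohort,
)
from shapalloc.games import TrialSpec


def trial(condition="SforS", p1=2, p2=3, criterion="additive", threshold=5, pot=10):
    return TrialSpec(criterion, p1, p2, threshold=threshold, pot=pot, condition=condition,
                     trial_id="t0", stimulus_id="s0")


class TestTargetRatio:
    def test_pure_performance_matcher_reproduces_relative_performance(self):
        agent = AgentParams(w_perf_other=1.0)
        assert agent_target_ratio(agent, trial(p1=2, p2=3)) == pytest.approx(0.4)

    def test_symmetric_trial_gives_half_without_bias(self):
        agent = AgentParams(w_perf_other=0.7)
        assert agent_target_ratio(agent, trial(p1=4, p2=4, threshold=5)) == pytest.approx(0.5)

    def test_bias_gated_by_recipient(self):
        biased = AgentParams(b0=0.5)
        base = AgentParams(b0=0.0)
        t_other = trial(condition="OforO")
        assert agent_target_ratio(biased, t_other) == pytest.approx(
            agent_target_ratio(base, t_other)
        )
        t_self = trial(condition="SforS")
        assert agent_target_ratio(biased, t_self) > agent_target_ratio(base, t_self)

    def test_crossed_conditions_follow_recipient_not_source(self):
        biased = AgentParams(b0=0.5)
        base = AgentParams(b0=0.0)
        # OforS: others' performance, self receives -> bias applies
        assert agent_target_ratio(biased, trial(condition="OforS")) > agent_target_ratio(
            base, trial(condition="OforS")
        )
        # SforO: own performance, others receive -> no bias
        assert agent_target_ratio(biased, trial(condition="SforO")) == pytest.approx(
            agent_target_ratio(base, trial(condition="SforO"))
        )
        # the sensitivity switch flips the gating
        assert agent_target_ratio(
            biased, trial(condition="SforO"), bias_gating="source"
        ) > agent_target_ratio(base, trial(condition="SforO"), bias_gating="source")

    def test_contribution_bias_only_in_player2_only_trials(self):
        agent = AgentParams(b_contrib=0.8)
        t_p2 = trial(p1=1, p2=6)  # additive, only player 2 reaches
        t_both = trial(p1=2, p2=3)
        base = AgentParams()
        lift_p2 = agent_target_ratio(agent, t_p2) - agent_target_ratio(base, t_p2)
        lift_both = agent_target_ratio(agent, t_both) - agent_target_ratio(base, t_both)
        assert lift_p2 > 0
        assert lift_both == pytest.approx(0.0)


class TestSampling:
    def test_boundary_frequency_matches_zoi(self):
        agent = AgentParams(zoi=0.15, coi=0.6)
        rng = np.random.default_rng(0)
        n = 10_000
        draws = [
            sample_allocation(agent, trial(), rng)["relative_allocation"] for _ in range(n)
        ]
        draws = np.asarray(draws)
        frac = np.mean((draws == 0) | (draws == 1))
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(frac - 0.15) < 3 * se

    def test_allocations_conserve_pot(self):
        agent = AgentParams(zoi=0.3)
        rng = np.random.default_rng(1)
        for _ in range(200):
            rec = sample_allocation(agent, trial(pot=12), rng)
            assert rec["allocation_p1"] + rec["allocation_p2"] == pytest.approx(12.0)
            steps = rec["allocation_p1"] * 10  # 0.1-yen slider granularity
            assert steps == pytest.approx(round(steps), abs=1e-6)

    def test_high_precision_concentrates_on_mu(self):
        agent = AgentParams(zoi=0.0, phi_prec=50_000, b0=0.3)
        rng = np.random.default_rng(2)
        mu = agent_target_ratio(agent, trial())
        draws = [
            sample_allocation(agent, trial(), rng, granularity=1e-6)["relative_allocation"]
            for _ in range(50)
        ]
        assert np.allclose(draws, mu, atol=0.02)


class TestCohort:
    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            simulate_cohort(1, seed=0)

    def test_unbiased_cohort_is_exchangeable(self):
        rec, truth = simulate_cohort(30, CohortDistribution.null(), seed=5)
        means = rec.groupby("self_relevance").relative_allocation.mean()
        # Monte-Carlo error of a mean over ~3000 trials with sd ~0.2
        assert abs(means["self"] - 0.5) < 0.02
        assert abs(means["other"] - 0.5) < 0.02
        assert (truth[["b0", "b_svo", "dw_self", "b_contrib"]] == 0).all().all()

    def test_baseline_bias_raises_self_allocation(self):
        rec, _ = simulate_cohort(30, CohortDistribution(), seed=5)
        means = rec.groupby("self_relevance").relative_allocation.mean()
        assert means["self"] > means["other"] + 0.02

    def test_bias_monotone_in_b0(self):
        gaps = []
        for b0 in (0.1, 0.4, 0.8):
            dist = CohortDistribution(b0_mean=b0, b0_sd=0.0, b_svo_mean=0.0, b_svo_sd=0.0,
                                      b_contrib_mean=0.0, b_contrib_sd=0.0,
                                      dw_self_mean=0.0, dw_self_sd=0.0)
            rec, _ = simulate_cohort(20, dist, seed=9)
            m = rec.groupby("self_relevance").relative_allocation.mean()
            gaps.append(m["self"] - m["other"])
        assert gaps[0] < gaps[1] < gaps[2]

    def test_deterministic_given_seed(self):
        a, _ = simulate_cohort(5, seed=3)
        b, _ = simulate_cohort(5, seed=3)
        assert a.equals(b)

    def test_records_carry_ground_truth_and_conservation(self):
        rec, truth = simulate_cohort(6, seed=2)
        assert set(truth.participant_id) == set(rec.participant_id)
        assert np.allclose(rec.allocation_p1 + rec.allocation_p2, rec.pot)
        assert np.allclose(
            rec.relative_allocation, rec.allocation_p1 / rec.pot, atol=1e-9
        )
        assert rec.svo_z.std() > 0
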