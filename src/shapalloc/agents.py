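"""Synthetic allocating agents with self-bias, social preferences, and noise.

Each agent turns a reward trial into a latent target share for player 1 and
emits a noisy slider response.  The latent mean blends the trial's relative
performance ``r`` with the equal split::

    logit(mu) = logit(w * r + (1 - w) * 0.5) + self_bias

where ``w = w_perf_other - dw_self * [self is a recipient]`` is the weight
placed on performance, and::

    self_bias = (b0 + b_svo * z_svo + b_contrib * [player2_only]) * gate

with ``gate = 1`` when the allocation recipients include the agent (the
crossed-design finding: the bias follows the recipient of the money, not
the source of the performance; ``bias_gating="source"`` switches this for
sensitivity runs).  ``z_svo`` is the agent's SVO angle standardized across
the cohort, with ``b_svo <= 0`` so individualistic agents self-allocate
more.  The observation model mirrors the analysis model: boundary responses
with probability ``zoi`` (1 with conditional probability ``coi``), interior
responses Beta with precision ``phi_prec``, then conversion to money at the
slider granularity preserving the pot sum.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

from .design import ExperimentLayout, PerformanceConfig, StimulusList, generate_stimulus_list
from .games import Condition, ContributionStructure, TrialSpec, contribution_category

__all__ = [
    "AgentParams",
    "CohortDistribution",
    "agent_target_ratio",
    "sample_allocation",
    "simulate_cohort",
]

_EPS = 1e-6  # latent blend is clipped into (eps, 1 - eps) before the logit


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic allocator."""

    svo_angle: float = 25.0  # degrees
    b0: float = 0.0          # baseline self-bias, log-odds
    b_svo: float = 0.0       # SVO slope on self-bias (<= 0 matches the observed direction)
    w_perf_other: float = 0.85  # performance weight when self is not a recipient
    dw_self: float = 0.0     # reduction of the weight when self receives (>= 0)
    b_contrib: float = 0.0   # extra self-bias when only player 2 contributed (>= 0)
    phi_prec: float = 30.0   # beta precision
    zoi: float = 0.05        # boundary-response probability
    coi: float = 0.5         # P(boundary response is 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_perf_other <= 1.0:
            raise ValueError("w_perf_other must lie in [0, 1]")
        if self.dw_self < 0 or self.dw_self > self.w_perf_other:
            raise ValueError("dw_self must lie in [0, w_perf_other]")
        if self.b_svo > 0:
            raise ValueError("b_svo must be <= 0")
        if self.b_contrib < 0:
            raise ValueError("b_contrib must be >= 0")
        if self.phi_prec <= 0:
            raise ValueError("phi_prec must be positive")
        if not 0.0 <= self.zoi < 1.0:
            raise ValueError("zoi must lie in [0, 1)")
        if not 0.0 <= self.coi <= 1.0:
            raise ValueError("coi must lie in [0, 1]")


@dataclass(frozen=True)
class CohortDistribution:
    """Population means/SDs of AgentParams (parameters truncated to support).

    The default regime mirrors the effects the analysis pipeline must
    recover: a baseline self-bias of ~0.2 log-odds (odds ratio ~1.2), a
    negative SVO slope, a reduced performance weight when allocating to
    oneself, and extra bias when only the partner contributed.
    """

    svo_angle_mean: float = 25.0
    svo_angle_sd: float = 14.0
    b0_mean: float = 0.2
    b0_sd: float = 0.1
    b_svo_mean: float = -0.15
    b_svo_sd: float = 0.05
    w_perf_other_mean: float = 0.85
    w_perf_other_sd: float = 0.05
    dw_self_mean: float = 0.15
    dw_self_sd: float = 0.05
    b_contrib_mean: float = 0.2
    b_contrib_sd: float = 0.1
    phi_prec_mean: float = 30.0
    phi_prec_sd: float = 5.0
    zoi: float = 0.05
    coi: float = 0.5

    @classmethod
    def null(cls) -> "CohortDistribution":
        """Exchangeable cohort: every bias mechanism switched off."""
        return cls(
            b0_mean=0.0, b0_sd=0.0,
            b_svo_mean=0.0, b_svo_sd=0.0,
            dw_self_mean=0.0, dw_self_sd=0.0,
            b_contrib_mean=0.0, b_contrib_sd=0.0,
        )

    def sample(self, n: int, rng: np.random.Generator) -> list[AgentParams]:
        def trunc(mean, sd, lo, hi):
            return float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))

        agents = []
        for _ in range(n):
            w = trunc(self.w_perf_other_mean, self.w_perf_other_sd, 0.0, 1.0)
            agents.append(
                AgentParams(
                    svo_angle=trunc(self.svo_angle_mean, self.svo_angle_sd, -16.26, 61.39),
                    b0=float(rng.normal(self.b0_mean, self.b0_sd)) if self.b0_sd > 0 else self.b0_mean,
                    b_svo=trunc(self.b_svo_mean, self.b_svo_sd, -np.inf, 0.0),
                    w_perf_other=w,
                    dw_self=trunc(self.dw_self_mean, self.dw_self_sd, 0.0, w),
                    b_contrib=trunc(self.b_contrib_mean, self.b_contrib_sd, 0.0, np.inf),
                    phi_prec=trunc(self.phi_prec_mean, self.phi_prec_sd, 5.0, np.inf),
                    zoi=self.zoi,
                    coi=self.coi,
                )
            )
        return agents


def _gate(trial: TrialSpec, bias_gating: str) -> bool:
    if bias_gating == "recipient":
        return trial.condition.recipient_is_self
    if bias_gating == "source":
        return trial.condition.source_is_self
    raise ValueError("bias_gating must be 'recipient' or 'source'")


def agent_target_ratio(
    agent: AgentParams,
    trial: TrialSpec,
    svo_z: float = 0.0,
    bias_gating: str = "recipient",
) -> float:
    """Latent mean share for player 1 on a reward trial, in (0, 1)."""
    if trial.is_loss:
        raise ValueError("loss trials are not allocated")
    total = trial.p1 + trial.p2
    if total == 0:
        raise ValueError("relative performance undefined for zero total performance")
    r = trial.p1 / total
    gate = _gate(trial, bias_gating)
    w = agent.w_perf_other - (agent.dw_self if gate else 0.0)
    blend = np.clip(w * r + (1.0 - w) * 0.5, _EPS, 1.0 - _EPS)
    bias = 0.0
    if gate:
        bias = agent.b0 + agent.b_svo * svo_z
        if contribution_category(trial) is ContributionStructure.PLAYER2_ONLY:
            bias += agent.b_contrib
    logit = np.log(blend / (1.0 - blend)) + bias
    return float(1.0 / (1.0 + np.exp(-logit)))


def sample_allocation(
    agent: AgentParams,
    trial: TrialSpec,
    seed=None,
    svo_z: float = 0.0,
    bias_gating: str = "recipient",
    granularity: float = 0.1,
) -> dict:
    """Draw one allocation decision; returns a tidy record dict.

    The continuous draw is converted to money on the slider grid
    (``granularity`` yen steps); player 2 receives the remainder so the two
    allocations sum exactly to the pot.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = agent_target_ratio(agent, trial, svo_z, bias_gating)
    if rng.uniform() < agent.zoi:
        ratio = 1.0 if rng.uniform() < agent.coi else 0.0
    else:
        ratio = float(rng.beta(mu * agent.phi_prec, (1 - mu) * agent.phi_prec))
    pot = float(trial.pot)
    a1 = round(round(ratio * pot / granularity) * granularity, 10)
    a1 = min(max(a1, 0.0), pot)
    a2 = round(pot - a1, 10)
    total = trial.p1 + trial.p2
    return {
        "trial_id": trial.trial_id,
        "stimulus_id": trial.stimulus_id,
        "condition": trial.condition.value,
        "criterion": trial.criterion.value,
        "contribution_category": contribution_category(trial).value,
        "relative_performance": trial.p1 / total,
        "relative_allocation": a1 / pot,
        "allocation_p1": a1,
        "allocation_p2": a2,
        "pot": pot,
    }


def simulate_cohort(
    n_participants: int,
    param_distribution: Optional[CohortDistribution] = None,
    layout: Optional[ExperimentLayout] = None,
    seed: int = 0,
    perf_config: Optional[PerformanceConfig] = None,
    stimuli: Optional[StimulusList] = None,
    bias_gating: str = "recipient",
    granularity: float = 0.1,
    miss_rate: float = 0.0096,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort on one experiment layout.

    Returns ``(records, truth)``: a tidy trial-level table of allocation
    decisions (loss and missed trials already excluded, as in the analysis)
    and the per-participant ground-truth parameter table for recovery tests.
    SVO angles are standardized within the cohort (column ``svo_z``).
    """
    if n_participants < 2:
        raise ValueError("a hierarchical cohort needs at least 2 participants")
    from .design import experiment_layout  # local import to avoid cycle confusion

    layout = layout or experiment_layout("exp2")
    dist = param_distribution or CohortDistribution()
    rng = np.random.default_rng(seed)
    if stimuli is None:
        stimuli = generate_stimulus_list(layout, perf_config, seed=int(rng.integers(2**31)))
    agents = dist.sample(n_participants, rng)

    angles = np.array([a.svo_angle for a in agents])
    sd = angles.std()
    zs = (angles - angles.mean()) / sd if sd > 0 else np.zeros_like(angles)

    reward = stimuli.reward_trials()
    # per-trial arrays shared by all participants
    n_t = len(reward)
    r = np.array([t.p1 / (t.p1 + t.p2) for t in reward])
    gate = np.array([_gate(t, bias_gating) for t in reward])
    cats = np.array([contribution_category(t).value for t in reward])
    p2only = cats == ContributionStructure.PLAYER2_ONLY.value
    pot = np.array([float(t.pot) for t in reward])
    meta = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in reward],
            "stimulus_id": [t.stimulus_id for t in reward],
            "condition": [t.condition.value for t in reward],
            "criterion": [t.criterion.value for t in reward],
            "contribution_category": cats,
            "relative_performance": r,
            "pot": pot,
        }
    )

    frames = []
    truth_rows = []
    for i, (agent, z) in enumerate(zip(agents, zs)):
        pid = f"p{i:03d}"
        prng = np.random.default_rng(rng.integers(2**31))
        kept = prng.uniform(size=n_t) >= miss_rate  # misses: no response in time
        w = agent.w_perf_other - np.where(gate, agent.dw_self, 0.0)
        blend = np.clip(w * r + (1.0 - w) * 0.5, _EPS, 1.0 - _EPS)
        bias = np.where(gate, agent.b0 + agent.b_svo * z + agent.b_contrib * p2only, 0.0)
        mu = 1.0 / (1.0 + np.exp(-(np.log(blend / (1.0 - blend)) + bias)))
        boundary = prng.uniform(size=n_t) < agent.zoi
        ones = prng.uniform(size=n_t) < agent.coi
        beta = prng.beta(mu * agent.phi_prec, (1 - mu) * agent.phi_prec)
        ratio = np.where(boundary, np.where(ones, 1.0, 0.0), beta)
        a1 = np.clip(np.round(ratio * pot / granularity) * granularity, 0.0, pot)
        a1 = np.round(a1, 10)
        df = meta[kept].copy()
        df["relative_allocation"] = (a1 / pot)[kept]
        df["allocation_p1"] = a1[kept]
        df["allocation_p2"] = np.round(pot - a1, 10)[kept]
        df["participant_id"] = pid
        df["svo_angle"] = agent.svo_angle
        df["svo_z"] = z
        frames.append(df)
        truth_rows.append(
            {"participant_id": pid, "svo_z": z,
             **{f.name: getattr(agent, f.name) for f in fields(agent)}}
        )
    records = pd.concat(frames, ignore_index=True)
    records["self_relevance"] = np.where(
        records.condition.isin([Condition.SFORS.value, Condition.OFORS.value]),
        "self", "other",
    )
    records["source"] = np.where(
        records.condition.isin([Condition.SFORS.value, Condition.SFORO.value]),
        "self", "other",
    )
    return records, pd.DataFrame(truth_rows)
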