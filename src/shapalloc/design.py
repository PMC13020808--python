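"""Experiment layouts, prime-judgment number lists, and symmetric trial lists.

The performance task shows 40 numbers per list (20 primes, 10 even
non-primes, 10 odd non-primes, all in 1..1000) and the cover story maps a
random 20 of those judgments onto each allocation trial, so displayed
performances live on 0..20.  The allocation task is organised in sessions
of alternating mini-blocks, one block per (condition x criterion) cell,
each cell receiving the same number of trials:

==========  ========  ======  ==========  ==============================
layout      sessions  trials  conditions  trials per (cond x crit) cell
==========  ========  ======  ==========  ==============================
``exp1``        4       384   2           64
``exp2``        6       216   2           36
``exp3``        6       432   4           36
==========  ========  ======  ==========  ==============================

The same stimulus set is shown in every condition (stimulus_id is shared),
and performance pairs are mirrored between players — for every stimulus
with performances (a, b) there is a partner stimulus with (b, a) — so the
mean relative performance of player 1 over the list is exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import sympy

from .games import (
    Condition,
    ContributionStructure,
    Criterion,
    TrialSpec,
    contribution_category,
    shapley_ratio,
)

__all__ = [
    "NumberList",
    "ExperimentLayout",
    "PerformanceConfig",
    "StimulusList",
    "generate_number_list",
    "generate_stimulus_list",
    "assign_blocks",
    "experiment_layout",
    "trials_to_frame",
    "trials_from_frame",
    "annotate_trials",
    "INSTRUCTION_LABELS",
]

#: Block instruction shown for each criterion.
INSTRUCTION_LABELS = {
    Criterion.SIMPLE: "no goal",
    Criterion.ADDITIVE: "mutual reach",
    Criterion.DISJUNCTIVE: "one reaches",
}

NUMBERS_PER_LIST = 40
N_PRIMES = 20
N_EVEN = 10
N_ODD_NONPRIME = 10
NUMBER_RANGE = (1, 1000)


@dataclass(frozen=True)
class NumberList:
    """One performance-task list: 40 numbers with their class labels."""

    numbers: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.numbers) != NUMBERS_PER_LIST or len(self.labels) != NUMBERS_PER_LIST:
            raise ValueError(f"a list holds exactly {NUMBERS_PER_LIST} numbers")
        if len(set(self.numbers)) != NUMBERS_PER_LIST:
            raise ValueError("duplicate numbers in list")
        lo, hi = NUMBER_RANGE
        if min(self.numbers) < lo or max(self.numbers) > hi:
            raise ValueError(f"numbers must lie in [{lo}, {hi}]")
        counts = pd.Series(self.labels).value_counts()
        if (
            counts.get("prime", 0) != N_PRIMES
            or counts.get("even_nonprime", 0) != N_EVEN
            or counts.get("odd_nonprime", 0) != N_ODD_NONPRIME
        ):
            raise ValueError("list must hold 20 primes, 10 even and 10 odd non-primes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"number": self.numbers, "label": self.labels})


def generate_number_list(seed: int) -> NumberList:
    """Sample a valid number list; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    lo, hi = NUMBER_RANGE
    primes = np.array(list(sympy.primerange(lo, hi + 1)))
    evens = np.array([n for n in range(lo, hi + 1) if n % 2 == 0 and not sympy.isprime(n)])
    odds = np.array([n for n in range(lo, hi + 1) if n % 2 == 1 and not sympy.isprime(n)])
    chosen = np.concatenate(
        [
            rng.choice(primes, N_PRIMES, replace=False),
            rng.choice(evens, N_EVEN, replace=False),
            rng.choice(odds, N_ODD_NONPRIME, replace=False),
        ]
    )
    labels = np.array(
        ["prime"] * N_PRIMES + ["even_nonprime"] * N_EVEN + ["odd_nonprime"] * N_ODD_NONPRIME
    )
    order = rng.permutation(NUMBERS_PER_LIST)
    return NumberList(tuple(int(n) for n in chosen[order]), tuple(labels[order]))


@dataclass(frozen=True)
class ExperimentLayout:
    """Session/trial structure of one experiment."""

    experiment: str
    n_sessions: int
    total_trials: int
    conditions: tuple[Condition, ...]
    criteria: tuple[Criterion, ...] = (
        Criterion.SIMPLE,
        Criterion.ADDITIVE,
        Criterion.DISJUNCTIVE,
    )
    decision_time_limit: float = 6.0  # seconds; metadata only

    @property
    def n_cells(self) -> int:
        return len(self.conditions) * len(self.criteria)

    @property
    def trials_per_cell(self) -> int:
        if self.total_trials % self.n_cells:
            raise ValueError(
                f"{self.total_trials} trials cannot be divided over {self.n_cells} cells"
            )
        return self.total_trials // self.n_cells

    @property
    def trials_per_session(self) -> int:
        if self.total_trials % self.n_sessions:
            raise ValueError(
                f"{self.total_trials} trials cannot be divided over {self.n_sessions} sessions"
            )
        return self.total_trials // self.n_sessions

    @property
    def stimuli_per_criterion(self) -> int:
        # one stimulus is shown once per condition
        return self.trials_per_cell


_LAYOUTS = {
    "exp1": ExperimentLayout(
        "exp1", 4, 384, (Condition.SFORS, Condition.OFORO), decision_time_limit=8.0
    ),
    "exp2": ExperimentLayout(
        "exp2", 6, 216, (Condition.SFORS, Condition.OFORO), decision_time_limit=6.0
    ),
    # trial counts for the crossed design are not fixed by the two-condition
    # experiments; the default keeps exp2's 36 trials per cell over 4 conditions
    "exp3": ExperimentLayout(
        "exp3",
        6,
        432,
        (Condition.SFORS, Condition.SFORO, Condition.OFORS, Condition.OFORO),
        decision_time_limit=6.0,
    ),
}


def experiment_layout(name: str) -> ExperimentLayout:
    """Return the standard layout for ``exp1``, ``exp2`` or ``exp3``."""
    try:
        return _LAYOUTS[name]
    except KeyError:
        raise ValueError(f"unknown experiment {name!r}; expected one of {sorted(_LAYOUTS)}")


@dataclass(frozen=True)
class PerformanceConfig:
    """Generator knobs for the displayed performances and pots.

    Performances are drawn from ``performance_grid`` (default 0..20, the 20
    judgments shown per trial); thresholds for the two goal criteria from
    ``thresholds``; pots for goal criteria from ``pots`` (yen).  Simple-trial
    pots equal ``unit_value * (p1 + p2)``.  ``loss_fraction`` of each
    criterion's stimuli are flagged as loss trials (negative pot) and are
    excluded from all analyses.
    """

    performance_grid: tuple[int, ...] = tuple(range(0, 21))
    thresholds: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    pots: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0)
    unit_value: float = 1.0
    loss_fraction: float = 0.2
    max_tries: int = 500


@dataclass(frozen=True)
class StimulusList:
    """All trials of one participant-independent stimulus set."""

    layout: ExperimentLayout
    trials: tuple[TrialSpec, ...]

    def to_frame(self) -> pd.DataFrame:
        return trials_to_frame(self.trials)

    def reward_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if not t.is_loss)

    def validate(self) -> None:
        """Check the symmetry and matching invariants; raise on violation."""
        df = self.to_frame()
        if len(df) != self.layout.total_trials:
            raise ValueError("wrong trial count")
        rew = df[~df.is_loss]
        r = rew.p1 / (rew.p1 + rew.p2)
        if abs(float(r.mean()) - 0.5) > 1e-12:
            raise ValueError("mean relative performance of reward trials is not 0.5")
        # identical (p1, p2, threshold, pot) for a stimulus across conditions
        per_stim = df.groupby("stimulus_id")[["p1", "p2", "threshold", "pot", "is_loss"]]
        if (per_stim.nunique() != 1).any().any():
            raise ValueError("stimulus content differs across conditions")
        if (df.groupby("stimulus_id").size() != len(self.layout.conditions)).any():
            raise ValueError("each stimulus must appear once per condition")


def _sample_goal_pair(rng, cfg: PerformanceConfig, criterion: Criterion) -> tuple[int, int, int]:
    """Draw (p1, p2, threshold) for a goal criterion, conditioned on winning."""
    grid = np.asarray(cfg.performance_grid)
    for _ in range(cfg.max_tries):
        p1, p2 = rng.choice(grid, 2, replace=True)
        t = int(rng.choice(cfg.thresholds))
        if criterion is Criterion.ADDITIVE and p1 + p2 >= t:
            return int(p1), int(p2), t
        if criterion is Criterion.DISJUNCTIVE and max(p1, p2) >= t:
            return int(p1), int(p2), t
    raise ValueError(f"could not sample a winning {criterion.value} trial; config infeasible")


def _criterion_stimuli(rng, cfg: PerformanceConfig, criterion: Criterion, n_stim: int):
    """Mirrored stimulus descriptors [(p1, p2, threshold, pot, is_loss), ...]."""
    if n_stim % 2:
        raise ValueError(
            f"{n_stim} stimuli per criterion cannot be mirrored into player-symmetric pairs"
        )
    n_pairs = n_stim // 2
    n_loss_pairs = round(cfg.loss_fraction * n_pairs)
    for _ in range(cfg.max_tries):
        stims = []
        loss_flags = np.zeros(n_pairs, bool)
        loss_flags[:n_loss_pairs] = True
        rng.shuffle(loss_flags)
        for k in range(n_pairs):
            if criterion is Criterion.SIMPLE:
                grid = np.asarray(cfg.performance_grid)
                p1, p2 = 0, 0
                while p1 + p2 == 0:
                    p1, p2 = (int(x) for x in rng.choice(grid, 2, replace=True))
                t = 0
                pot = cfg.unit_value * (p1 + p2)
            else:
                p1, p2, t = _sample_goal_pair(rng, cfg, criterion)
                pot = float(rng.choice(cfg.pots))
            is_loss = bool(loss_flags[k])
            if is_loss:
                pot = -abs(pot)
            stims.append((p1, p2, t, pot, is_loss))
            stims.append((p2, p1, t, pot, is_loss))  # mirrored partner
        if criterion is Criterion.SIMPLE:
            return stims
        cats = {
            contribution_category(
                TrialSpec(criterion, p1, p2, threshold=t, pot=abs(pot))
            )
            for p1, p2, t, pot, is_loss in stims
            if not is_loss
        }
        if cats == set(ContributionStructure):
            return stims
    raise ValueError(
        f"could not cover all three contribution structures for {criterion.value};"
        " widen the performance or threshold grids"
    )


def generate_stimulus_list(
    layout: ExperimentLayout,
    perf_config: Optional[PerformanceConfig] = None,
    seed: int = 0,
) -> StimulusList:
    """Generate the symmetric stimulus set shown in every condition.

    Deterministic given the seed.  Reward trials of the two goal criteria
    span all three contribution structures.
    """
    cfg = perf_config or PerformanceConfig()
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for criterion in layout.criteria:
        stims = _criterion_stimuli(rng, cfg, criterion, layout.stimuli_per_criterion)
        for k, (p1, p2, t, pot, is_loss) in enumerate(stims):
            stim_id = f"{layout.experiment}-{criterion.value}-{k:03d}"
            for cond in layout.conditions:
                trials.append(
                    TrialSpec(
                        criterion=criterion,
                        p1=p1,
                        p2=p2,
                        threshold=t,
                        pot=pot,
                        condition=cond,
                        trial_id=f"{stim_id}-{cond.value}",
                        stimulus_id=stim_id,
                        is_loss=is_loss,
                    )
                )
    out = StimulusList(layout, tuple(trials))
    out.validate()
    return out


def assign_blocks(
    layout: ExperimentLayout, stimuli: StimulusList, seed: int = 0
) -> pd.DataFrame:
    """Order trials into sessions of alternating (condition x criterion) blocks.

    Every cell contributes one mini-block per session; block order within a
    session and trial order within a block are permuted by the seed, so the
    cell counts are seed-invariant.  Returns one row per presented trial with
    ``session``, ``block``, ``block_label`` and position columns.
    """
    rng = np.random.default_rng(seed)
    cells = [(cond, crit) for cond in layout.conditions for crit in layout.criteria]
    per_block = layout.trials_per_cell // layout.n_sessions
    if per_block * layout.n_sessions != layout.trials_per_cell:
        raise ValueError(
            f"{layout.trials_per_cell} trials per cell do not divide into "
            f"{layout.n_sessions} equal session blocks"
        )
    by_cell: dict[tuple, list[TrialSpec]] = {c: [] for c in cells}
    for t in stimuli.trials:
        by_cell[(t.condition, t.criterion)].append(t)
    for cell, ts in by_cell.items():
        if len(ts) != layout.trials_per_cell:
            raise ValueError(f"cell {cell} holds {len(ts)} trials, expected {layout.trials_per_cell}")
        rng.shuffle(ts)

    rows = []
    for session in range(layout.n_sessions):
        order = list(rng.permutation(len(cells)))
        for b, cell_idx in enumerate(order):
            cond, crit = cells[cell_idx]
            block_trials = by_cell[(cond, crit)][session * per_block : (session + 1) * per_block]
            for pos, t in enumerate(block_trials):
                rows.append(
                    {
                        "session": session + 1,
                        "block": b + 1,
                        "block_label": f"{INSTRUCTION_LABELS[crit]} | {cond.value}",
                        "trial_in_block": pos + 1,
                        **_trial_row(t),
                    }
                )
    return pd.DataFrame(rows)


def _trial_row(t: TrialSpec) -> dict:
    return {
        "trial_id": t.trial_id,
        "stimulus_id": t.stimulus_id,
        "condition": t.condition.value,
        "criterion": t.criterion.value,
        "p1": t.p1,
        "p2": t.p2,
        "threshold": t.threshold,
        "pot": float(t.pot),
        "is_loss": t.is_loss,
    }


def trials_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Tidy DataFrame representation (one row per trial)."""
    return pd.DataFrame([_trial_row(t) for t in trials])


def trials_from_frame(df: pd.DataFrame, layout: Optional[ExperimentLayout] = None):
    """Rebuild TrialSpec objects from a trial table (CSV round-trip)."""
    trials = tuple(
        TrialSpec(
            criterion=row.criterion,
            p1=int(row.p1),
            p2=int(row.p2),
            threshold=int(row.threshold),
            pot=row.pot,
            condition=row.condition,
            trial_id=row.trial_id,
            stimulus_id=row.stimulus_id,
            is_loss=bool(row.is_loss),
        )
        for row in df.itertuples()
    )
    if layout is not None:
        return StimulusList(layout, trials)
    return trials


def annotate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Add contribution_category, shapley_ratio and relative_performance.

    Loss trials get NA in the derived columns; reward trials are scored by
    the coalition-game machinery.
    """
    df = df.copy()
    cats, ratios, relperf = [], [], []
    for row in df.itertuples():
        if row.is_loss:
            cats.append(pd.NA)
            ratios.append(np.nan)
            relperf.append(np.nan)
            continue
        t = TrialSpec(
            criterion=row.criterion,
            p1=int(row.p1),
            p2=int(row.p2),
            threshold=int(row.threshold),
            pot=row.pot,
            condition=row.condition,
        )
        cats.append(contribution_category(t).value)
        ratios.append(float(shapley_ratio(t)))
        total = row.p1 + row.p2
        relperf.append(row.p1 / total if total else np.nan)
    df["contribution_category"] = cats
    df["shapley_ratio"] = ratios
    df["relative_performance"] = relperf
    return df
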