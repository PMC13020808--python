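"""Two-player coalition games induced by collective task criteria.

A trial of the allocation task shows two players' performances (counts of
correct prime-number judgments), a task criterion, a threshold, and the pot
won by the pair.  Each reward trial induces a monotone two-player coalition
game whose characteristic function says what every coalition would have
earned on its own; the Shapley value of that game is the performance-based
benchmark for splitting the pot.

Three criteria are supported:

``simple``
    No threshold: the pot scales with the total number of correct
    responses (``unit_value`` yen per correct response).
``additive``
    The pot is won iff the *sum* of the two performances reaches the
    threshold.
``disjunctive``
    The pot is won iff at least one player alone reaches the threshold.

Money is carried as :class:`fractions.Fraction` (exact to the 0.01 yen the
slider can express) so that Shapley efficiency holds exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Union

__all__ = [
    "Criterion",
    "Condition",
    "TrialSpec",
    "CoalitionGame",
    "ContributionStructure",
    "LossTrialError",
    "joint_outcome",
    "characteristic_function",
    "shapley_values",
    "shapley_ratio",
    "contribution_category",
]

Money = Union[int, float, Fraction]


class Criterion(str, enum.Enum):
    """Collective task criterion mapping performances to a joint outcome."""

    SIMPLE = "simple"
    ADDITIVE = "additive"
    DISJUNCTIVE = "disjunctive"


class Condition(str, enum.Enum):
    """Who produced the performance (source) x who receives the pot (recipient).

    ``SforS``/``OforO`` are the self-relevant/self-irrelevant conditions of
    the two-condition experiments; the crossed ``SforO``/``OforS`` cells
    separate source from recipient.
    """

    SFORS = "SforS"
    SFORO = "SforO"
    OFORS = "OforS"
    OFORO = "OforO"

    @property
    def recipient_is_self(self) -> bool:
        return self in (Condition.SFORS, Condition.OFORS)

    @property
    def source_is_self(self) -> bool:
        return self in (Condition.SFORS, Condition.SFORO)


class ContributionStructure(str, enum.Enum):
    """Which player(s) are causally necessary for the reward."""

    PLAYER1_ONLY = "player1_only"
    BOTH = "both"
    PLAYER2_ONLY = "player2_only"


class LossTrialError(ValueError):
    """Raised when a coalition game is requested for a loss trial."""


def as_money(x: Money) -> Fraction:
    """Convert a money amount to an exact Fraction with 0.01 resolution."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    cents = round(x * 100)
    if abs(x * 100 - cents) > 1e-6:
        raise ValueError(f"money amount {x!r} is not expressible in 0.01 units")
    return Fraction(cents, 100)


@dataclass(frozen=True)
class TrialSpec:
    """One allocation trial as shown to the participant."""

    criterion: Criterion
    p1: int
    p2: int
    threshold: int = 0
    pot: Money = 10
    condition: Condition = Condition.SFORS
    trial_id: str = ""
    stimulus_id: str = ""
    is_loss: bool = False
    judgments_per_trial: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.p1 < 0 or self.p2 < 0:
            raise ValueError("performances must be non-negative")
        if self.p1 > self.judgments_per_trial or self.p2 > self.judgments_per_trial:
            raise ValueError(
                f"performance exceeds the {self.judgments_per_trial} judgments shown per trial"
            )
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        pot = as_money(self.pot)
        if not self.is_loss and pot <= 0:
            raise ValueError("reward trials require pot > 0")
        object.__setattr__(self, "pot", pot)


@dataclass(frozen=True)
class CoalitionGame:
    """Characteristic function of a monotone two-player game, v(empty) = 0."""

    v_p1: Fraction
    v_p2: Fraction
    v_both: Fraction
    v_empty: Fraction = field(default=Fraction(0))

    def __post_init__(self) -> None:
        for name in ("v_p1", "v_p2", "v_both", "v_empty"):
            object.__setattr__(self, name, as_money(getattr(self, name)))
        if self.v_empty != 0:
            raise ValueError("v(empty) must be 0")
        if not (0 <= self.v_p1 <= self.v_both and 0 <= self.v_p2 <= self.v_both):
            raise ValueError(
                f"non-monotone game: v_p1={self.v_p1}, v_p2={self.v_p2}, v_both={self.v_both}"
            )


def joint_outcome(trial: TrialSpec) -> Fraction:
    """Pot earned by the pair on a trial under its criterion.

    Thresholds are inclusive: the goal is met when the relevant performance
    quantity is >= the threshold.  For the simple criterion the pot itself
    encodes the per-response value, so the pot is always awarded.
    """
    if trial.criterion is Criterion.SIMPLE:
        return trial.pot
    if trial.criterion is Criterion.ADDITIVE:
        return trial.pot if trial.p1 + trial.p2 >= trial.threshold else Fraction(0)
    return trial.pot if max(trial.p1, trial.p2) >= trial.threshold else Fraction(0)


def characteristic_function(trial: TrialSpec) -> CoalitionGame:
    """Coalition game of a reward trial: what each coalition earns alone.

    For the simple criterion the pot is proportional to the total number of
    correct responses, so singleton coalitions earn their proportional share
    ``pot * p_i / (p1 + p2)``.
    """
    if trial.is_loss:
        raise LossTrialError("loss trials do not define a coalition game")
    pot = trial.pot
    if trial.criterion is Criterion.SIMPLE:
        total = trial.p1 + trial.p2
        if total == 0:
            raise ValueError("simple trial with zero total performance has no game")
        unit = pot / total
        return CoalitionGame(v_p1=unit * trial.p1, v_p2=unit * trial.p2, v_both=pot)
    if trial.criterion is Criterion.ADDITIVE:
        v1 = pot if trial.p1 >= trial.threshold else Fraction(0)
        v2 = pot if trial.p2 >= trial.threshold else Fraction(0)
    else:  # disjunctive: a singleton wins iff that player alone reaches it
        v1 = pot if trial.p1 >= trial.threshold else Fraction(0)
        v2 = pot if trial.p2 >= trial.threshold else Fraction(0)
    v_both = joint_outcome(trial)
    if v_both == 0:
        raise ValueError("trial does not reach its goal; no reward to divide")
    return CoalitionGame(v_p1=v1, v_p2=v2, v_both=v_both)


def shapley_values(game: CoalitionGame) -> tuple[Fraction, Fraction]:
    """Shapley pair (phi1, phi2): average marginal contributions over orderings.

    For two players this is the closed form
    phi1 = (v({1}) + v({1,2}) - v({2})) / 2, and symmetrically for phi2;
    efficiency phi1 + phi2 = v({1,2}) holds exactly.
    """
    phi1 = (game.v_p1 + game.v_both - game.v_p2) / 2
    phi2 = (game.v_p2 + game.v_both - game.v_p1) / 2
    return phi1, phi2


def shapley_ratio(trial: TrialSpec) -> Fraction:
    """Player 1's Shapley share of the joint outcome, in [0, 1].

    For threshold (additive/disjunctive) games the ratio is one of
    {0, 1/2, 1}; for simple games it equals player 1's relative
    performance under the proportional characteristic function.
    """
    game = characteristic_function(trial)
    phi1, phi2 = shapley_values(game)
    total = phi1 + phi2
    if total == 0:
        raise ValueError("zero total Shapley value")
    return phi1 / total


def contribution_category(trial: TrialSpec) -> ContributionStructure:
    """Classify a reward trial by which player(s) the reward depends on.

    Simple trials are always ``both`` (there is no threshold to reach);
    threshold trials map through the Shapley ratio {1, 1/2, 0} to
    player1_only / both / player2_only.
    """
    if trial.is_loss:
        raise LossTrialError("loss trials have no contribution structure")
    if trial.criterion is Criterion.SIMPLE:
        return ContributionStructure.BOTH
    ratio = shapley_ratio(trial)
    if ratio == 1:
        return ContributionStructure.PLAYER1_ONLY
    if ratio == 0:
        return ContributionStructure.PLAYER2_ONLY
    if ratio == Fraction(1, 2):
        return ContributionStructure.BOTH
    raise RuntimeError(  # unreachable for two-player threshold games
        f"Shapley ratio {ratio} outside {{0, 1/2, 1}} for a threshold game"
    )
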