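"""Derived behavioral quantities: relative shares, trial-matched self-allocation
bias, SVO slider scoring, and descriptive condition summaries.

The central outcome of the allocation task is *relative allocation*, player
1's share of the allocated pot; its benchmark under symmetric performance is
0.5.  The *self-allocation bias* is the trial-wise difference in relative
allocation between a self-relevant trial and the matched self-irrelevant
trial showing the same stimulus.  Social value orientation (SVO) is scored
from the slider measure's six primary items as the angle
``atan2(mean_other - 50, mean_self - 50)`` in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .games import Condition

__all__ = [
    "relative_allocation",
    "relative_performance",
    "self_allocation_bias",
    "svo_angle",
    "svo_category",
    "condition_summary",
    "SVO_PRIMARY_ITEMS",
    "SVOResponse",
]

# ---------------------------------------------------------------------------
# SVO slider measure, six primary items (nine payoff options each).
# Payoff vectors from the published slider instrument; option payoffs are
# (self, other) points.  Version: 6-item primary slider, v1.
SVO_PRIMARY_ITEMS: tuple[tuple[tuple[int, int], ...], ...] = (
    tuple(zip((85, 85, 85, 85, 85, 85, 85, 85, 85), (85, 76, 68, 59, 50, 41, 33, 24, 15))),
    tuple(zip((85, 87, 89, 91, 93, 94, 96, 98, 100), (15, 19, 24, 28, 33, 37, 41, 46, 50))),
    tuple(zip((50, 54, 59, 63, 68, 72, 76, 81, 85), (100, 98, 96, 94, 93, 91, 89, 87, 85))),
    tuple(zip((50, 54, 59, 63, 68, 72, 76, 81, 85), (100, 89, 79, 68, 58, 47, 36, 26, 15))),
    tuple(zip((100, 94, 88, 81, 75, 69, 63, 56, 50), (50, 56, 63, 69, 75, 81, 88, 94, 100))),
    tuple(zip((100, 98, 96, 94, 93, 91, 89, 87, 85), (50, 54, 59, 63, 68, 72, 76, 81, 85))),
)

#: Angle boundaries (degrees) of the four SVO categories.
SVO_CATEGORY_BOUNDS = (-12.04, 22.45, 57.15)


@dataclass(frozen=True)
class SVOResponse:
    """Chosen (self, other) payoff pair for each of the six primary items."""

    choices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.choices) != 6:
            raise ValueError("the primary SVO score uses exactly 6 items")

    @classmethod
    def from_option_indices(cls, indices: Sequence[int]) -> "SVOResponse":
        """Build a response from option indices (0..8) into the slider items."""
        if len(indices) != 6:
            raise ValueError("need one option index per primary item")
        return cls(tuple(SVO_PRIMARY_ITEMS[i][k] for i, k in enumerate(indices)))


def svo_angle(resp: SVOResponse) -> float:
    """SVO angle in degrees from the six primary slider items.

    The angle is ``atan2(mean_other - 50, mean_self - 50)``: 0 deg is a pure
    own-payoff maximizer, 45 deg weighs self and other equally.  atan2 keeps
    the score defined when mean_self equals the 50-point origin.
    """
    mean_self = float(np.mean([c[0] for c in resp.choices]))
    mean_other = float(np.mean([c[1] for c in resp.choices]))
    return math.degrees(math.atan2(mean_other - 50.0, mean_self - 50.0))


def svo_category(angle: float) -> str:
    """Map an SVO angle to altruistic/prosocial/individualistic/competitive."""
    lo, mid, hi = SVO_CATEGORY_BOUNDS
    if angle > hi:
        return "altruistic"
    if angle > mid:
        return "prosocial"
    if angle > lo:
        return "individualistic"
    return "competitive"


# ---------------------------------------------------------------------------


def relative_allocation(a1: float, a2: float) -> float:
    """Player 1's share of the allocated money, a1 / (a1 + a2)."""
    if a1 < 0 or a2 < 0:
        raise ValueError("allocations must be non-negative")
    total = a1 + a2
    if total <= 0:
        raise ValueError("zero total allocation; loss/miss trials are excluded upstream")
    return a1 / total


def relative_performance(p1: float, p2: float) -> float:
    """Player 1's share of the total correct responses, p1 / (p1 + p2)."""
    if p1 < 0 or p2 < 0:
        raise ValueError("performances must be non-negative")
    total = p1 + p2
    if total <= 0:
        raise ValueError("both performances zero; trial must be excluded")
    return p1 / total


def self_allocation_bias(
    records: pd.DataFrame,
    self_condition: str = Condition.SFORS.value,
    other_condition: str = Condition.OFORO.value,
) -> tuple[pd.DataFrame, int]:
    """Trial-matched self-allocation bias table.

    For every participant and stimulus present in both the self-relevant and
    the matched self-irrelevant condition, the bias is the difference of the
    two relative allocations.  For the four-condition (crossed) design pass
    the condition pair explicitly — e.g. ``("SforS", "SforO")`` for a
    recipient difference at fixed source, or ``("SforS", "OforS")`` for a
    source difference at fixed recipient; the default pair is the classic
    self-relevant minus self-irrelevant contrast.

    Returns ``(bias_table, n_unmatched)`` where ``n_unmatched`` counts the
    (participant, stimulus) pairs dropped because one side was missing.
    """
    needed = {"participant_id", "stimulus_id", "condition", "relative_allocation"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    keep = ["participant_id", "stimulus_id", "relative_allocation"]
    extra = [c for c in ("contribution_category", "criterion", "svo_angle", "svo_z") if c in records]
    a = records.loc[records.condition == self_condition, keep + extra]
    b = records.loc[records.condition == other_condition, keep]
    merged = a.merge(
        b, on=["participant_id", "stimulus_id"], how="outer",
        suffixes=("_self", "_other"), indicator=True,
    )
    n_unmatched = int((merged["_merge"] != "both").sum())
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged["bias"] = merged.relative_allocation_self - merged.relative_allocation_other
    return merged.reset_index(drop=True), n_unmatched


def condition_summary(records: pd.DataFrame, by: Iterable[str] = ("condition", "criterion")) -> pd.DataFrame:
    """Group means of relative allocation: participants first, then the group.

    Each participant contributes one mean per cell; the group mean and its
    SEM are computed over those participant means (the descriptive view used
    for plotting — inference comes from the hierarchical model, not from
    this table).
    """
    by = list(by)
    per_part = (
        records.groupby(by + ["participant_id"], observed=True)["relative_allocation"]
        .mean()
        .reset_index()
    )
    out = (
        per_part.groupby(by, observed=True)["relative_allocation"]
        .agg(mean="mean", sd="std", n_participants="count")
        .reset_index()
    )
    out["sem"] = out.sd / np.sqrt(out.n_participants)
    return out
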