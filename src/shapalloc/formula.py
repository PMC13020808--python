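"""Minimal mixed-model formula grammar: fixed effects + one random intercept.

Accepts Wilkinson-style formulas with main effects, ``*`` / ``:``
interactions, and exactly one random-intercept term ``(1|group)``, e.g.::

    relative_allocation ~ self_relevance * criterion * svo_z + (1|participant_id)

The fixed part is handed to patsy for design-matrix construction; the
random-intercept group is handled by the hierarchical estimator.
"""

from __future__ import annotations

import re

__all__ = ["parse_mixed_formula", "ParsedFormula"]

_RE_GROUP = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)")
_RE_ALLOWED = re.compile(r"^[A-Za-z0-9_+*:~.\s-]*$")


class ParsedFormula:
    """Response name, patsy fixed-effects formula, and grouping column."""

    def __init__(self, response: str, fixed: str, group: str, raw: str):
        self.response = response
        self.fixed = fixed
        self.group = group
        self.raw = raw

    def __repr__(self) -> str:
        return f"ParsedFormula({self.raw!r})"


def parse_mixed_formula(formula: str) -> ParsedFormula:
    """Split a mixed formula into (response, fixed patsy formula, group)."""
    groups = _RE_GROUP.findall(formula)
    if len(groups) != 1:
        raise ValueError(
            "formula must contain exactly one random-intercept term '(1|group)'"
        )
    fixed_part = _RE_GROUP.sub("", formula)
    # drop dangling '+' left behind by removing the random term
    fixed_part = re.sub(r"\+\s*$", "", fixed_part.strip())
    fixed_part = re.sub(r"\+\s*\+", "+", fixed_part)
    if "(" in fixed_part or ")" in fixed_part:
        raise ValueError(
            "only main effects, '*'/':' interactions and a single '(1|group)' are supported"
        )
    if not _RE_ALLOWED.match(fixed_part):
        raise ValueError(f"unsupported syntax in formula: {formula!r}")
    if fixed_part.count("~") != 1:
        raise ValueError("formula needs exactly one '~'")
    lhs, rhs = (s.strip() for s in fixed_part.split("~"))
    if not lhs:
        raise ValueError("formula needs a response on the left of '~'")
    rhs = rhs.strip()
    if rhs.startswith("+"):
        rhs = rhs[1:].strip()
    if not rhs:
        rhs = "1"
    return ParsedFormula(lhs, f"{lhs} ~ {rhs}", groups[0], formula)
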