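"""Coalition-game scoring: joint outcomes, Shapley values, categorization."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapalloc.games import (
    CoalitionGame,
    ContributionStructure,
    Criterion,
    LossTrialError,
    TrialSpec,
    characteristic_function,
    contribution_category,
    joint_outcome,
    shapley_ratio,
    shapley_values,
)


def shapley_by_orderings(game: CoalitionGame) -> tuple[Fraction, Fraction]:
    """Independent oracle: average marginal contribution over both orderings."""
    # ordering (1, 2): player 1 joins first
    m1_a, m2_a = game.v_p1 - game.v_empty, game.v_both - game.v_p1
    # ordering (2, 1): player 2 joins first
    m2_b, m1_b = game.v_p2 - game.v_empty, game.v_both - game.v_p2
    return (m1_a + m1_b) / 2, (m2_a + m2_b) / 2


class TestJointOutcome:
    @pytest.mark.parametrize(
        "criterion,p1,p2,threshold,expected",
        [
            ("additive", 2, 3, 5, 10),   # the worked example trial: sum meets goal
            ("additive", 2, 2, 5, 0),
            ("disjunctive", 6, 1, 5, 10),
            ("disjunctive", 4, 4, 5, 0),
        ],
    )
    def test_threshold_criteria(self, criterion, p1, p2, threshold, expected):
        t = TrialSpec(criterion, p1, p2, threshold=threshold, pot=10)
        assert joint_outcome(t) == expected

    def test_simple_always_awards_pot(self):
        t = TrialSpec("simple", 4, 4, pot=8)
        assert joint_outcome(t) == 8

    def test_negative_performance_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec("additive", -1, 3, threshold=5, pot=10)

    def test_nonpositive_pot_rejected_for_reward_trials(self):
        with pytest.raises(ValueError):
            TrialSpec("additive", 2, 3, threshold=5, pot=0)


class TestCharacteristicFunction:
    def test_both_needed(self):
        g = characteristic_function(TrialSpec("additive", 2, 3, threshold=5, pot=10))
        assert (g.v_p1, g.v_p2, g.v_both) == (0, 0, 10)

    def test_player1_alone_sufficient(self):
        g = characteristic_function(TrialSpec("additive", 6, 1, threshold=5, pot=10))
        assert (g.v_p1, g.v_p2, g.v_both) == (10, 0, 10)

    def test_disjunctive_both_exceed(self):
        g = characteristic_function(TrialSpec("disjunctive", 6, 7, threshold=5, pot=10))
        assert (g.v_p1, g.v_p2, g.v_both) == (10, 10, 10)

    def test_loss_trial_has_no_game(self):
        t = TrialSpec("additive", 2, 3, threshold=5, pot=-10, is_loss=True)
        with pytest.raises(LossTrialError):
            characteristic_function(t)

    def test_non_monotone_game_rejected(self):
        with pytest.raises(ValueError):
            CoalitionGame(v_p1=12, v_p2=0, v_both=10)


class TestShapley:
    @pytest.mark.parametrize(
        "game,expected",
        [
            ((0, 0, 10), (5, 5)),
            ((10, 0, 10), (10, 0)),
            ((10, 10, 10), (5, 5)),
        ],
    )
    def test_closed_form(self, game, expected):
        phi = shapley_values(CoalitionGame(*game))
        assert phi == expected

    @given(
        v1=st.integers(0, 1000), v2=st.integers(0, 1000), extra=st.integers(0, 1000)
    )
    @settings(max_examples=200, derandomize=True)
    def test_axioms_on_random_monotone_games(self, v1, v2, extra):
        vb = max(v1, v2) + extra
        game = CoalitionGame(
            v_p1=Fraction(v1, 100), v_p2=Fraction(v2, 100), v_both=Fraction(vb, 100)
        )
        phi1, phi2 = shapley_values(game)
        # efficiency (exact rational arithmetic)
        assert phi1 + phi2 == game.v_both
        # symmetry under relabelling
        swapped = CoalitionGame(v_p1=game.v_p2, v_p2=game.v_p1, v_both=game.v_both)
        assert shapley_values(swapped) == (phi2, phi1)
        # dummy player
        if game.v_p2 == 0 and game.v_both == game.v_p1:
            assert phi2 == 0
        # permutation-enumeration oracle
        assert (phi1, phi2) == shapley_by_orderings(game)


class TestCategorization:
    @pytest.mark.parametrize(
        "criterion,p1,p2,threshold,expected",
        [
            ("simple", 3, 9, 0, "both"),
            ("additive", 2, 3, 5, "both"),
            ("additive", 6, 1, 5, "player1_only"),
            ("additive", 1, 6, 5, "player2_only"),
            ("disjunctive", 6, 3, 5, "player1_only"),
            ("disjunctive", 1, 6, 5, "player2_only"),
            ("disjunctive", 6, 7, 5, "both"),
        ],
    )
    def test_examples(self, criterion, p1, p2, threshold, expected):
        t = TrialSpec(criterion, p1, p2, threshold=threshold, pot=10)
        assert contribution_category(t).value == expected

    @pytest.mark.parametrize("criterion", ["additive", "disjunctive"])
    @pytest.mark.parametrize("threshold", [3, 5, 8])
    def test_partition_of_the_performance_grid(self, criterion, threshold):
        """Every winning (p1, p2) cell maps to exactly one category and the
        category matches the Shapley ratio {1, 1/2, 0}."""
        ratio_of = {"player1_only": 1, "both": Fraction(1, 2), "player2_only": 0}
        seen = set()
        for p1 in range(0, 21):
            for p2 in range(0, 21):
                t = TrialSpec(criterion, p1, p2, threshold=threshold, pot=10)
                if joint_outcome(t) == 0:
                    continue
                cat = contribution_category(t)
                seen.add(cat)
                assert shapley_ratio(t) == ratio_of[cat.value]
                # symmetry: swapping players mirrors the category
                mirrored = contribution_category(
                    TrialSpec(criterion, p2, p1, threshold=threshold, pot=10)
                )
                flip = {
                    "player1_only": "player2_only",
                    "player2_only": "player1_only",
                    "both": "both",
                }
                assert mirrored.value == flip[cat.value]
        assert seen == set(ContributionStructure)

    def test_simple_ratio_equals_relative_performance(self):
        t = TrialSpec("simple", 4, 4, pot=8)
        assert shapley_ratio(t) == Fraction(1, 2)
        t = TrialSpec("simple", 2, 6, pot=8)
        assert shapley_ratio(t) == Fraction(1, 4)
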