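import numpy as np
import pytest

from pufval.puf import (
    dimension_weights,
    level_decrements,
    puf_from_responses,
    rank_all_states,
    state_utility,
    uniform_puf,
)
from pufval.responses import LevelAllocations, SwingRatings
from pufval.state_space import DIMENSIONS, dominates, enumerate_states, parse_state

MO, SC, UA, PD, AD = DIMENSIONS


def swing(*vals):
    return SwingRatings(rating=dict(zip(DIMENSIONS, vals)))


def alloc(*vals):
    return LevelAllocations(points_intermediate=dict(zip(DIMENSIONS, vals)))


# ---------------------------------------------------------------------------
# weights

def test_equal_ratings_give_equal_weights():
    w = dimension_weights(swing(100, 100, 100, 100, 100))
    assert all(w[d] == pytest.approx(0.2) for d in DIMENSIONS)


def test_single_positive_rating_concentrates_weight():
    w = dimension_weights(swing(100, 0, 0, 0, 0))
    assert w[MO] == 1.0
    assert all(w[d] == 0.0 for d in DIMENSIONS[1:])


def test_weights_are_proportional_ratings():
    # ratings sum to 432; weights are each rating / 432
    w = dimension_weights(swing(100, 80, 80, 90, 82))
    assert w[MO] == pytest.approx(100 / 432)
    assert w[SC] == pytest.approx(80 / 432)
    assert w[PD] == pytest.approx(90 / 432)
    assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)


def test_weights_need_no_100_rating():
    # proportional normalisation also applies when the top rating is 90
    w = dimension_weights(swing(90, 45, 45, 45, 45))
    assert w[MO] == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# level-2 decrements and the two mapping conventions

def test_allocation_of_50_is_convention_invariant():
    w = {d: 0.2 for d in DIMENSIONS}
    for conv in ("share_of_swing", "remaining_badness"):
        puf = level_decrements(w, alloc(50, 50, 50, 50, 50), conv)
        assert all(puf.decrement2[d] == pytest.approx(0.1) for d in DIMENSIONS)


def test_allocation_endpoints_differ_between_conventions():
    w = {d: 0.2 for d in DIMENSIONS}
    hundreds = alloc(100, 100, 100, 100, 100)
    assert level_decrements(w, hundreds, "share_of_swing").decrement2[MO] == pytest.approx(0.2)
    assert level_decrements(w, hundreds, "remaining_badness").decrement2[MO] == pytest.approx(0.0)
    zeros = alloc(0, 0, 0, 0, 0)
    assert level_decrements(w, zeros, "share_of_swing").decrement2[MO] == 0.0


def test_unknown_convention_rejected():
    with pytest.raises(ValueError, match="unknown level-2 mapping"):
        level_decrements({d: 0.2 for d in DIMENSIONS}, alloc(50, 50, 50, 50, 50), "nope")


def test_puf_invariants_hold_for_random_inputs(random_pufs):
    for puf in random_pufs:
        assert sum(puf.weight.values()) == pytest.approx(1.0, abs=1e-9)
        for d in DIMENSIONS:
            assert 0 <= puf.decrement2[d] <= puf.decrement3[d] + 1e-12
            assert puf.decrement3[d] == puf.weight[d]


# ---------------------------------------------------------------------------
# state utilities

def test_utility_endpoints(random_pufs):
    for puf in random_pufs:
        assert state_utility(puf, parse_state("11111")) == pytest.approx(1.0)
        assert state_utility(puf, parse_state("33333")) == pytest.approx(0.0, abs=1e-12)


def test_single_level2_decrement():
    puf = uniform_puf()
    assert state_utility(puf, parse_state("21111")) == pytest.approx(0.9)


def test_utility_monotone_in_single_dimension_worsening(random_pufs):
    states = enumerate_states()
    for puf in random_pufs[:5]:
        for s in states:
            for i, d in enumerate(DIMENSIONS):
                if s.levels[i] < 3:
                    worse = s.with_level(d, s.levels[i] + 1)
                    assert state_utility(puf, worse) <= state_utility(puf, s) + 1e-12


def test_dominance_implies_utility_order(random_pufs):
    states = enumerate_states()
    rng = np.random.default_rng(3)
    pairs = rng.integers(0, 243, size=(500, 2))
    for puf in random_pufs[:5]:
        for i, j in pairs:
            a, b = states[i], states[j]
            if dominates(a, b):
                assert state_utility(puf, a) >= state_utility(puf, b) - 1e-12


# ---------------------------------------------------------------------------
# ranking

def test_ranking_bounds_for_uniform_puf(equal_puf):
    ranking = rank_all_states(equal_puf)
    assert ranking.state_at(1).code == "11111"
    assert ranking.utility_at(1) == pytest.approx(1.0)
    assert ranking.state_at(243).code == "33333"
    assert ranking.utility_at(243) == pytest.approx(0.0, abs=1e-12)


def test_tied_utilities_break_by_code(equal_puf):
    # under equal weights and p=50, "21111" and "11112" have equal utility;
    # the lexicographically smaller code ranks first
    ranking = rank_all_states(equal_puf)
    pos = {e[1].code: e[0] for e in ranking}
    assert pos["11112"] < pos["21111"]


def test_ranking_matches_brute_force_sort(random_pufs):
    for puf in random_pufs[:5]:
        # independent oracle: direct decrement arithmetic + stable sort
        def u(s):
            total = 1.0
            for i, d in enumerate(DIMENSIONS):
                lv = s.levels[i]
                if lv == 3:
                    total -= puf.weight[d]
                elif lv == 2:
                    total -= puf.weight[d] * puf.level2_fraction[d]
            return total

        expected = sorted(enumerate_states(), key=lambda s: (-u(s), s.code))
        ranking = rank_all_states(puf)
        assert [e[1] for e in ranking] == expected
        assert [e[0] for e in ranking] == list(range(1, 244))


def test_ranking_is_permutation(random_pufs):
    ranking = rank_all_states(random_pufs[0])
    assert {e[1].code for e in ranking} == {s.code for s in enumerate_states()}


def test_puf_from_responses_composes():
    puf = puf_from_responses(swing(100, 80, 80, 90, 82), alloc(50, 50, 50, 50, 50))
    assert puf.weight[MO] == pytest.approx(100 / 432)
    assert puf.decrement2[MO] == pytest.approx(50 / 432)
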