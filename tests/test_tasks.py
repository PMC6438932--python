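import itertools

import pytest

from pufval.puf import puf_from_responses, rank_all_states, state_utility, uniform_puf
from pufval.responses import InteractionRecord
from pufval.state_space import DIMENSIONS, dominates, level_sum_score
from pufval.tasks import (
    bisection_next,
    classify_bracket,
    enumerate_bracket_widths,
    generate_interaction_tasks,
    generate_validation_pairs,
    most_least_important,
    run_dead_search,
    tally_interactions,
)

MO, SC, UA, PD, AD = DIMENSIONS


# ---------------------------------------------------------------------------
# bisection arithmetic

@pytest.mark.parametrize(
    "lower, upper, expected",
    [
        (None, 243, 122),  # opening midpoint: half-way between 1st and 243rd
        (122, 243, 183),   # round-half-up of 182.5
        (None, 122, 62),   # round-half-up of 61.5
        (122, 183, 153),
        (1, 3, 2),
    ],
)
def test_bisection_next_midpoints(lower, upper, expected):
    assert bisection_next(lower, upper) == expected


def test_bisection_exhausted_interval_raises():
    with pytest.raises(ValueError, match="exhausted"):
        bisection_next(10, 11)


def scripted(choices):
    it = iter(choices)
    return lambda state: next(it)


def test_dead_search_worked_example(equal_puf):
    """Death preferred at the worst state, living thereafter: dead lands
    between the 228th and 243rd ranked states."""
    ranking = rank_all_states(equal_puf)
    record, bracket = run_dead_search(ranking, scripted("BAAAA"))
    assert [r for r, _ in record.presented] == [243, 122, 183, 213, 228]
    assert bracket.classification == "bracketed"
    assert (bracket.lower_rank, bracket.upper_rank) == (228, 243)


def test_dead_search_stops_after_first_A(equal_puf):
    ranking = rank_all_states(equal_puf)
    record, bracket = run_dead_search(ranking, scripted("A"))
    assert len(record.choices) == 1
    assert bracket.classification == "below_33333"


def test_dead_search_all_B_records_mildest_rank(equal_puf):
    ranking = rank_all_states(equal_puf)
    record, bracket = run_dead_search(ranking, scripted("BBBBB"))
    assert [r for r, _ in record.presented] == [243, 122, 62, 32, 17]
    assert bracket.classification == "above_mildest"
    assert bracket.upper_rank == 17


def test_all_completed_paths_bracket_15_or_16_states():
    widths = enumerate_bracket_widths()
    assert len(widths) == 16
    for pattern, width in widths.items():
        if pattern == "B" * 5:
            continue  # one-sided: dead above the mildest presented state
        assert width in (15, 16), pattern
    assert max(w for w in widths.values() if w is not None) == 16


def test_search_brackets_straddle_latent_dead_utility(random_pufs):
    for puf in random_pufs[:5]:
        ranking = rank_all_states(puf)
        for u_star in (0.02, 0.1, 0.3, 0.55, 0.9):
            answer = lambda s: "A" if state_utility(puf, s) >= u_star else "B"
            record, bracket = run_dead_search(ranking, answer)
            if bracket.classification == "bracketed":
                assert ranking.utility_at(bracket.upper_rank) <= u_star
                assert ranking.utility_at(bracket.lower_rank) >= u_star


def test_classify_bracket_round_trips_run(equal_puf):
    ranking = rank_all_states(equal_puf)
    record, bracket = run_dead_search(ranking, scripted("BABAB"))
    assert classify_bracket(record) == bracket


# ---------------------------------------------------------------------------
# section E validation pairs

def test_validation_pairs_structure(random_pufs):
    for puf in random_pufs:
        ranking = rank_all_states(puf)
        pair1, pair2 = generate_validation_pairs(ranking)
        for pair in (pair1, pair2):
            assert not dominates(pair.option_a, pair.option_b)
            assert not dominates(pair.option_b, pair.option_a)
            assert (
                state_utility(puf, pair.option_a)
                >= state_utility(puf, pair.option_b) - 1e-12
            )
        assert pair1.task_index == 1 and pair2.task_index == 2
        assert pair1.utility_gap > pair2.utility_gap


def test_hard_pair_has_minimal_gap(random_pufs):
    # oracle: scan every non-dominating adjacent pair for the smallest gap
    for puf in random_pufs[:5]:
        ranking = rank_all_states(puf)
        _, pair2 = generate_validation_pairs(ranking)
        best = min(
            ranking.utility_at(r) - ranking.utility_at(r + 1)
            for r in range(1, 243)
            if not dominates(ranking.state_at(r), ranking.state_at(r + 1))
            and not dominates(ranking.state_at(r + 1), ranking.state_at(r))
        )
        assert pair2.utility_gap == pytest.approx(best, abs=1e-12)


def test_easy_pairs_contrast_severity(realistic_cohort):
    """Across a simulated cohort, most easy pairs put the better option at
    a level-sum score at least three units below the worse option."""
    _, _, records = realistic_cohort
    n_contrast = 0
    for rec in records:
        puf = puf_from_responses(rec.swing, rec.levels)
        pair1, _ = generate_validation_pairs(rank_all_states(puf))
        if level_sum_score(pair1.option_a) <= level_sum_score(pair1.option_b) - 3:
            n_contrast += 1
    assert n_contrast > len(records) / 2


def test_validation_pairs_deterministic(equal_puf):
    ranking = rank_all_states(equal_puf)
    assert generate_validation_pairs(ranking) == generate_validation_pairs(ranking)


# ---------------------------------------------------------------------------
# section G interaction tasks

def test_interaction_tasks_worked_example():
    task1, task2 = generate_interaction_tasks(most=MO, least=AD)
    assert [s.code for s in task1.option_a] == ["31111", "21111"]
    assert [s.code for s in task1.option_b] == ["31112", "21112"]
    assert [s.code for s in task2.option_a] == ["11113", "11112"]
    assert [s.code for s in task2.option_b] == ["21113", "21112"]


def test_interaction_tasks_swap_symmetry():
    fwd = generate_interaction_tasks(most=MO, least=AD)
    rev = generate_interaction_tasks(most=AD, least=MO)
    assert [s.code for s in rev[0].option_a] == ["11113", "11112"]
    assert [s.code for s in rev[0].option_b] == ["21113", "21112"]
    assert [s.code for s in rev[1].option_a] == [s.code for s in fwd[0].option_a]


def test_interaction_tasks_require_distinct_dimensions():
    with pytest.raises(ValueError):
        generate_interaction_tasks(most=MO, least=MO)


def test_most_least_important_tie_breaks():
    ranks = {MO: 1.5, SC: 1.5, UA: 3, PD: 4, AD: 5}
    ratings = {MO: 90, SC: 100, UA: 70, PD: 60, AD: 50}
    most, least = most_least_important(ranks, ratings)
    assert most == SC  # tied on rank, higher rating wins
    assert least == AD


def test_tally_interactions_pilot_style_counts():
    records = (
        [InteractionRecord(task_index=1, choice="A")] * 55
        + [InteractionRecord(task_index=1, choice="B")] * 6
        + [InteractionRecord(task_index=1, choice="I")] * 14
        + [InteractionRecord(task_index=2, choice="A")] * 57
        + [InteractionRecord(task_index=2, choice="B")] * 9
        + [InteractionRecord(task_index=2, choice="I")] * 9
    )
    tally = tally_interactions(records, n_respondents=76)
    t1, t2 = tally[1], tally[2]
    assert t1["count"]["A"] == 55 and t1["count"]["missing"] == 1
    assert t1["percent"]["A"] == pytest.approx(72.4, abs=0.05)
    assert t2["percent"]["A"] == pytest.approx(75.0, abs=0.05)
    assert sum(t1["count"].values()) == 76


def test_tally_interactions_degenerate_inputs():
    empty = tally_interactions([], n_respondents=0)
    assert all(v == 0 for v in empty[1]["count"].values())
    all_ind = tally_interactions(
        [InteractionRecord(task_index=1, choice="I")] * 10, n_respondents=10
    )
    assert all_ind[1]["percent"]["indifferent"] == 100.0
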