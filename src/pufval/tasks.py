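"""Generation of the adaptive interview tasks.

Three task families are tailored to each respondent's estimated utility
ranking of the 243 states:

* two validation pairs — an "easy" pair with a large utility gap and a
  "hard" pair with a minimal gap, neither member dominating the other;
* the five-task bisection search for the personal location of dead, which
  narrows dead to a bracket of 15-16 adjacent-ranked states;
* two interaction tasks contrasting the same one-level improvement with and
  without moderate problems on another dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Optional

from .puf import StateRanking
from .responses import DeadSearchRecord, InteractionRecord
from .state_space import Dimension, FULL_HEALTH, HealthState, dominates

N_TOTAL = 243

Classification = Literal["below_33333", "bracketed", "above_mildest"]


@dataclass(frozen=True)
class GeneratedPair:
    """A validation choice pair; option A has the higher estimated utility."""

    task_index: Literal[1, 2]
    option_a: HealthState
    option_b: HealthState
    utility_gap: float


@dataclass(frozen=True)
class BisectionBracket:
    """Where the search located dead.

    ``lower_rank`` is the better bound (the respondent preferred that state
    to dying, so dead lies below it); ``upper_rank`` the worse bound (dying
    was preferred, so dead lies above it).  ``above_mildest`` records the
    mildest presented rank in ``upper_rank``; ``below_33333`` means dead was
    never preferred to any state.
    """

    classification: Classification
    lower_rank: Optional[int] = None
    upper_rank: Optional[int] = None


@dataclass(frozen=True)
class InteractionTaskPair:
    """Two one-level improvements in the same dimension, differing only in
    the background level of one other dimension."""

    task_index: Literal[1, 2]
    option_a: tuple[HealthState, HealthState]
    option_b: tuple[HealthState, HealthState]


# ---------------------------------------------------------------------------
# Section E: validation pairs

def _non_dominating(a: HealthState, b: HealthState) -> bool:
    return not dominates(a, b) and not dominates(b, a)


def generate_validation_pairs(ranking: StateRanking) -> list[GeneratedPair]:
    """The easy (task 1) and hard (task 2) validation pairs.

    Task 1 starts from the outer decile ranks (25 and 219 of 243) and scans
    outward — widening the rank gap — to the first pair where neither state
    dominates the other; the wide rank separation gives the large utility
    disparity and clear severity contrast the easy task needs.  Task 2
    takes, among non-dominating adjacent-rank pairs, one attaining the
    minimal utility gap, preferring pairs nearest the median rank.  Both
    selections are deterministic.
    """
    lo0 = math.ceil(0.1 * N_TOTAL)  # 25
    hi0 = math.ceil(0.9 * N_TOTAL)  # 219

    pair1 = None
    for k in range(N_TOTAL):
        for i in range(k + 1):
            a_rank, b_rank = lo0 - i, hi0 + (k - i)
            if a_rank < 1 or b_rank > N_TOTAL:
                continue
            a, b = ranking.state_at(a_rank), ranking.state_at(b_rank)
            if _non_dominating(a, b):
                pair1 = GeneratedPair(
                    1, a, b, ranking.utility_at(a_rank) - ranking.utility_at(b_rank)
                )
                break
        if pair1 is not None:
            break
    assert pair1 is not None  # a non-dominating pair always exists

    # minimal utility gap over all non-dominating adjacent-rank pairs
    gaps = {}
    for r in range(1, N_TOTAL):
        a, b = ranking.state_at(r), ranking.state_at(r + 1)
        if _non_dominating(a, b):
            gaps[r] = ranking.utility_at(r) - ranking.utility_at(r + 1)
    min_gap = min(gaps.values())
    median = math.ceil(N_TOTAL / 2)  # 122
    # scan outward from the median rank: 122, 121, 123, 120, 124, ...
    order = sorted(gaps, key=lambda r: (abs(r - median), r))
    r2 = next(r for r in order if gaps[r] <= min_gap + 1e-12)
    pair2 = GeneratedPair(
        2, ranking.state_at(r2), ranking.state_at(r2 + 1), gaps[r2]
    )
    return [pair1, pair2]


# ---------------------------------------------------------------------------
# Section F: bisection search for the location of dead

def bisection_next(
    lower_rank: Optional[int], upper_rank: int, total: int = N_TOTAL
) -> int:
    """Next rank to present: the round-half-up midpoint of the current
    bounds, with rank 1 standing in when no lower bound is known yet.

    After the opening task at rank ``total`` (the worst state), a 'B'
    (prefer dying) leaves only an upper bound, so the second task sits at
    the midpoint of 1 and ``total`` — rank 122 of 243.
    """
    lo = 1 if lower_rank is None else lower_rank
    if upper_rank - lo < 2:
        raise ValueError(f"search interval ({lo}, {upper_rank}) is exhausted")
    return math.floor((lo + upper_rank) / 2 + 0.5)


def run_dead_search(
    ranking: StateRanking,
    answer_fn: Callable[[HealthState], str],
    n_tasks: int = 5,
) -> tuple[DeadSearchRecord, BisectionBracket]:
    """Run the adaptive search against a respondent (or simulated) oracle.

    The first task presents the worst state (rank 243).  Choosing to live
    there ('A') ends the search — dead lies below every describable state.
    Otherwise exactly ``n_tasks`` choices are collected, each 'A' raising
    the lower bound and each 'B' lowering the upper bound, bisecting the
    rank interval each time.
    """
    presented: list[tuple[int, HealthState]] = []
    choices: list[str] = []

    rank = N_TOTAL
    lower: Optional[int] = None
    upper: Optional[int] = None
    for task in range(n_tasks):
        state = ranking.state_at(rank)
        choice = answer_fn(state)
        if choice not in ("A", "B"):
            raise ValueError(f"answer_fn must return 'A' or 'B', got {choice!r}")
        presented.append((rank, state))
        choices.append(choice)
        if choice == "A":
            lower = rank
        else:
            upper = rank
        if task == 0 and choice == "A":
            break  # nothing is worse than dead for this respondent
        if task < n_tasks - 1:
            rank = bisection_next(lower, upper)

    record = DeadSearchRecord(presented=presented, choices=choices)
    return record, classify_bracket(record)


def classify_bracket(record: DeadSearchRecord) -> BisectionBracket:
    """Reduce a completed search record to its final bracket."""
    lower: Optional[int] = None
    upper: Optional[int] = None
    for (rank, _), choice in zip(record.presented, record.choices):
        if choice == "A":
            lower = rank if lower is None else max(lower, rank)
        else:
            upper = rank if upper is None else min(upper, rank)
    if record.choices[0] == "A":
        return BisectionBracket("below_33333", lower_rank=243)
    if lower is None:
        # never chose to live: dead lies above the mildest presented state
        return BisectionBracket("above_mildest", upper_rank=upper)
    return BisectionBracket("bracketed", lower_rank=lower, upper_rank=upper)


def enumerate_bracket_widths(n_tasks: int = 5) -> dict[str, Optional[int]]:
    """Final upper-minus-lower rank difference for every choice pattern.

    Enumerates all completed search paths (first choice 'B', then every
    combination of the remaining choices).  One-sided outcomes (all 'B')
    map to None.  Used to verify that a full search always pins dead to a
    bracket spanning a rank difference of 15 or 16.
    """
    import itertools

    widths: dict[str, Optional[int]] = {}
    for tail in itertools.product("AB", repeat=n_tasks - 1):
        pattern = "B" + "".join(tail)
        it = iter(pattern)
        # replay against an arbitrary ranking-free rank walk
        lower: Optional[int] = None
        upper: Optional[int] = None
        rank = N_TOTAL
        for task in range(n_tasks):
            c = next(it)
            if c == "A":
                lower = rank
            else:
                upper = rank
            if task < n_tasks - 1:
                rank = bisection_next(lower, upper)
        widths[pattern] = None if lower is None else upper - lower
    return widths


# ---------------------------------------------------------------------------
# Section G: interaction tasks

def generate_interaction_tasks(
    most: Dimension, least: Dimension
) -> list[InteractionTaskPair]:
    """The two interaction pairs for a respondent's most and least
    important dimensions.

    Task 1 contrasts a 3->2 improvement in the most important dimension
    with (A) no problems elsewhere versus (B) moderate problems on the
    least important dimension.  Task 2 contrasts a 3->2 improvement in the
    least important dimension with (A) no problems elsewhere versus (B)
    moderate problems on the most important dimension.
    """
    if most == least:
        raise ValueError("most and least important dimensions must differ")

    def improvement(improved: Dimension, background: Optional[Dimension]):
        frm = FULL_HEALTH.with_level(improved, 3)
        to = FULL_HEALTH.with_level(improved, 2)
        if background is not None:
            frm = frm.with_level(background, 2)
            to = to.with_level(background, 2)
        return frm, to

    return [
        InteractionTaskPair(
            1,
            option_a=improvement(most, None),
            option_b=improvement(most, least),
        ),
        InteractionTaskPair(
            2,
            option_a=improvement(least, None),
            option_b=improvement(least, most),
        ),
    ]


def most_least_important(
    ranks: dict[Dimension, float], ratings: Optional[dict[Dimension, float]] = None
) -> tuple[Dimension, Dimension]:
    """Most and least important dimensions from section B ranks (AVG).

    Ties on rank are broken by the higher (for most) / lower (for least)
    section C rating when available, then by the fixed dimension order.
    """
    dims = list(ranks)
    r = ratings or {d: 0.0 for d in dims}
    most = min(dims, key=lambda d: (ranks[d], -r[d], dims.index(d)))
    least = max(dims, key=lambda d: (ranks[d], -r[d], -dims.index(d)))
    return most, least


def tally_interactions(
    records: Iterable[InteractionRecord], n_respondents: Optional[int] = None
) -> dict[int, dict[str, dict[str, float]]]:
    """Per-task counts and percentages of A / B / indifferent / missing.

    ``n_respondents`` sets the denominator; respondents without a record
    for a task count as missing.  Defaults to the larger per-task record
    count.
    """
    counts = {1: {"A": 0, "B": 0, "I": 0}, 2: {"A": 0, "B": 0, "I": 0}}
    for rec in records:
        counts[rec.task_index][rec.choice] += 1
    per_task_totals = {t: sum(c.values()) for t, c in counts.items()}
    n = n_respondents if n_respondents is not None else max(per_task_totals.values(), default=0)
    out: dict[int, dict[str, dict[str, float]]] = {}
    for t, c in counts.items():
        missing = n - per_task_totals[t]
        full = {"A": c["A"], "B": c["B"], "indifferent": c["I"], "missing": missing}
        out[t] = {
            "count": {k: float(v) for k, v in full.items()},
            "percent": {k: (100.0 * v / n if n else 0.0) for k, v in full.items()},
        }
    return out
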