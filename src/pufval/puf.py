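"""Constructing a respondent's personal utility function (PUF).

The PUF is additive over dimensions.  Starting from a value of 1 for full
health ("11111"), each dimension at its worst level (3) subtracts that
dimension's relative weight w_d, obtained by normalising the section C
swing ratings to sum to 1 — so "33333" is valued exactly 0 on the raw
scale.  Moderate problems (level 2) subtract a configurable fraction of the
full swing, derived from the section D point allocation p_d:

* ``share_of_swing`` (default): delta_{d,2} = w_d * p_d / 100 — the points
  given to the extreme->moderate improvement are read as the share of the
  dimension's swing already recovered at the moderate level.
* ``remaining_badness``: delta_{d,2} = w_d * (1 - p_d / 100) — the literal
  reading of the allocation instruction, under which a large p_d means the
  moderate level retains little of the dimension's badness.

Both conventions coincide at p_d = 50.  Ranking all 243 states by utility
(ties broken by state code) yields the per-respondent ordering that drives
the adaptive tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .responses import LevelAllocations, SwingRatings
from .state_space import (
    DIMENSIONS,
    Dimension,
    HealthState,
    enumerate_states,
)

Level2Mapping = Literal["share_of_swing", "remaining_badness"]

LEVEL2_MAPPINGS: tuple[str, ...] = ("share_of_swing", "remaining_badness")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PersonalUtilityFunction:
    """Per-dimension weights and level decrements on the raw 0-1 scale.

    Invariants: weights sum to 1; delta_{d,3} = w_d; and
    0 <= delta_{d,2} <= delta_{d,3} for every dimension.
    """

    weight: dict[Dimension, float]
    level2_fraction: dict[Dimension, float]
    decrement2: dict[Dimension, float] = field(default_factory=dict)
    decrement3: dict[Dimension, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.weight.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"dimension weights must sum to 1, got {total!r}")
        if not self.decrement3:
            object.__setattr__(self, "decrement3", dict(self.weight))
        if not self.decrement2:
            object.__setattr__(
                self,
                "decrement2",
                {d: self.weight[d] * self.level2_fraction[d] for d in DIMENSIONS},
            )
        for d in DIMENSIONS:
            if not 0 <= self.decrement2[d] <= self.decrement3[d] + _SUM_TOL:
                raise ValueError(
                    f"level-2 decrement for {d.value} outside [0, level-3 decrement]"
                )

    def decrement(self, dim: Dimension, level: int) -> float:
        if level == 1:
            return 0.0
        return self.decrement2[dim] if level == 2 else self.decrement3[dim]

    def utility(self, state: HealthState) -> float:
        return state_utility(self, state)


@dataclass(frozen=True)
class StateRanking:
    """All 243 states ordered best (rank 1, "11111") to worst (rank 243,
    "33333") by a respondent's estimated utility."""

    entries: tuple[tuple[int, HealthState, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 243:
            raise ValueError("a state ranking must cover all 243 states")

    def state_at(self, rank: int) -> HealthState:
        return self.entries[rank - 1][1]

    def utility_at(self, rank: int) -> float:
        return self.entries[rank - 1][2]

    def __iter__(self):
        return iter(self.entries)


def dimension_weights(swing: SwingRatings) -> dict[Dimension, float]:
    """Relative dimension weights: w_d = r_d / sum(r); sums to 1.

    A zero rating yields a zero weight (the dimension never contributes to
    the PUF).  All-zero ratings are rejected at the :class:`SwingRatings`
    level.
    """
    total = sum(swing.rating.values())
    return {d: swing.rating[d] / total for d in DIMENSIONS}


def level_decrements(
    weights: dict[Dimension, float],
    levels: LevelAllocations,
    mapping_convention: Level2Mapping = "share_of_swing",
) -> PersonalUtilityFunction:
    """Build the PUF from dimension weights and section D allocations."""
    if mapping_convention not in LEVEL2_MAPPINGS:
        raise ValueError(
            f"unknown level-2 mapping {mapping_convention!r}; "
            f"expected one of {LEVEL2_MAPPINGS}"
        )
    p = levels.points_intermediate
    if mapping_convention == "share_of_swing":
        frac = {d: p[d] / 100.0 for d in DIMENSIONS}
    else:
        frac = {d: 1.0 - p[d] / 100.0 for d in DIMENSIONS}
    return PersonalUtilityFunction(weight=dict(weights), level2_fraction=frac)


def puf_from_responses(
    swing: SwingRatings,
    levels: LevelAllocations,
    mapping_convention: Level2Mapping = "share_of_swing",
) -> PersonalUtilityFunction:
    """Convenience: sections C + D straight to a PUF."""
    return level_decrements(dimension_weights(swing), levels, mapping_convention)


def state_utility(puf: PersonalUtilityFunction, state: HealthState) -> float:
    """u(s) = 1 - sum of per-dimension decrements at s's levels."""
    return 1.0 - sum(
        puf.decrement(d, state.levels[i]) for i, d in enumerate(DIMENSIONS)
    )


def rank_all_states(puf: PersonalUtilityFunction) -> StateRanking:
    """Rank all 243 states by utility, best first.

    Ties in utility are broken by ascending state code, so the ranking is
    deterministic for any PUF.
    """
    states = enumerate_states()
    ordered = sorted(states, key=lambda s: (-state_utility(puf, s), s.code))
    entries = tuple(
        (rank, s, state_utility(puf, s)) for rank, s in enumerate(ordered, start=1)
    )
    return StateRanking(entries)


def uniform_puf() -> PersonalUtilityFunction:
    """The tool's default PUF: equal weights 0.2, all level-2 fractions 0.5.

    Used when adaptive tasks must be generated without a respondent's own
    section C/D answers.
    """
    return PersonalUtilityFunction(
        weight={d: 0.2 for d in DIMENSIONS},
        level2_fraction={d: 0.5 for d in DIMENSIONS},
    )
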