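"""The simplified 3-level EQ-5D descriptive system.

Five dimensions (mobility, self-care, usual activities, pain/discomfort,
anxiety/depression), each at one of three levels: 1 = no problems,
2 = moderate problems, 3 = extreme problems.  A health state is a 5-digit
code such as ``"21312"`` in the fixed dimension order MO, SC, UA, PD, AD,
giving a state space of 3**5 = 243 states.  ``"11111"`` is full health and
``"33333"`` the worst describable state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator


class Dimension(str, Enum):
    """The five EQ-5D dimensions, in the fixed order used throughout."""

    MO = "MO"  # mobility
    SC = "SC"  # self-care
    UA = "UA"  # usual activities
    PD = "PD"  # pain/discomfort
    AD = "AD"  # anxiety/depression

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Dimension.MO: "Mobility",
    Dimension.SC: "Self-care",
    Dimension.UA: "Usual activities",
    Dimension.PD: "Pain/discomfort",
    Dimension.AD: "Anxiety/depression",
}

#: The five dimensions in their fixed, stable order.
DIMENSIONS: tuple[Dimension, ...] = tuple(Dimension)

LEVELS: tuple[int, ...] = (1, 2, 3)

N_STATES = 3 ** 5  # 243


class StateCodeError(ValueError):
    """Raised when a state code is malformed."""


@dataclass(frozen=True, order=True)
class HealthState:
    """An immutable health state: one level in {1,2,3} per dimension.

    Ordering is lexicographic on the 5-digit code, so sorting states sorts
    their codes.
    """

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 5 or any(l not in (1, 2, 3) for l in self.levels):
            raise StateCodeError(f"levels must be five integers in {{1,2,3}}, got {self.levels!r}")

    @property
    def code(self) -> str:
        """5-character state code, e.g. ``"21312"``."""
        return "".join(str(l) for l in self.levels)

    def level(self, dim: Dimension) -> int:
        return self.levels[DIMENSIONS.index(dim)]

    def with_level(self, dim: Dimension, level: int) -> "HealthState":
        """Copy of this state with one dimension set to ``level``."""
        i = DIMENSIONS.index(dim)
        levels = list(self.levels)
        levels[i] = level
        return HealthState(tuple(levels))

    def __str__(self) -> str:
        return self.code

    def __repr__(self) -> str:
        return f"HealthState({self.code!r})"


FULL_HEALTH = HealthState((1, 1, 1, 1, 1))
WORST_STATE = HealthState((3, 3, 3, 3, 3))


def parse_state(code: str) -> HealthState:
    """Parse a 5-character state code into a :class:`HealthState`.

    Raises :class:`StateCodeError` naming the offending position for
    malformed input.
    """
    if not isinstance(code, str) or len(code) != 5:
        raise StateCodeError(f"state code must be a 5-character string, got {code!r}")
    levels = []
    for pos, ch in enumerate(code, start=1):
        if ch not in "123":
            raise StateCodeError(
                f"state code {code!r}: character {ch!r} at position {pos} is not in 1-3"
            )
        levels.append(int(ch))
    return HealthState(tuple(levels))


def enumerate_states() -> list[HealthState]:
    """All 243 states in lexicographic code order ("11111" first)."""
    return [HealthState(lv) for lv in itertools.product(LEVELS, repeat=5)]


def iter_dim_levels() -> Iterator[tuple[Dimension, int]]:
    """(dimension, level) pairs for the decrement-bearing levels 2 and 3."""
    for dim in DIMENSIONS:
        for level in (2, 3):
            yield dim, level


def level_sum_score(state: HealthState) -> int:
    """Sum of the five dimension levels — a crude severity proxy in [5, 15]."""
    return sum(state.levels)


def dominates(a: HealthState, b: HealthState) -> bool:
    """True iff ``a`` is at least as good as ``b`` on every dimension and
    strictly better on at least one (lower level = better)."""
    return all(x <= y for x, y in zip(a.levels, b.levels)) and a.levels != b.levels
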