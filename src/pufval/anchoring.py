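"""Anchoring personal utility functions at dead = 0.

The raw PUF lives on a 0-1 scale with 0 at the worst describable state.
The bisection search (section F) brackets the respondent's location of
dead between two ranked states; the midpoint of their raw utilities is
taken as u_dead and all values are rescaled affinely so that dead maps to
0 and full health stays at 1:

    v(s) = (u(s) - u_dead) / (1 - u_dead)

equivalently each decrement is divided by (1 - u_dead).  States the
respondent holds worse than dead then value below 0.  Respondents who never
preferred dying (dead below "33333") cannot be rescaled by this method and
pass through unrescaled; respondents who never preferred living place dead
between full health and the mildest state they saw, and the midpoint of
those utilities is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .puf import PersonalUtilityFunction, StateRanking
from .state_space import DIMENSIONS, Dimension, HealthState, WORST_STATE
from .tasks import BisectionBracket

Status = Literal["rescaled", "unrescaled_dead_below_33333", "excluded_outlier"]


@dataclass(frozen=True)
class AnchoredPUF:
    """A PUF on the dead = 0, full health = 1 scale."""

    source: PersonalUtilityFunction
    dead_utility: Optional[float]
    anchored_decrement2: dict[Dimension, float]
    anchored_decrement3: dict[Dimension, float]
    status: Status

    def decrement(self, dim: Dimension, level: int) -> float:
        if level == 1:
            return 0.0
        return (self.anchored_decrement2 if level == 2 else self.anchored_decrement3)[dim]

    def value(self, state: HealthState) -> float:
        return 1.0 - sum(
            self.decrement(d, state.levels[i]) for i, d in enumerate(DIMENSIONS)
        )

    def with_status(self, status: Status) -> "AnchoredPUF":
        return AnchoredPUF(
            self.source, self.dead_utility,
            self.anchored_decrement2, self.anchored_decrement3, status,
        )


def dead_utility(
    puf: PersonalUtilityFunction,
    bracket: BisectionBracket,
    ranking: StateRanking,
) -> Optional[float]:
    """u_dead on the raw 0-1 scale, or None when dead lies below 33333.

    Bracketed: midpoint of the raw utilities of the two bracketing states.
    Above the mildest presented state: midpoint of 1 (full health) and that
    state's utility.
    """
    if bracket.classification == "below_33333":
        return None
    if bracket.classification == "above_mildest":
        if bracket.upper_rank is None:
            raise ValueError("above_mildest bracket lacks the mildest presented rank")
        return (1.0 + ranking.utility_at(bracket.upper_rank)) / 2.0
    if bracket.lower_rank is None or bracket.upper_rank is None:
        raise ValueError("bracketed classification requires both bounds")
    if not bracket.lower_rank < bracket.upper_rank:
        raise ValueError(
            f"inconsistent bracket: lower rank {bracket.lower_rank} "
            f">= upper rank {bracket.upper_rank}"
        )
    return (
        ranking.utility_at(bracket.lower_rank) + ranking.utility_at(bracket.upper_rank)
    ) / 2.0


def rescale_puf(
    puf: PersonalUtilityFunction, u_dead: Optional[float]
) -> AnchoredPUF:
    """Rescale a raw PUF so dead = 0, or pass it through when u_dead is None."""
    if u_dead is None:
        return AnchoredPUF(
            source=puf,
            dead_utility=None,
            anchored_decrement2=dict(puf.decrement2),
            anchored_decrement3=dict(puf.decrement3),
            status="unrescaled_dead_below_33333",
        )
    if u_dead >= 1.0:
        raise ValueError(f"dead utility must be below 1 (full health), got {u_dead}")
    scale = 1.0 / (1.0 - u_dead)
    return AnchoredPUF(
        source=puf,
        dead_utility=u_dead,
        anchored_decrement2={d: puf.decrement2[d] * scale for d in DIMENSIONS},
        anchored_decrement3={d: puf.decrement3[d] * scale for d in DIMENSIONS},
        status="rescaled",
    )


def anchor_puf(
    puf: PersonalUtilityFunction,
    bracket: BisectionBracket,
    ranking: StateRanking,
) -> AnchoredPUF:
    """Bracket -> u_dead -> rescaled PUF in one step."""
    return rescale_puf(puf, dead_utility(puf, bracket, ranking))


DEFAULT_OUTLIER_THRESHOLD = -10.0


def filter_outliers(
    anchored: list[AnchoredPUF], threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> tuple[list[AnchoredPUF], list[AnchoredPUF]]:
    """Split into (kept, excluded) by the anchored value of the worst state.

    A respondent whose dead lies very close to full health implies an
    extreme negative value for "33333" (the pilot's excluded outlier valued
    it at -31); any respondent valuing the worst state below ``threshold``
    is excluded.
    """
    if threshold >= 0:
        raise ValueError("outlier threshold must be negative")
    kept: list[AnchoredPUF] = []
    excluded: list[AnchoredPUF] = []
    for a in anchored:
        if a.value(WORST_STATE) < threshold:
            excluded.append(a.with_status("excluded_outlier"))
        else:
            kept.append(a)
    return kept, excluded
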