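"""Data model and validation for elicitation responses (sections A-G).

Each respondent record carries the raw answers from the structured
interview: a self-reported profile and VAS (section A), a ranking of the
five dimensions with ties permitted (B), 0-100 swing ratings per dimension
(C), a 100-point allocation between the extreme->moderate and
moderate->none improvements per dimension (D), two forced-choice validation
pairs (E), the adaptive search for the location of dead (F) and two
interaction choice tasks where indifference is permitted (G).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .state_space import DIMENSIONS, Dimension, HealthState, dominates, parse_state


def _as_state(v) -> HealthState:
    if isinstance(v, HealthState):
        return v
    return parse_state(v)


class _Record(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)


class SelfReport(_Record):
    """Section A: self-reported current and worst-experienced health."""

    current_profile: HealthState
    current_vas: int
    worst_profile: HealthState
    worst_vas: int

    _coerce = field_validator("current_profile", "worst_profile", mode="before")(_as_state)

    @field_validator("current_vas", "worst_vas")
    @classmethod
    def _vas_range(cls, v: int) -> int:
        if not 0 <= v <= 100:
            raise ValueError(f"VAS must be in [0, 100], got {v}")
        return v


class RankingWithTies(_Record):
    """Section B: ordered groups of dimensions, most important first.

    Tied dimensions share a group.  The groups partition the five
    dimensions.
    """

    groups: list[list[Dimension]]

    @model_validator(mode="after")
    def _partition(self) -> "RankingWithTies":
        flat = [d for g in self.groups for d in g]
        if not all(self.groups):
            raise ValueError("ranking groups must be non-empty")
        if sorted(flat) != sorted(DIMENSIONS):
            raise ValueError(
                f"ranking groups must partition the five dimensions, got {flat}"
            )
        return self


class SwingRatings(_Record):
    """Section C: rating in [0, 100] of each dimension's full swing
    (extreme problems -> no problems), 100 = most valued improvement."""

    rating: dict[Dimension, float]

    @model_validator(mode="after")
    def _check(self) -> "SwingRatings":
        if set(self.rating) != set(DIMENSIONS):
            raise ValueError("swing ratings must cover all five dimensions")
        for d, r in self.rating.items():
            if not 0 <= r <= 100:
                raise ValueError(f"rating for {d.value} must be in [0, 100], got {r}")
        if all(r == 0 for r in self.rating.values()):
            raise ValueError("at least one swing rating must be positive")
        return self


class LevelAllocations(_Record):
    """Section D: points (of 100) allocated to the intermediate improvement
    (extreme -> moderate) per dimension; the moderate -> none improvement
    implicitly receives the remaining 100 - p points."""

    points_intermediate: dict[Dimension, float]

    @model_validator(mode="after")
    def _check(self) -> "LevelAllocations":
        if set(self.points_intermediate) != set(DIMENSIONS):
            raise ValueError("level allocations must cover all five dimensions")
        for d, p in self.points_intermediate.items():
            if not 0 <= p <= 100:
                raise ValueError(f"points for {d.value} must be in [0, 100], got {p}")
        return self


class PairChoiceRecord(_Record):
    """Section E: forced choice between two non-dominating states."""

    task_index: Literal[1, 2]
    option_a: HealthState
    option_b: HealthState
    choice: Literal["A", "B"]

    _coerce = field_validator("option_a", "option_b", mode="before")(_as_state)

    @model_validator(mode="after")
    def _non_dominating(self) -> "PairChoiceRecord":
        if dominates(self.option_a, self.option_b) or dominates(self.option_b, self.option_a):
            raise ValueError(
                f"options {self.option_a.code} / {self.option_b.code} must not dominate"
            )
        return self


class DeadSearchRecord(_Record):
    """Section F: the adaptive choice sequence locating dead.

    ``presented`` pairs each presented rank (1-243, rank 1 = best) with its
    state; ``choices`` holds 'A' (prefer 10 years in the state) or 'B'
    (prefer dying now) per task.  The first presented state is always the
    worst state (rank 243); an 'A' there ends the search.
    """

    presented: list[tuple[int, HealthState]]
    choices: list[Literal["A", "B"]]

    @field_validator("presented", mode="before")
    @classmethod
    def _coerce_presented(cls, v):
        return [(r, _as_state(s)) for r, s in v]

    @model_validator(mode="after")
    def _shape(self) -> "DeadSearchRecord":
        if len(self.presented) != len(self.choices):
            raise ValueError("presented and choices must have equal length")
        if not 1 <= len(self.choices) <= 5:
            raise ValueError("dead search has between 1 and 5 tasks")
        if self.presented[0][0] != 243:
            raise ValueError("first presented state must be rank 243 (33333)")
        if len(self.choices) < 5 and self.choices[0] != "A":
            raise ValueError("search stops early only when the first choice is A")
        for rank, _ in self.presented:
            if not 1 <= rank <= 243:
                raise ValueError(f"presented rank {rank} out of range 1-243")
        return self


class InteractionRecord(_Record):
    """Section G: choice between two one-level improvements; indifference
    ('I') permitted."""

    task_index: Literal[1, 2]
    choice: Literal["A", "B", "I"]


class RespondentRecord(_Record):
    """One respondent's full set of responses."""

    respondent_id: str
    self_report: Optional[SelfReport] = None
    ranking: RankingWithTies
    swing: SwingRatings
    levels: LevelAllocations
    pair_choices: list[PairChoiceRecord] = []
    dead_search: Optional[DeadSearchRecord] = None
    interactions: list[InteractionRecord] = []
    used_default_tasks: bool = False


# ---------------------------------------------------------------------------
# Tie-aware rank statistics

def ranks_avg(ranking: RankingWithTies) -> dict[Dimension, float]:
    """Average-rank (AVG) convention: tied dimensions share the mean of the
    rank positions they jointly occupy.  Ranks over five dimensions always
    sum to 15."""
    ranks: dict[Dimension, float] = {}
    pos = 1
    for group in ranking.groups:
        k = len(group)
        mean_rank = (pos + (pos + k - 1)) / 2
        for d in group:
            ranks[d] = mean_rank
        pos += k
    return ranks


def ranks_eq(ranking: RankingWithTies) -> dict[Dimension, float]:
    """Shared-top (EQ) convention: every member of a tied group takes the
    position at which the group starts; subsequent positions are skipped."""
    ranks: dict[Dimension, float] = {}
    pos = 1
    for group in ranking.groups:
        for d in group:
            ranks[d] = float(pos)
        pos += len(group)
    return ranks


# ---------------------------------------------------------------------------
# Record validation

class Finding(BaseModel):
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: Literal["error", "warning"]
    field: str
    message: str


def validate_record(record: RespondentRecord) -> list[Finding]:
    """Check a respondent record for protocol conformance.

    Structural violations surface at parse time via pydantic; this adds
    protocol-level findings: a warning when no dimension was rated 100 in
    section C (respondents were instructed to rate their most valued swing
    100), a warning when several were, and a warning for a full five-way tie
    in the section B ranking.
    """
    findings: list[Finding] = []
    ratings = record.swing.rating
    n_hundred = sum(1 for r in ratings.values() if r == 100)
    if n_hundred == 0:
        findings.append(Finding(severity="warning", field="swing",
                                message="no dimension rated 100"))
    elif n_hundred > 1:
        findings.append(Finding(severity="warning", field="swing",
                                message="multiple dimensions rated 100"))
    if len(record.ranking.groups) == 1:
        findings.append(Finding(severity="warning", field="ranking",
                                message="all five dimensions tied in ranking"))
    if record.used_default_tasks and record.dead_search is not None:
        # tasks were generated from the uniform defaults, not this
        # respondent's own C/D answers; downstream anchoring must know
        findings.append(Finding(severity="warning", field="dead_search",
                                message="section E/F tasks used default settings"))
    return findings


#: Tool defaults substituted when adaptive tasks were generated without the
#: respondent's own section C/D answers: every swing rated 100, every
#: intermediate improvement allocated 50 points.
DEFAULT_SWING = SwingRatings(rating={d: 100.0 for d in DIMENSIONS})
DEFAULT_LEVELS = LevelAllocations(points_intermediate={d: 50.0 for d in DIMENSIONS})
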