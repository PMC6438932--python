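"""Synthetic respondents with known latent preferences.

The simulator draws a latent preference structure per respondent —
Dirichlet dimension weights, level-2 fractions centred near one half, a
subpopulation (about a quarter by default) for whom no state is worse than
dead, and otherwise a latent dead utility on the raw 0-1 scale — then
produces the section A-G responses that such a respondent would give:
swing ratings proportional to the latent weights (rounded to a grid,
emulating round-number bias), point allocations from the latent fractions,
and choice tasks answered by comparing latent utilities with logistic
noise.  Because the latents are known, the whole pipeline can be tested
for parameter recovery.

Randomness flows from a single seed through per-respondent spawned
streams, so extending a cohort never perturbs earlier respondents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .puf import (
    PersonalUtilityFunction,
    dimension_weights,
    puf_from_responses,
    rank_all_states,
    state_utility,
)
from .responses import (
    LevelAllocations,
    PairChoiceRecord,
    RankingWithTies,
    RespondentRecord,
    SelfReport,
    SwingRatings,
)
from .state_space import DIMENSIONS, Dimension, FULL_HEALTH, HealthState
from .tasks import (
    generate_interaction_tasks,
    generate_validation_pairs,
    most_least_important,
    run_dead_search,
)
from .responses import InteractionRecord, ranks_avg


@dataclass(frozen=True)
class LatentRespondent:
    """Ground-truth preferences of one synthetic respondent."""

    true_weight: dict[Dimension, float]
    true_level2_fraction: dict[Dimension, float]
    nothing_worse_than_dead: bool
    true_dead_utility: Optional[float]  # raw-scale, in (0, 1); None when nothing worse
    choice_noise_scale: float = 0.0
    rating_rounding: float = 5.0  # grid for ratings/allocations; 0 disables

    def puf(self) -> PersonalUtilityFunction:
        return PersonalUtilityFunction(
            weight=dict(self.true_weight),
            level2_fraction=dict(self.true_level2_fraction),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for a simulated cohort.

    Defaults mirror the pilot's observed phenomena: ratings cluster on
    multiples of 5; roughly 24% of respondents hold no state worse than
    dead; dimension weights are heterogeneous but not extreme
    (symmetric Dirichlet, concentration 4); level-2 fractions centre on
    0.5 (symmetric Beta, concentration 4); latent dead utilities sit low
    on the raw scale (Beta(2, 6)), as the observed brackets did.
    """

    n_respondents: int = 60
    seed: int = 0
    weight_concentration: float = 4.0
    level2_concentration: float = 4.0
    p_nothing_worse_than_dead: float = 0.24
    dead_utility_beta: tuple[float, float] = (2.0, 6.0)
    choice_noise_scale: float = 0.0
    rating_rounding: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_nothing_worse_than_dead <= 1:
            raise ValueError("p_nothing_worse_than_dead must be a probability")
        if self.n_respondents < 0 or self.choice_noise_scale < 0:
            raise ValueError("n_respondents and noise scale must be non-negative")
        if self.rating_rounding < 0:
            raise ValueError("rating_rounding must be non-negative (0 disables)")


def _rng(seed: int, i: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, stream)))


def sample_latent(config: SimulationConfig) -> list[LatentRespondent]:
    """Draw the latent cohort; deterministic given the config seed."""
    latents = []
    for i in range(config.n_respondents):
        rng = _rng(config.seed, i, 0)
        w = rng.dirichlet([config.weight_concentration] * 5)
        frac = rng.beta(config.level2_concentration, config.level2_concentration, size=5)
        nothing_worse = bool(rng.random() < config.p_nothing_worse_than_dead)
        a, b = config.dead_utility_beta
        u_dead = None if nothing_worse else float(rng.beta(a, b))
        latents.append(
            LatentRespondent(
                true_weight=dict(zip(DIMENSIONS, map(float, w))),
                true_level2_fraction=dict(zip(DIMENSIONS, map(float, frac))),
                nothing_worse_than_dead=nothing_worse,
                true_dead_utility=u_dead,
                choice_noise_scale=config.choice_noise_scale,
                rating_rounding=config.rating_rounding,
            )
        )
    return latents


def _round_grid(x: float, grid: float) -> float:
    if grid <= 0:
        return x
    return float(grid * np.round(x / grid))


def _choose(diff: float, scale: float, rng: np.random.Generator) -> str:
    """'A' with probability sigmoid(diff / scale); deterministic at scale 0."""
    if scale <= 0:
        return "A" if diff >= 0 else "B"
    p = 1.0 / (1.0 + np.exp(-diff / scale))
    return "A" if rng.random() < p else "B"


def simulate_responses(latent: LatentRespondent, seed: int) -> RespondentRecord:
    """Produce one respondent's full A-G record from their latents.

    Adaptive tasks (sections E-G) are generated exactly as the interview
    tool would — from the respondent's *stated* (rounded) section C/D
    answers — while the choices made in those tasks come from the latent
    utilities, plus logistic choice noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grid = latent.rating_rounding
    w = latent.true_weight
    wmax = max(w.values())

    ratings = {
        d: min(100.0, _round_grid(100.0 * w[d] / wmax, grid)) for d in DIMENSIONS
    }
    points = {
        d: min(100.0, _round_grid(100.0 * latent.true_level2_fraction[d], grid))
        for d in DIMENSIONS
    }
    swing = SwingRatings(rating=ratings)
    levels = LevelAllocations(points_intermediate=points)

    # section B: rank by stated rating; equal stated ratings tie
    by_rating: dict[float, list[Dimension]] = {}
    for d in DIMENSIONS:
        by_rating.setdefault(ratings[d], []).append(d)
    groups = [by_rating[r] for r in sorted(by_rating, reverse=True)]
    ranking_b = RankingWithTies(groups=groups)

    # section A: a light self-report (not used downstream)
    if rng.random() < 0.6:
        current = FULL_HEALTH
    else:
        lv = [1 + int(rng.random() < 0.4) for _ in range(5)]
        current = HealthState(tuple(lv))
    worst = HealthState(tuple(min(3, l + 1 + int(rng.random() < 0.5)) for l in current.levels))
    self_report = SelfReport(
        current_profile=current,
        current_vas=int(np.clip(rng.normal(79, 10), 0, 100)),
        worst_profile=worst,
        worst_vas=int(np.clip(rng.normal(40, 15), 0, 100)),
    )

    latent_puf = latent.puf()
    stated_puf = puf_from_responses(swing, levels)
    stated_ranking = rank_all_states(stated_puf)
    noise = latent.choice_noise_scale

    # section E: tailored validation pairs, answered from latent utilities
    pair_choices = []
    for pair in generate_validation_pairs(stated_ranking):
        diff = state_utility(latent_puf, pair.option_a) - state_utility(
            latent_puf, pair.option_b
        )
        pair_choices.append(
            PairChoiceRecord(
                task_index=pair.task_index,
                option_a=pair.option_a,
                option_b=pair.option_b,
                choice=_choose(diff, noise, rng),
            )
        )

    # section F: live-vs-die choices against the latent dead utility
    if latent.nothing_worse_than_dead:
        answer = lambda state: "A"
    else:
        u_dead = latent.true_dead_utility

        def answer(state: HealthState) -> str:
            return _choose(state_utility(latent_puf, state) - u_dead, noise, rng)

    dead_record, _ = run_dead_search(stated_ranking, answer)

    # section G: the latent PUF is additive, so matched one-level
    # improvements are exactly equal in value -> indifference at zero noise
    most, least = most_least_important(ranks_avg(ranking_b), ratings)
    interactions = []
    for task in generate_interaction_tasks(most, least):
        da = state_utility(latent_puf, task.option_a[1]) - state_utility(
            latent_puf, task.option_a[0]
        )
        db = state_utility(latent_puf, task.option_b[1]) - state_utility(
            latent_puf, task.option_b[0]
        )
        if noise <= 0:
            choice = "I" if abs(da - db) < 1e-12 else ("A" if da > db else "B")
        else:
            z = (da - db) / noise + rng.logistic()
            choice = "A" if z > 1 else ("B" if z < -1 else "I")
        interactions.append(InteractionRecord(task_index=task.task_index, choice=choice))

    return RespondentRecord(
        respondent_id=f"sim-{seed}",
        self_report=self_report,
        ranking=ranking_b,
        swing=swing,
        levels=levels,
        pair_choices=pair_choices,
        dead_search=dead_record,
        interactions=interactions,
        used_default_tasks=False,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[LatentRespondent], list[RespondentRecord]]:
    """Latents plus their simulated records, ids ``r0001`` onward."""
    latents = sample_latent(config)
    records = []
    for i, latent in enumerate(latents):
        seed_i = int(_rng(config.seed, i, 1).integers(0, 2**31 - 1))
        rec = simulate_responses(latent, seed_i)
        records.append(rec.model_copy(update={"respondent_id": f"r{i + 1:04d}"}))
    return latents, records


def recovery_report(config: SimulationConfig) -> dict:
    """Bias and RMSE of recovered weights, level-2 fractions and dead
    utilities against the latent truth, per dimension and overall."""
    from .anchoring import dead_utility as bracket_midpoint
    from .tasks import classify_bracket

    latents, records = simulate_cohort(config)
    w_err = {d: [] for d in DIMENSIONS}
    f_err = {d: [] for d in DIMENSIONS}
    dead_err = []
    for latent, rec in zip(latents, records):
        w_hat = dimension_weights(rec.swing)
        for d in DIMENSIONS:
            w_err[d].append(w_hat[d] - latent.true_weight[d])
            f_err[d].append(
                rec.levels.points_intermediate[d] / 100.0
                - latent.true_level2_fraction[d]
            )
        if latent.true_dead_utility is not None and rec.dead_search is not None:
            bracket = classify_bracket(rec.dead_search)
            if bracket.classification != "below_33333":
                stated_puf = puf_from_responses(rec.swing, rec.levels)
                ranking = rank_all_states(stated_puf)
                u_hat = bracket_midpoint(stated_puf, bracket, ranking)
                dead_err.append(u_hat - latent.true_dead_utility)

    def _stats(errs: list[float]) -> dict[str, float]:
        if not errs:
            return {"bias": float("nan"), "rmse": float("nan"), "n": 0}
        a = np.asarray(errs)
        return {
            "bias": float(a.mean()),
            "rmse": float(np.sqrt((a**2).mean())),
            "n": len(a),
        }

    report = {
        "weights": {d.value: _stats(w_err[d]) for d in DIMENSIONS},
        "level2_fractions": {d.value: _stats(f_err[d]) for d in DIMENSIONS},
        "dead_utility": _stats(dead_err),
    }
    report["weights"]["overall"] = _stats([e for d in DIMENSIONS for e in w_err[d]])
    report["level2_fractions"]["overall"] = _stats(
        [e for d in DIMENSIONS for e in f_err[d]]
    )
    return report
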