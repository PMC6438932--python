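"""Study files: reading and writing respondent records.

The canonical on-disk format is JSON — one study object with metadata
(recording every convention in force, so any value set can be reproduced
from its inputs) and a list of respondent records with states as 5-digit
codes.  A flat CSV format (one row per respondent) is provided for
spreadsheet work; rankings serialize as ">"-separated, ","-joined tied
groups, e.g. ``PD>MO,AD>SC>UA``.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, ValidationError

from .responses import (
    DeadSearchRecord,
    InteractionRecord,
    LevelAllocations,
    PairChoiceRecord,
    RankingWithTies,
    RespondentRecord,
    SelfReport,
    SwingRatings,
)
from .state_space import DIMENSIONS, Dimension

logger = logging.getLogger("pufval")


class StudyConventions(BaseModel):
    """Normative analysis choices recorded alongside the data."""

    level2_mapping: str = "share_of_swing"
    outlier_threshold: float = -10.0
    include_unrescaled: bool = True
    central_measure: str = "mean"


class StudyMetadata(BaseModel):
    study_id: str = "study"
    duration_years: float = 10.0
    conventions: StudyConventions = StudyConventions()


class StudyFile(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    metadata: StudyMetadata = StudyMetadata()
    respondents: list[RespondentRecord] = []


class StudyParseError(ValueError):
    """Malformed study file; message names the respondent and field."""


# ---------------------------------------------------------------------------
# dict <-> record conversion (states as 5-char codes)

def record_to_dict(rec: RespondentRecord) -> dict:
    d: dict = {
        "respondent_id": rec.respondent_id,
        "used_default_tasks": rec.used_default_tasks,
        "ranking": [[dim.value for dim in g] for g in rec.ranking.groups],
        "swing": {dim.value: rec.swing.rating[dim] for dim in DIMENSIONS},
        "levels": {
            dim.value: rec.levels.points_intermediate[dim] for dim in DIMENSIONS
        },
    }
    if rec.self_report is not None:
        sr = rec.self_report
        d["self_report"] = {
            "current_profile": sr.current_profile.code,
            "current_vas": sr.current_vas,
            "worst_profile": sr.worst_profile.code,
            "worst_vas": sr.worst_vas,
        }
    d["pair_choices"] = [
        {
            "task_index": p.task_index,
            "option_a": p.option_a.code,
            "option_b": p.option_b.code,
            "choice": p.choice,
        }
        for p in rec.pair_choices
    ]
    if rec.dead_search is not None:
        d["dead_search"] = {
            "presented": [[r, s.code] for r, s in rec.dead_search.presented],
            "choices": list(rec.dead_search.choices),
        }
    d["interactions"] = [
        {"task_index": i.task_index, "choice": i.choice} for i in rec.interactions
    ]
    return d


def record_from_dict(d: dict) -> RespondentRecord:
    rid = d.get("respondent_id", "<missing id>")
    try:
        return RespondentRecord(
            respondent_id=d["respondent_id"],
            used_default_tasks=d.get("used_default_tasks", False),
            ranking=RankingWithTies(groups=d["ranking"]),
            swing=SwingRatings(
                rating={Dimension(k): v for k, v in d["swing"].items()}
            ),
            levels=LevelAllocations(
                points_intermediate={Dimension(k): v for k, v in d["levels"].items()}
            ),
            self_report=(
                SelfReport(**d["self_report"]) if d.get("self_report") else None
            ),
            pair_choices=[PairChoiceRecord(**p) for p in d.get("pair_choices", [])],
            dead_search=(
                DeadSearchRecord(**d["dead_search"]) if d.get("dead_search") else None
            ),
            interactions=[
                InteractionRecord(**i) for i in d.get("interactions", [])
            ],
        )
    except (KeyError, ValidationError, ValueError) as exc:
        raise StudyParseError(f"respondent {rid!r}: {exc}") from exc


def study_to_dict(study: StudyFile) -> dict:
    return {
        "metadata": study.metadata.model_dump(),
        "respondents": [record_to_dict(r) for r in study.respondents],
    }


def study_from_dict(d: dict) -> StudyFile:
    meta = StudyMetadata(**d.get("metadata", {}))
    respondents = [record_from_dict(r) for r in d.get("respondents", [])]
    ids = [r.respondent_id for r in respondents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise StudyParseError(f"duplicate respondent ids: {dupes}")
    if not respondents:
        logger.warning("study %s contains no respondents", meta.study_id)
    return StudyFile(metadata=meta, respondents=respondents)


# ---------------------------------------------------------------------------
# JSON

def write_study(study: StudyFile, path: Union[str, Path]) -> None:
    conv = study.metadata.conventions
    logger.info(
        "writing study %s: level2_mapping=%s outlier_threshold=%s "
        "include_unrescaled=%s central=%s",
        study.metadata.study_id, conv.level2_mapping, conv.outlier_threshold,
        conv.include_unrescaled, conv.central_measure,
    )
    Path(path).write_text(json.dumps(study_to_dict(study), indent=1) + "\n")


def read_study(path: Union[str, Path]) -> StudyFile:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_study_csv(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StudyParseError(f"{path}: not valid JSON ({exc})") from exc
    return study_from_dict(data)


# ---------------------------------------------------------------------------
# flat CSV (sections B-D and G; E/F serialized compactly)

def _ranking_to_str(ranking: RankingWithTies) -> str:
    return ">".join(",".join(d.value for d in g) for g in ranking.groups)


def _ranking_from_str(s: str) -> RankingWithTies:
    groups = [[Dimension(x) for x in grp.split(",")] for grp in s.split(">")]
    return RankingWithTies(groups=groups)


def write_study_csv(study: StudyFile, path: Union[str, Path]) -> None:
    fields = (
        ["respondent_id", "used_default_tasks", "ranking"]
        + [f"swing_{d.value}" for d in DIMENSIONS]
        + [f"points_{d.value}" for d in DIMENSIONS]
        + ["dead_ranks", "dead_choices", "g1_choice", "g2_choice"]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in study.respondents:
            row = {
                "respondent_id": rec.respondent_id,
                "used_default_tasks": int(rec.used_default_tasks),
                "ranking": _ranking_to_str(rec.ranking),
            }
            for d in DIMENSIONS:
                row[f"swing_{d.value}"] = rec.swing.rating[d]
                row[f"points_{d.value}"] = rec.levels.points_intermediate[d]
            if rec.dead_search is not None:
                row["dead_ranks"] = ";".join(
                    str(r) for r, _ in rec.dead_search.presented
                )
                row["dead_choices"] = "".join(rec.dead_search.choices)
            for i in rec.interactions:
                row[f"g{i.task_index}_choice"] = i.choice
            writer.writerow(row)


def read_study_csv(path: Union[str, Path]) -> StudyFile:
    """Read the flat CSV.  Dead-search states are reconstructed from the
    respondent's own ranking, which the presented ranks index into."""
    from .puf import puf_from_responses, rank_all_states, uniform_puf

    respondents = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rid = row.get("respondent_id", "<missing id>")
            try:
                used_default = bool(int(row.get("used_default_tasks", 0) or 0))
                swing = SwingRatings(
                    rating={d: float(row[f"swing_{d.value}"]) for d in DIMENSIONS}
                )
                levels = LevelAllocations(
                    points_intermediate={
                        d: float(row[f"points_{d.value}"]) for d in DIMENSIONS
                    }
                )
                dead = None
                if row.get("dead_ranks"):
                    task_puf = (
                        uniform_puf()
                        if used_default
                        else puf_from_responses(swing, levels)
                    )
                    ranking = rank_all_states(task_puf)
                    ranks = [int(x) for x in row["dead_ranks"].split(";")]
                    dead = DeadSearchRecord(
                        presented=[(r, ranking.state_at(r)) for r in ranks],
                        choices=list(row["dead_choices"]),
                    )
                interactions = [
                    InteractionRecord(task_index=t, choice=row[f"g{t}_choice"])
                    for t in (1, 2)
                    if row.get(f"g{t}_choice")
                ]
                respondents.append(
                    RespondentRecord(
                        respondent_id=row["respondent_id"],
                        used_default_tasks=used_default,
                        ranking=_ranking_from_str(row["ranking"]),
                        swing=swing,
                        levels=levels,
                        dead_search=dead,
                        interactions=interactions,
                    )
                )
            except (KeyError, ValidationError, ValueError) as exc:
                raise StudyParseError(f"respondent {rid!r}: {exc}") from exc
    return StudyFile(respondents=respondents)
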