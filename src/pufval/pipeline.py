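"""End-to-end analysis: respondent records -> anchored PUFs -> value set."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .aggregation import DecrementSummary, ValueSetTable, build_value_set, summarize_decrements
from .anchoring import (
    DEFAULT_OUTLIER_THRESHOLD,
    AnchoredPUF,
    anchor_puf,
    filter_outliers,
)
from .puf import (
    Level2Mapping,
    PersonalUtilityFunction,
    puf_from_responses,
    rank_all_states,
    uniform_puf,
)
from .responses import RespondentRecord
from .tasks import classify_bracket

logger = logging.getLogger("pufval")


@dataclass
class RespondentResult:
    """Per-respondent artefacts of the pipeline."""

    respondent_id: str
    puf: PersonalUtilityFunction
    anchored: Optional[AnchoredPUF]
    excluded_reason: Optional[str] = None


@dataclass
class StudyResult:
    respondents: list[RespondentResult]
    summary: DecrementSummary
    value_set: ValueSetTable

    @property
    def included(self) -> list[RespondentResult]:
        return [r for r in self.respondents if r.excluded_reason is None]


def anchored_puf_for_record(
    record: RespondentRecord, level2_mapping: Level2Mapping = "share_of_swing"
) -> Optional[AnchoredPUF]:
    """Anchor one respondent's PUF from their dead-search record.

    The ranking the presented ranks refer to is the one the interview tool
    used: the respondent's own stated PUF, or the uniform default PUF when
    the adaptive tasks were generated from default settings.  Returns None
    when no dead search was recorded.
    """
    if record.dead_search is None:
        return None
    puf = puf_from_responses(record.swing, record.levels, level2_mapping)
    task_puf = uniform_puf() if record.used_default_tasks else puf
    ranking = rank_all_states(task_puf)
    bracket = classify_bracket(record.dead_search)
    return anchor_puf(puf, bracket, ranking)


def build_social_value_set(
    records: list[RespondentRecord],
    central_measure: str = "mean",
    level2_mapping: Level2Mapping = "share_of_swing",
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    include_unrescaled: bool = True,
    drop_default_tasks: bool = True,
) -> StudyResult:
    """Aggregate a cohort's records into a social utility function.

    Respondents are excluded when their adaptive tasks were not tailored
    to their own answers (``drop_default_tasks``, since the dead search
    then cannot anchor their PUF), when no dead search was recorded, when
    dead lies below the worst state and ``include_unrescaled`` is off, or
    when their anchored worst-state value falls below ``outlier_threshold``.
    """
    logger.info(
        "building value set: central=%s level2_mapping=%s outlier_threshold=%s "
        "include_unrescaled=%s drop_default_tasks=%s",
        central_measure, level2_mapping, outlier_threshold,
        include_unrescaled, drop_default_tasks,
    )
    results: list[RespondentResult] = []
    for rec in records:
        puf = puf_from_responses(rec.swing, rec.levels, level2_mapping)
        if drop_default_tasks and rec.used_default_tasks:
            results.append(RespondentResult(rec.respondent_id, puf, None, "default_tasks"))
            continue
        anchored = anchored_puf_for_record(rec, level2_mapping)
        if anchored is None:
            results.append(RespondentResult(rec.respondent_id, puf, None, "no_dead_search"))
            continue
        if anchored.status == "unrescaled_dead_below_33333" and not include_unrescaled:
            results.append(
                RespondentResult(rec.respondent_id, puf, anchored, "dead_below_33333")
            )
            continue
        results.append(RespondentResult(rec.respondent_id, puf, anchored))

    kept, excluded = filter_outliers(
        [r.anchored for r in results if r.excluded_reason is None],
        outlier_threshold,
    )
    excluded_ids = {id(a.source) for a in excluded}
    for r in results:
        if r.excluded_reason is None and id(r.puf) in excluded_ids:
            r.anchored = r.anchored.with_status("excluded_outlier")
            r.excluded_reason = "outlier"

    if not kept:
        raise ValueError("no respondents remain after exclusions")
    summary = summarize_decrements(kept)
    value_set = build_value_set(summary, central_measure)
    return StudyResult(respondents=results, summary=summary, value_set=value_set)
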