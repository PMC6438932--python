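"""Aggregating individual PUFs into a social utility function (value set).

Aggregation runs on the per-dimension, per-level decrements (as the
published summary tables do), not on state values: for each of the ten
(dimension, level in {2,3}) cells the respondents' decrements are
summarised (min, quartiles, median, mean, max, SD, SE), and the value set
follows by subtracting the chosen central decrements from 1 for every
state.  With unanchored inputs the mean level-3 decrements sum to exactly
1, so the worst state values exactly 0; with dead-anchored inputs the
worst state typically values below 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

from .anchoring import AnchoredPUF
from .puf import PersonalUtilityFunction
from .state_space import Dimension, HealthState, enumerate_states, iter_dim_levels

CentralMeasure = Literal["mean", "median"]

STATISTICS = ("min", "q1", "median", "mean", "q3", "max", "sd", "se")


@dataclass(frozen=True)
class DecrementSummary:
    """Order statistics and moments of respondents' decrements per
    (dimension, level) cell.

    ``table`` is indexed by (dimension code, level) with one column per
    statistic.  Quartiles use linear interpolation between order
    statistics; SD uses the n-1 denominator and SE = SD / sqrt(n).
    """

    table: pd.DataFrame
    n: int

    def stat(self, dim: Dimension, level: int, statistic: str) -> float:
        return float(self.table.loc[(dim.value, level), statistic])

    def central(self, measure: CentralMeasure) -> dict[tuple[Dimension, int], float]:
        if measure not in ("mean", "median"):
            raise ValueError(f"central measure must be 'mean' or 'median', got {measure!r}")
        return {
            (d, lv): self.stat(d, lv, measure) for d, lv in iter_dim_levels()
        }


@dataclass(frozen=True)
class ValueSetTable:
    """A value set: a value for each of the 243 states, derived from the
    central (mean or median) decrements of a :class:`DecrementSummary`."""

    summary: DecrementSummary
    central_measure: CentralMeasure
    values: dict[str, float]

    def value(self, state: Union[HealthState, str]) -> float:
        code = state.code if isinstance(state, HealthState) else state
        return self.values[code]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"code": list(self.values), "value": list(self.values.values())}
        )


def summarize_decrements(
    pufs: Sequence[Union[AnchoredPUF, PersonalUtilityFunction]],
) -> DecrementSummary:
    """Summarise decrements across respondents for every dimension-level cell."""
    if len(pufs) == 0:
        raise ValueError("cannot summarise an empty collection of PUFs")
    rows = []
    for dim, level in iter_dim_levels():
        x = np.array([p.decrement(dim, level) for p in pufs], dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        rows.append(
            {
                "dimension": dim.value,
                "level": level,
                "min": float(x.min()),
                "q1": float(q1),
                "median": float(med),
                "mean": float(x.mean()),
                "q3": float(q3),
                "max": float(x.max()),
                "sd": sd,
                "se": sd / np.sqrt(len(x)),
            }
        )
    table = pd.DataFrame(rows).set_index(["dimension", "level"])
    return DecrementSummary(table=table, n=len(pufs))


def build_value_set(
    summary: DecrementSummary, central_measure: CentralMeasure = "mean"
) -> ValueSetTable:
    """Value of every state = 1 - sum of the chosen central decrements."""
    central = summary.central(central_measure)
    dec = {(d, 1): 0.0 for d, _ in iter_dim_levels()}
    dec.update(central)
    values: dict[str, float] = {}
    from .state_space import DIMENSIONS

    for s in enumerate_states():
        values[s.code] = 1.0 - sum(
            dec[(d, s.levels[i])] for i, d in enumerate(DIMENSIONS)
        )
    return ValueSetTable(summary=summary, central_measure=central_measure, values=values)
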