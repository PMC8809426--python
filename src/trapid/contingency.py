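"""Contingency-table tests and rate summaries for face-capture success.

Pearson chi-squared tests are computed *without* continuity correction —
the printed 2x2 statistics are only reproduced under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .events import Behavior, DetectionEvent, InputError, SiteDeployment

__all__ = [
    "ContingencyTable",
    "Chi2Result",
    "DegenerateTableError",
    "pearson_chi2",
    "capture_rate",
    "format_percent",
    "format_p_value",
    "behavior_table",
]


class DegenerateTableError(ValueError):
    """A row or column total is zero; the chi-squared test is undefined."""


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("contingency table must be 2-dimensional")
        if np.any(self.counts < 0):
            raise InputError("contingency table counts must be nonnegative")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def pearson_chi2(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-squared test of independence, no continuity correction.

    statistic = sum (O - E)^2 / E,  df = (r - 1)(c - 1),
    p from the upper tail of the chi-squared distribution.
    """
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("chi-squared test needs at least a 2x2 table")
    if not np.allclose(counts, np.round(counts)):
        raise InputError("contingency counts must be integers")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise DegenerateTableError("zero row or column total; test undefined")
    n = counts.sum()
    expected = np.outer(row_tot, col_tot) / n
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return Chi2Result(statistic=statistic, df=df, p_value=p)


def capture_rate(numerator: int, denominator: int) -> float:
    """Exact face-capture proportion (numerator successes out of denominator events)."""
    if denominator <= 0:
        raise InputError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise InputError("numerator must lie in [0, denominator]")
    return numerator / denominator


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Percentage string, rounding half away from zero."""
    scaled = proportion * 100.0 * 10**decimals
    # round half away from zero, robust to float representation
    rounded = np.floor(np.abs(scaled) + 0.5) * np.sign(scaled)
    value = rounded / 10**decimals
    return f"{value:.{decimals}f}%"


def format_p_value(p: float, decimals: int = 3) -> str:
    """p to 3 dp with the journal-style '< .001' floor."""
    floor = 10**-decimals
    if p < floor:
        return f"< .{'0' * (decimals - 1)}1"
    text = f"{p:.{decimals}f}"
    return text[1:] if text.startswith("0.") else text


_BEHAVIOR_ORDER = [Behavior.RETREAT, Behavior.CURIOSITY, Behavior.LOOK_ONLY, Behavior.NONE]


def behavior_table(
    events: Sequence[DetectionEvent],
    sites: Mapping[str, SiteDeployment] | Sequence[SiteDeployment],
    split_by_night: bool = False,
) -> ContingencyTable:
    """Cross-classify events: behavior rows x (ACD, conventional) columns.

    With ``split_by_night`` each site-type column is split into night/day.
    Marginal totals equal the event count.
    """
    if not isinstance(sites, Mapping):
        sites = {s.site_id: s for s in sites}
    unknown = sorted({e.site_id for e in events} - set(sites))
    if unknown:
        raise InputError(f"events reference unknown sites: {unknown}")

    if split_by_night:
        cols = ["acd_night", "acd_day", "conventional_night", "conventional_day"]
    else:
        cols = ["acd", "conventional"]
    rows = [b.value for b in _BEHAVIOR_ORDER] + [Behavior.UNKNOWN.value]
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for e in events:
        acd = sites[e.site_id].has_acd
        if split_by_night:
            if e.is_night is None:
                raise InputError(f"event {e.event_id} has no night flag; classify first")
            j = (0 if acd else 2) + (0 if e.is_night else 1)
        else:
            j = 0 if acd else 1
        counts[rows.index(e.behavior.value), j] += 1
    return ContingencyTable(counts=counts, row_labels=rows, col_labels=cols)


def retreat_table(
    events: Sequence[DetectionEvent],
    sites: Mapping[str, SiteDeployment] | Sequence[SiteDeployment],
) -> ContingencyTable:
    """2x2 of retreat vs non-retreat reactions by site type."""
    if not isinstance(sites, Mapping):
        sites = {s.site_id: s for s in sites}
    counts = np.zeros((2, 2), dtype=int)
    for e in events:
        i = 0 if e.behavior is Behavior.RETREAT else 1
        j = 0 if sites[e.site_id].has_acd else 1
        counts[i, j] += 1
    return ContingencyTable(
        counts=counts,
        row_labels=["retreat", "non_retreat"],
        col_labels=["acd", "conventional"],
    )
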