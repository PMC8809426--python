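"""Chance-corrected inter-rater agreement for the pairwise rating task.

Fleiss' kappa over an N-subjects x k-categories assignment-count table:

    p_j  = sum_i n_ij / (N R)                    category proportions
    P_i  = (sum_j n_ij^2 - R) / (R (R - 1))      per-subject agreement
    kappa = (Pbar - Pbar_e) / (1 - Pbar_e),      Pbar_e = sum_j p_j^2

with the large-sample variance

    var(kappa) = 2 / (N R (R-1))
                 * [Pbar_e - (2R-3) Pbar_e^2 + 2 (R-2) sum_j p_j^3]
                 / (1 - Pbar_e)^2

giving a symmetric normal confidence interval.  A table in which every
assignment falls in one category has Pbar_e = 1 and kappa undefined; such
"perfect/degenerate" subsets are reported as a signal, not a number.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ratings import DIFFERENT, SAME, PairRatingSet, RatingsError

__all__ = [
    "RatingTable",
    "KappaResult",
    "SubsetSpec",
    "SubsetMode",
    "PairingAttribute",
    "UndefinedKappaError",
    "fleiss_kappa",
    "fleiss_kappa_ci",
    "subset_kappa",
    "spearman_rho",
    "rating_table_from_pairs",
]

_Z_975 = 1.959964  # standard normal 97.5% quantile, unrounded


class UndefinedKappaError(ValueError):
    """All assignments fall in one category; kappa is undefined (0/0)."""


@dataclass
class RatingTable:
    """N subjects x k categories; cell (i, j) = raters assigning subject i to j."""

    counts: np.ndarray
    categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise RatingsError("rating table must be 2-dimensional")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise RatingsError("rating table needs N >= 2 subjects and k >= 2 categories")
        row_sums = self.counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise RatingsError("every subject must be rated by the same number of raters")
        if self.categories is None:
            self.categories = [f"c{j}" for j in range(self.counts.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])


def _kappa_terms(table: RatingTable) -> tuple[float, float, np.ndarray, int, int]:
    counts = table.counts
    n, r = table.n_subjects, table.n_raters
    p_j = counts.sum(axis=0) / (n * r)
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_e = float(np.sum(p_j**2))
    return p_bar, p_e, p_j, n, r

def fleiss_kappa(table: RatingTable) -> float:
    """Fleiss' kappa for the assignment-count table; raises if degenerate."""
    p_bar, p_e, _, _, _ = _kappa_terms(table)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("all assignments in a single category; kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa_ci(table: RatingTable, level: float = 0.95) -> tuple[float, float]:
    """Large-sample symmetric normal confidence interval for Fleiss' kappa."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    kappa = fleiss_kappa(table)
    _, p_e, p_j, n, r = _kappa_terms(table)
    var = (
        2.0
        / (n * r * (r - 1))
        * (p_e - (2 * r - 3) * p_e**2 + 2 * (r - 2) * float(np.sum(p_j**3)))
        / (1.0 - p_e) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = _Z_975 if level == 0.95 else float(stats.norm.ppf((1 + level) / 2))
    return kappa - z * se, kappa + z * se


class PairingAttribute(str, enum.Enum):
    MONOCHROME = "monochrome"
    AMBIENT_LIGHT = "ambient_light"
    PINNAE_DAMAGE = "pinnae_damage"
    RESOLUTION_HIGH = "resolution_high"


class SubsetMode(str, enum.Enum):
    BOTH = "both"        # attribute true for both events of the pairing
    NEITHER = "neither"  # false for both
    MIXED = "mixed"      # exactly one


@dataclass(frozen=True)
class SubsetSpec:
    attribute: PairingAttribute
    mode: SubsetMode

    def matches(self, flag_a: bool, flag_b: bool) -> bool:
        if self.mode is SubsetMode.BOTH:
            return flag_a and flag_b
        if self.mode is SubsetMode.NEITHER:
            return not flag_a and not flag_b
        return flag_a != flag_b

    @property
    def label(self) -> str:
        return f"{self.attribute.value}:{self.mode.value}"


@dataclass(frozen=True)
class KappaResult:
    label: str
    n_pairings: int
    kappa: float | None
    ci: tuple[float, float] | None
    degenerate: bool = False
    empty: bool = False

    @property
    def perfect_degenerate(self) -> bool:
        return self.degenerate and not self.empty


def rating_table_from_pairs(
    ratings: PairRatingSet, pairs: Sequence[tuple[str, str]] | None = None
) -> RatingTable:
    """Build the N x 2 {same, different} count table over the given pairings."""
    pairs = list(ratings.pairs()) if pairs is None else list(pairs)
    counts = np.zeros((len(pairs), 2), dtype=float)
    for i, pair in enumerate(pairs):
        votes = ratings.votes(pair)
        counts[i, 0] = votes.count(SAME)
        counts[i, 1] = votes.count(DIFFERENT)
    return RatingTable(counts=counts, categories=[SAME, DIFFERENT])


def subset_kappa(
    ratings: PairRatingSet,
    events: Mapping[str, object] | Sequence[object],
    spec: SubsetSpec,
    level: float = 0.95,
) -> KappaResult:
    """Fleiss' kappa restricted to pairings matching an either/or/both subset.

    ``events`` supplies per-event attribute flags via attributes named like
    the :class:`PairingAttribute` values (works for detection events and for
    synthetic rated events alike).  Degenerate subsets — every retained
    verdict in one category — are reported as perfect/degenerate, without a
    numeric kappa.
    """
    if not isinstance(events, Mapping):
        events = {getattr(e, "event_id"): e for e in events}
    attr = spec.attribute.value

    def flag(event_id: str) -> bool:
        event = events[event_id]
        value = getattr(event, attr)
        if value is None:
            raise RatingsError(f"event {event_id} has no {attr} attribute set")
        return bool(value)

    pairs = [p for p in ratings.pairs() if spec.matches(flag(p[0]), flag(p[1]))]
    if not pairs:
        return KappaResult(label=spec.label, n_pairings=0, kappa=None, ci=None, empty=True)
    if len(pairs) < 2:
        return KappaResult(
            label=spec.label, n_pairings=len(pairs), kappa=None, ci=None, degenerate=True
        )
    table = rating_table_from_pairs(ratings, pairs)
    try:
        kappa = fleiss_kappa(table)
        ci = fleiss_kappa_ci(table, level=level)
    except UndefinedKappaError:
        return KappaResult(
            label=spec.label, n_pairings=len(pairs), kappa=None, ci=None, degenerate=True
        )
    return KappaResult(label=spec.label, n_pairings=len(pairs), kappa=kappa, ci=ci)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool | None = None,
) -> SpearmanResult:
    """Spearman rank correlation with average-rank ties.

    p comes from the t approximation; for n <= 10 an exact permutation p is
    available with ``exact=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero variance in one of the vectors; rho undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    n = len(x)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        # permutation distribution of |rho| under exchangeability
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return SpearmanResult(rho=rho, p_value=count / total)

    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p_value=min(1.0, p))
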