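"""Synthetic inputs with known ground truth for every pipeline stage.

Generates site deployment schedules, site-day detection histories from a
Poisson log-linear model with random intercepts, latent individual
identities with per-event attributes, multi-rater pairwise verdicts under a
confusion model, and photo streams whose regrouping reproduces the source
events exactly.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .events import Behavior, PhotoRecord, SiteDeployment
from .glmm import ModelSpec, build_design, season_of
from .ratings import DIFFERENT, SAME, PairRatingSet

__all__ = [
    "RaterModel",
    "SimScenario",
    "RatedEvent",
    "simulate_deployments",
    "simulate_detection_history",
    "simulate_identities",
    "simulate_ratings",
    "simulate_photo_stream",
    "default_raters",
]

_UTC = timezone.utc


@dataclass
class RaterModel:
    """Error model for one rater judging pairings.

    ``attribute_modifiers`` maps ``(attribute, mode)`` pairing-attribute keys
    (mode in {both, neither, mixed}) to multiplicative factors
    ``(split_factor, merge_factor)`` on the two error probabilities.  By
    default a mixed pinnae-damage pairing forces the false-merge rate to
    zero (such pairings are unmistakably "different").
    """

    rater_id: str
    p_false_split: float = 0.1
    p_false_merge: float = 0.05
    attribute_modifiers: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {("pinnae_damage", "mixed"): (1.0, 0.0)}
    )

    def __post_init__(self) -> None:
        for p in (self.p_false_split, self.p_false_merge):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"error probability {p} outside [0, 1]")
        for factors in self.attribute_modifiers.values():
            if any(f < 0 for f in factors):
                raise ValueError("attribute modifiers must be nonnegative")

    def error_probs(self, attrs_a: dict, attrs_b: dict) -> tuple[float, float]:
        p_split, p_merge = self.p_false_split, self.p_false_merge
        for (attr, mode), (f_split, f_merge) in self.attribute_modifiers.items():
            a, b = bool(attrs_a[attr]), bool(attrs_b[attr])
            matched = (
                (mode == "both" and a and b)
                or (mode == "neither" and not a and not b)
                or (mode == "mixed" and a != b)
            )
            if matched:
                p_split *= f_split
                p_merge *= f_merge
        return min(1.0, p_split), min(1.0, p_merge)


def default_raters(n: int = 5, p_false_split: float = 0.1, p_false_merge: float = 0.05) -> list[RaterModel]:
    return [
        RaterModel(rater_id=f"R{i+1}", p_false_split=p_false_split, p_false_merge=p_false_merge)
        for i in range(n)
    ]


@dataclass
class SimScenario:
    """Study-scale parameters; defaults mirror a season-long deployment
    (61 sites, 13,375 camera-trap days, 208 events, 16-event rating subset)."""

    seed: int = 0
    n_sites: int = 61
    total_ct_days: int = 13375
    acd_fraction: float = 0.5
    scrape_fraction: float = 0.4
    start_date: date = date(2018, 6, 1)
    lure_interval_days: int = 30
    # GLMM truth: named fixed-effect coefficients on the model (scaled) scale
    glmm_intercept: float = np.log(0.015)
    glmm_betas: dict[str, float] = field(default_factory=dict)
    re_sds: dict[str, float] = field(default_factory=lambda: {"site": 0.3, "season": 0.2, "year": 0.1})
    # identity / rating truth
    n_events: int = 208
    n_individuals: int = 7
    n_rated_events: int = 16
    monochrome_fraction: float = 10 / 16
    night_fraction: float = 8 / 16
    pinnae_fraction: float = 6 / 16
    resolution_px_range: tuple[int, int] = (13_000, 110_000)

    def __post_init__(self) -> None:
        for frac in (self.acd_fraction, self.scrape_fraction, self.monochrome_fraction,
                     self.night_fraction, self.pinnae_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.n_individuals < 1 or self.n_events < self.n_individuals:
            raise ValueError("need n_events >= n_individuals >= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def simulate_deployments(scenario: SimScenario) -> list[SiteDeployment]:
    """Deterministic site table; active-day totals sum to ``total_ct_days``."""
    base, extra = divmod(scenario.total_ct_days, scenario.n_sites)
    n_acd = round(scenario.n_sites * scenario.acd_fraction)
    n_scrape = round(scenario.n_sites * scenario.scrape_fraction)
    rng = scenario.rng(salt=1)
    scrape_sites = set(rng.permutation(scenario.n_sites)[:n_scrape])
    sites = []
    for i in range(scenario.n_sites):
        n_days = base + (1 if i < extra else 0)
        start = scenario.start_date
        end = start + timedelta(days=n_days - 1)
        lure_dates = [
            start + timedelta(days=d)
            for d in range(0, n_days, scenario.lure_interval_days)
        ]
        sites.append(
            SiteDeployment(
                site_id=f"S{i+1:03d}",
                latitude=43.0 + 0.01 * i,
                longitude=-110.5 - 0.01 * i,
                has_acd=i < n_acd,
                is_scrape_site=i in scrape_sites,
                deploy_date=start,
                lure_dates=lure_dates,
                active_start=start,
                active_end=end,
            )
        )
    return sites


def _history_skeleton(sites: list[SiteDeployment]) -> pd.DataFrame:
    rows = []
    for s in sites:
        day = s.active_start
        lure_dates = sorted(s.lure_dates)
        while day <= s.active_end:
            past_lures = [d for d in lure_dates if d <= day]
            rows.append(
                {
                    "site_id": s.site_id,
                    "date": day,
                    "days_since_deploy": (day - s.deploy_date).days,
                    "days_since_lure": (day - past_lures[-1]).days if past_lures else np.nan,
                    "has_acd": s.has_acd,
                    "is_scrape": s.is_scrape_site,
                    "season": season_of(day),
                    "year": str(day.year),
                }
            )
            day += timedelta(days=1)
    frame = pd.DataFrame(rows)
    frame["days_since_lure"] = frame["days_since_lure"].fillna(0.0)
    return frame


def simulate_detection_history(scenario: SimScenario) -> tuple[pd.DataFrame, dict]:
    """Site-day counts from the Poisson log-linear truth; returns (frame, truth).

    The linear predictor applies the scenario's named betas to the same
    scaled design the fitting stage builds, plus Gaussian random-intercept
    draws per site / season / year.
    """
    sites = simulate_deployments(scenario)
    frame = _history_skeleton(sites)
    spec = ModelSpec(
        fixed_terms=list(scenario.glmm_betas),
        random_intercepts=[g for g, sd in scenario.re_sds.items() if sd > 0],
    )
    frame["count"] = 0  # placeholder so design building can see all columns
    x, names = build_design(frame, spec)
    beta = np.array([scenario.glmm_intercept] + [scenario.glmm_betas[t] for t in names[1:]])
    eta = x @ beta

    rng = scenario.rng(salt=2)
    intercepts: dict[str, dict] = {}
    group_cols = {"site": "site_id", "season": "season", "year": "year"}
    for g in spec.random_intercepts:
        levels = sorted(frame[group_cols[g]].unique())
        draws = rng.normal(0.0, scenario.re_sds[g], size=len(levels))
        intercepts[g] = dict(zip(levels, draws))
        eta = eta + frame[group_cols[g]].map(intercepts[g]).to_numpy()

    frame["count"] = rng.poisson(np.exp(eta))
    truth = {
        "intercept": scenario.glmm_intercept,
        "betas": dict(scenario.glmm_betas),
        "term_order": names,
        "re_sds": {g: scenario.re_sds[g] for g in spec.random_intercepts},
        "random_intercepts": intercepts,
        "scaling": dict(spec.scaling),
        "spec": spec,
    }
    return frame, truth


@dataclass
class RatedEvent:
    """Synthetic event carrying its latent individual and ID-relevant attributes."""

    event_id: str
    site_id: str
    start_time: datetime
    individual: str
    monochrome: bool
    flash_fired: bool
    pinnae_damage: bool
    night: bool
    resolution_px: int
    resolution_class: str = "unset"

    @property
    def ambient_light(self) -> bool:
        return not self.flash_fired

    @property
    def resolution_high(self) -> bool:
        return self.resolution_class == "high"

    def attributes(self) -> dict:
        return {
            "monochrome": self.monochrome,
            "ambient_light": self.ambient_light,
            "pinnae_damage": self.pinnae_damage,
            "resolution_high": self.resolution_high,
            "night": self.night,
        }


def simulate_identities(scenario: SimScenario) -> list[RatedEvent]:
    """Events with latent individual labels and attributes drawn per scenario.

    Every individual appears at least once; pinnae damage and face
    resolution are properties of the individual (consistent across its
    events), image attributes are per event.  Resolution classes come from
    a median split over the generated events.
    """
    rng = scenario.rng(salt=3)
    n_ev, n_ind = scenario.n_events, scenario.n_individuals
    individuals = [f"I{i+1:02d}" for i in range(n_ind)]
    assignment = list(range(n_ind)) + list(rng.integers(0, n_ind, size=n_ev - n_ind))
    rng.shuffle(assignment)

    ind_pinnae = rng.random(n_ind) < scenario.pinnae_fraction
    lo, hi = scenario.resolution_px_range
    ind_res = rng.integers(lo, hi, size=n_ind)

    events = []
    t0 = datetime(scenario.start_date.year, scenario.start_date.month, scenario.start_date.day,
                  tzinfo=_UTC)
    for i, ind_idx in enumerate(assignment):
        monochrome = bool(rng.random() < scenario.monochrome_fraction)
        # night implies IR flash / monochrome imagery in practice
        night = monochrome and bool(rng.random() < scenario.night_fraction / max(scenario.monochrome_fraction, 1e-9))
        events.append(
            RatedEvent(
                event_id=f"E{i+1:04d}",
                site_id=f"S{(i % scenario.n_sites) + 1:03d}",
                start_time=t0 + timedelta(hours=6 * i),
                individual=individuals[ind_idx],
                monochrome=monochrome,
                flash_fired=monochrome,
                pinnae_damage=bool(ind_pinnae[ind_idx]),
                night=night,
                resolution_px=int(ind_res[ind_idx] + rng.integers(0, 500)),
            )
        )
    med = float(np.median([e.resolution_px for e in events]))
    for e in events:
        e.resolution_class = "low" if e.resolution_px <= med else "high"
    return events


def simulate_ratings(
    events: list[RatedEvent],
    raters: list[RaterModel],
    seed: int = 0,
) -> PairRatingSet:
    """Pairwise verdicts under the confusion model, independent across cells."""
    if not raters:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    by_id = {e.event_id: e for e in events}
    ids = sorted(by_id)
    verdicts = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ev_a, ev_b = by_id[a], by_id[b]
            truly_same = ev_a.individual == ev_b.individual
            for rater in raters:
                p_split, p_merge = rater.error_probs(ev_a.attributes(), ev_b.attributes())
                flip = rng.random() < (p_split if truly_same else p_merge)
                verdict = (DIFFERENT if truly_same else SAME) if flip else (SAME if truly_same else DIFFERENT)
                verdicts[((a, b), rater.rater_id)] = verdict
    return PairRatingSet(event_ids=ids, raters=[r.rater_id for r in raters], verdicts=verdicts)


def simulate_photo_stream(
    events: list[RatedEvent],
    photos_per_event: int = 5,
    intra_gap_minutes: float = 5.0,
    independence_gap_minutes: float = 30.0,
    seed: int = 0,
) -> list[PhotoRecord]:
    """Photos whose regrouping under the gap rule reproduces the events.

    Within an event photos are spaced ``intra_gap_minutes`` apart; the
    schedule is validated so that consecutive events at one site are
    separated by strictly more than the independence gap.
    """
    if intra_gap_minutes >= independence_gap_minutes:
        raise ValueError("intra-event gap must be smaller than the independence gap")
    if photos_per_event < 1:
        raise ValueError("need at least one photo per event")
    span = (photos_per_event - 1) * intra_gap_minutes
    by_site: dict[str, list[RatedEvent]] = {}
    for e in sorted(events, key=lambda e: (e.site_id, e.start_time)):
        by_site.setdefault(e.site_id, []).append(e)
    for site, evs in by_site.items():
        for prev, nxt in zip(evs, evs[1:]):
            gap = (nxt.start_time - prev.start_time).total_seconds() / 60.0 - span
            if gap <= independence_gap_minutes:
                raise ValueError(
                    f"events {prev.event_id} and {nxt.event_id} at site {site} "
                    "violate the independence gap"
                )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    photos = []
    for e in events:
        face_idx = int(rng.integers(0, photos_per_event))
        for k in range(photos_per_event):
            has_face = k == face_idx
            photos.append(
                PhotoRecord(
                    site_id=e.site_id,
                    timestamp=e.start_time + timedelta(minutes=k * intra_gap_minutes),
                    is_color=not e.monochrome,
                    flash_fired=e.flash_fired,
                    face_visible=has_face,
                    face_bbox_pixels=e.resolution_px if has_face else 0,
                    behavior_code=Behavior.NONE,
                    pinnae_damage=e.pinnae_damage if has_face else False,
                )
            )
    return photos
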