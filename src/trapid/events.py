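"""Detection-event construction from raw camera-trap photo records.

Photos from one site are chained into an independent detection event while
consecutive gaps stay within the independence interval (default 30 min,
strict ``>`` starts a new event).  Per-event attributes (face capture,
behavior, night/day, image type, face resolution) are aggregated from the
constituent photos.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

from .solar import ASTRONOMICAL_TWILIGHT_DEG, solar_elevation

__all__ = [
    "Behavior",
    "ResolutionClass",
    "PhotoRecord",
    "DetectionEvent",
    "SiteDeployment",
    "InputError",
    "group_events",
    "classify_night",
    "assign_resolution_class",
    "midpoint_median",
]

DEFAULT_GAP_MINUTES = 30.0


class InputError(ValueError):
    """Raised for malformed or inconsistent input records."""


class Behavior(str, enum.Enum):
    RETREAT = "retreat"
    CURIOSITY = "curiosity"
    LOOK_ONLY = "look_only"
    NONE = "none"
    UNKNOWN = "unknown"


#: Most "reactive" code wins when photos within an event disagree.
_BEHAVIOR_PRECEDENCE = [
    Behavior.RETREAT,
    Behavior.CURIOSITY,
    Behavior.LOOK_ONLY,
    Behavior.NONE,
    Behavior.UNKNOWN,
]


class ResolutionClass(str, enum.Enum):
    LOW = "low"
    HIGH = "high"
    UNSET = "unset"


@dataclass(frozen=True)
class PhotoRecord:
    """One camera-trap image."""

    site_id: str
    timestamp: datetime
    is_color: bool = False
    flash_fired: bool = False
    face_visible: bool = False
    face_bbox_pixels: int = 0
    behavior_code: Behavior = Behavior.UNKNOWN
    species: str = "puma"
    pinnae_damage: bool = False

    def __post_init__(self) -> None:
        if self.face_bbox_pixels < 0:
            raise InputError(f"negative face_bbox_pixels for photo at {self.timestamp}")
        if self.face_bbox_pixels > 0 and not self.face_visible:
            raise InputError(
                f"photo at site {self.site_id} {self.timestamp}: "
                "face_bbox_pixels > 0 requires face_visible"
            )
        if self.timestamp.tzinfo is None:
            raise InputError(
                f"photo at site {self.site_id} has naive timestamp {self.timestamp}"
            )


@dataclass
class DetectionEvent:
    """An independent detection: >=1 photos at one site within the gap rule."""

    event_id: str
    site_id: str
    start_time: datetime
    end_time: datetime
    n_photos: int
    face_captured: bool
    behavior: Behavior
    monochrome: bool
    flash_fired: bool
    pinnae_damage: bool
    face_resolution_px: int
    is_night: bool | None = None
    resolution_class: ResolutionClass = ResolutionClass.UNSET

    @property
    def ambient_light(self) -> bool:
        """True when the event was lit by ambient light only (no flash)."""
        return not self.flash_fired

    @property
    def resolution_high(self) -> bool:
        return self.resolution_class is ResolutionClass.HIGH


@dataclass
class SiteDeployment:
    """Camera-trap site metadata."""

    site_id: str
    latitude: float
    longitude: float
    has_acd: bool = False
    is_scrape_site: bool = False
    deploy_date: date | None = None
    lure_dates: list[date] = field(default_factory=list)
    active_start: date | None = None
    active_end: date | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise InputError(f"site {self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise InputError(f"site {self.site_id}: longitude {self.longitude} out of range")
        if self.active_start is not None and self.active_end is not None:
            for d in self.lure_dates:
                if not self.active_start <= d <= self.active_end:
                    raise InputError(
                        f"site {self.site_id}: lure date {d} outside active interval"
                    )


def _aggregate(event_id: str, photos: Sequence[PhotoRecord]) -> DetectionEvent:
    behavior = next(
        (b for b in _BEHAVIOR_PRECEDENCE if any(p.behavior_code is b for p in photos)),
        Behavior.UNKNOWN,
    )
    return DetectionEvent(
        event_id=event_id,
        site_id=photos[0].site_id,
        start_time=photos[0].timestamp,
        end_time=photos[-1].timestamp,
        n_photos=len(photos),
        face_captured=any(p.face_visible for p in photos),
        behavior=behavior,
        monochrome=any(not p.is_color for p in photos),
        flash_fired=any(p.flash_fired for p in photos),
        pinnae_damage=any(p.pinnae_damage for p in photos),
        face_resolution_px=max(p.face_bbox_pixels for p in photos),
    )


def group_events(
    photos: Iterable[PhotoRecord],
    gap_minutes: float = DEFAULT_GAP_MINUTES,
) -> list[DetectionEvent]:
    """Chain photos into independent detection events, per site.

    A photo joins the current event iff its gap to the *previous* photo at
    that site is <= ``gap_minutes``; a strictly larger gap starts a new
    event.  Events are returned sorted by start time (ties by site id).
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    photos = sorted(photos, key=lambda p: (p.site_id, p.timestamp))
    gap = timedelta(minutes=gap_minutes)

    events: list[DetectionEvent] = []
    current: list[PhotoRecord] = []
    for photo in photos:
        if current and (
            photo.site_id != current[-1].site_id
            or photo.timestamp - current[-1].timestamp > gap
        ):
            events.append(_aggregate("", current))
            current = []
        current.append(photo)
    if current:
        events.append(_aggregate("", current))

    events.sort(key=lambda e: (e.start_time, e.site_id))
    for i, ev in enumerate(events, start=1):
        ev.event_id = f"E{i:04d}"
    return events


def classify_night(
    event: DetectionEvent,
    site: SiteDeployment,
    threshold_deg: float = ASTRONOMICAL_TWILIGHT_DEG,
) -> bool:
    """True iff solar elevation at the event start is below the twilight threshold.

    Night is evaluated at ``start_time`` — the triggering moment.
    """
    if site.latitude is None or site.longitude is None:
        raise InputError(f"site {site.site_id}: coordinates required for night classification")
    if event.start_time.tzinfo is None:
        raise InputError(f"event {event.event_id}: start_time must be timezone-aware")
    return solar_elevation(site.latitude, site.longitude, event.start_time) < threshold_deg


def midpoint_median(values: Sequence[float]) -> float:
    """Standard midpoint median of a non-empty sequence."""
    if not values:
        raise ValueError("median of empty sequence")
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def assign_resolution_class(events: Sequence[DetectionEvent]) -> list[DetectionEvent]:
    """Median-split events on face resolution; ties at the median go to low.

    All events must carry a face (``face_resolution_px > 0``); the split is
    computed once over the full collection passed in.
    """
    missing = [e.event_id for e in events if e.face_resolution_px <= 0]
    if missing:
        raise InputError(f"events without a face capture cannot be split: {missing}")
    if not events:
        return []
    med = midpoint_median([e.face_resolution_px for e in events])
    out = []
    for e in events:
        cls = ResolutionClass.LOW if e.face_resolution_px <= med else ResolutionClass.HIGH
        out.append(replace_resolution(e, cls))
    return out


def replace_resolution(event: DetectionEvent, cls: ResolutionClass) -> DetectionEvent:
    return replace(event, resolution_class=cls)
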