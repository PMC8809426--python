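"""Delimited-text readers/writers and run configuration.

Everything is interchange-friendly CSV (UTF-8, header row, ISO-8601
timestamps).  Readers are strict by default: unknown columns, bad types and
duplicate keys are rejected with the offending row number; a lenient mode
normalizes cosmetic variation (case, surrounding whitespace) in verdicts
and booleans.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Sequence
from zoneinfo import ZoneInfo

import pandas as pd
import yaml

from .events import Behavior, DetectionEvent, InputError, PhotoRecord, ResolutionClass, SiteDeployment
from .ratings import PairRatingSet, RatingsError, ratings_from_long

logger = logging.getLogger("trapid")

__all__ = [
    "RunConfig",
    "read_photos",
    "read_sites",
    "read_ratings",
    "read_history",
    "write_events",
    "read_events",
    "write_ratings",
    "write_history",
]

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


@dataclass
class RunConfig:
    """Analysis-wide settings; round-trips through YAML unchanged."""

    photos: str | None = None
    sites: str | None = None
    ratings: str | None = None
    history: str | None = None
    out_dir: str = "results"
    timezone: str = "UTC"
    gap_minutes: float = 30.0
    twilight_threshold_deg: float = -18.0
    kappa_level: float = 0.95
    selection_alpha: float = 0.05
    seed: int = 0
    strict: bool = True
    column_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gap_minutes <= 0:
            raise InputError("gap_minutes must be positive")
        if not -90.0 <= self.twilight_threshold_deg <= 0.0:
            raise InputError("twilight threshold must be in [-90, 0] degrees")
        if not 0.0 < self.kappa_level < 1.0:
            raise InputError("kappa confidence level must be in (0, 1)")
        if not 0.0 < self.selection_alpha < 1.0:
            raise InputError("selection alpha must be in (0, 1)")
        ZoneInfo(self.timezone)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _read_csv(path: str | Path, required: Sequence[str], optional: Sequence[str] = (),
              strict: bool = True, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    unknown = [c for c in frame.columns if c not in set(required) | set(optional)]
    if unknown and strict:
        raise InputError(f"{path}: unknown columns {unknown} (strict mode)")
    if frame.empty:
        logger.warning("%s: file contains a header but no rows", path)
    logger.info("%s: read %d rows", path, len(frame))
    return frame


def _parse_bool(value: str, where: str, strict: bool) -> bool:
    text = value if strict else value.strip().lower()
    if strict and text not in _TRUE | _FALSE | {"True", "False"}:
        raise InputError(f"{where}: unparseable boolean {value!r} (strict mode)")
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise InputError(f"{where}: unparseable boolean {value!r}")


def _parse_timestamp(value: str, tz: ZoneInfo, where: str) -> datetime:
    try:
        stamp = datetime.fromisoformat(value)
    except ValueError as exc:
        raise InputError(f"{where}: unparseable timestamp {value!r}") from exc
    if stamp.tzinfo is None:
        stamp = stamp.replace(tzinfo=tz)
    return stamp.astimezone(tz)


def read_photos(path: str | Path, timezone: str = "UTC", strict: bool = True,
                column_map: dict[str, str] | None = None) -> list[PhotoRecord]:
    tz = ZoneInfo(timezone)
    frame = _read_csv(
        path,
        required=["site_id", "timestamp"],
        optional=["is_color", "flash_fired", "face_visible", "face_bbox_pixels",
                  "behavior_code", "species", "pinnae_damage"],
        strict=strict, column_map=column_map,
    )
    photos = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path} row {i}"
        d = row._asdict()
        try:
            behavior = Behavior(d.get("behavior_code", "unknown") or "unknown")
        except ValueError as exc:
            raise InputError(f"{where}: unknown behavior code {d['behavior_code']!r}") from exc
        photos.append(
            PhotoRecord(
                site_id=d["site_id"],
                timestamp=_parse_timestamp(d["timestamp"], tz, where),
                is_color=_parse_bool(d.get("is_color", "false"), where, strict),
                flash_fired=_parse_bool(d.get("flash_fired", "false"), where, strict),
                face_visible=_parse_bool(d.get("face_visible", "false"), where, strict),
                face_bbox_pixels=int(d.get("face_bbox_pixels", "0") or 0),
                behavior_code=behavior,
                species=d.get("species", "puma") or "puma",
                pinnae_damage=_parse_bool(d.get("pinnae_damage", "false"), where, strict),
            )
        )
    return photos


def read_sites(path: str | Path, strict: bool = True,
               column_map: dict[str, str] | None = None) -> list[SiteDeployment]:
    frame = _read_csv(
        path,
        required=["site_id", "latitude", "longitude"],
        optional=["has_acd", "is_scrape_site", "deploy_date", "lure_dates",
                  "active_start", "active_end"],
        strict=strict, column_map=column_map,
    )
    sites = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        d = row._asdict()
        where = f"{path} row {i}"
        if d["site_id"] in seen:
            raise InputError(f"{where}: duplicate site_id {d['site_id']!r}")
        seen.add(d["site_id"])
        lure_dates = [date.fromisoformat(s) for s in d.get("lure_dates", "").split(";") if s]
        sites.append(
            SiteDeployment(
                site_id=d["site_id"],
                latitude=float(d["latitude"]),
                longitude=float(d["longitude"]),
                has_acd=_parse_bool(d.get("has_acd", "false"), where, strict),
                is_scrape_site=_parse_bool(d.get("is_scrape_site", "false"), where, strict),
                deploy_date=date.fromisoformat(d["deploy_date"]) if d.get("deploy_date") else None,
                lure_dates=lure_dates,
                active_start=date.fromisoformat(d["active_start"]) if d.get("active_start") else None,
                active_end=date.fromisoformat(d["active_end"]) if d.get("active_end") else None,
            )
        )
    return sites


def read_ratings(path: str | Path, strict: bool = True,
                 column_map: dict[str, str] | None = None) -> PairRatingSet:
    frame = _read_csv(path, required=["event_a", "event_b", "rater", "verdict"],
                      strict=strict, column_map=column_map)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        verdict = row.verdict
        if strict:
            if verdict not in ("same", "different"):
                raise InputError(f"{path} row {i}: verdict {verdict!r} rejected (strict mode)")
        else:
            verdict = verdict.strip().lower()
        records.append((row.event_a, row.event_b, row.rater, verdict))
    try:
        return ratings_from_long(records)
    except RatingsError as exc:
        raise InputError(f"{path}: {exc}") from exc


def read_history(path: str | Path, strict: bool = True) -> pd.DataFrame:
    frame = _read_csv(
        path,
        required=["site_id", "date", "count", "days_since_deploy", "days_since_lure",
                  "has_acd", "is_scrape", "season", "year"],
        strict=strict,
    )
    out = pd.DataFrame(
        {
            "site_id": frame["site_id"],
            "date": pd.to_datetime(frame["date"]).dt.date,
            "count": frame["count"].astype(int),
            "days_since_deploy": frame["days_since_deploy"].astype(float),
            "days_since_lure": frame["days_since_lure"].astype(float),
            "has_acd": [_parse_bool(v, f"{path}", strict) for v in frame["has_acd"]],
            "is_scrape": [_parse_bool(v, f"{path}", strict) for v in frame["is_scrape"]],
            "season": frame["season"],
            "year": frame["year"],
        }
    )
    if (out["count"] < 0).any():
        raise InputError(f"{path}: negative counts present")
    return out


_EVENT_COLUMNS = [
    "event_id", "site_id", "start_time", "end_time", "n_photos", "face_captured",
    "behavior", "monochrome", "flash_fired", "pinnae_damage", "face_resolution_px",
    "is_night", "resolution_class",
]


def write_events(events: Sequence[DetectionEvent], path: str | Path,
                 header_comment: str | None = None) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "site_id": e.site_id,
                "start_time": e.start_time.isoformat(),
                "end_time": e.end_time.isoformat(),
                "n_photos": e.n_photos,
                "face_captured": e.face_captured,
                "behavior": e.behavior.value,
                "monochrome": e.monochrome,
                "flash_fired": e.flash_fired,
                "pinnae_damage": e.pinnae_damage,
                "face_resolution_px": e.face_resolution_px,
                "is_night": "" if e.is_night is None else e.is_night,
                "resolution_class": e.resolution_class.value,
            }
        )
    _write_csv(pd.DataFrame(rows, columns=_EVENT_COLUMNS), path, header_comment)


def read_events(path: str | Path, timezone: str = "UTC", strict: bool = True) -> list[DetectionEvent]:
    tz = ZoneInfo(timezone)
    frame = _read_csv(path, required=_EVENT_COLUMNS, strict=strict)
    events = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        d = row._asdict()
        where = f"{path} row {i}"
        events.append(
            DetectionEvent(
                event_id=d["event_id"],
                site_id=d["site_id"],
                start_time=_parse_timestamp(d["start_time"], tz, where),
                end_time=_parse_timestamp(d["end_time"], tz, where),
                n_photos=int(d["n_photos"]),
                face_captured=_parse_bool(d["face_captured"], where, strict),
                behavior=Behavior(d["behavior"]),
                monochrome=_parse_bool(d["monochrome"], where, strict),
                flash_fired=_parse_bool(d["flash_fired"], where, strict),
                pinnae_damage=_parse_bool(d["pinnae_damage"], where, strict),
                face_resolution_px=int(d["face_resolution_px"]),
                is_night=None if d["is_night"] == "" else _parse_bool(d["is_night"], where, strict),
                resolution_class=ResolutionClass(d["resolution_class"]),
            )
        )
    return events


def write_ratings(ratings: PairRatingSet, path: str | Path,
                  header_comment: str | None = None) -> None:
    rows = [
        {"event_a": pair[0], "event_b": pair[1], "rater": rater,
         "verdict": ratings.verdicts[(pair, rater)]}
        for pair in ratings.pairs()
        for rater in ratings.raters
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def write_history(frame: pd.DataFrame, path: str | Path,
                  header_comment: str | None = None) -> None:
    _write_csv(frame, path, header_comment)


def _write_csv(frame: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
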