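"""Threshold alerting over a geotagged sensor stream.

Software re-implementation of an in-situ IoT monitoring station's decision
logic: temperature readings tagged with a WGS84 position and a GMT
timestamp are screened against a pre-set LSAT threshold (typically in the
26–35.1 °C band associated with bloom conditions); a strict exceedance
triggers a geotagged alert carrying a browser-viewable map link, at most
once per station per GMT calendar day. The SMS transport is abstracted
behind a message-sink interface with in-memory and file implementations,
so no network is involved.

Readings outside the sensor's trusted envelope (a DHT11-class device is
specified for 0–50 °C at ±2 °C) are flagged out-of-range and excluded from
alerting rather than clamped.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Protocol, Sequence

__all__ = [
    "SensorReading",
    "AlertConfig",
    "AlertEvent",
    "AlertRecord",
    "MessageSink",
    "MemorySink",
    "FileSink",
    "parse_gga",
    "evaluate_reading",
    "format_message",
    "run_stream",
    "read_readings_csv",
]

logger = logging.getLogger(__name__)

#: Trusted measurement envelope of the DHT11-class temperature sensor (°C).
SENSOR_RANGE = (0.0, 50.0)
#: Threshold band associated with bloom conditions (°C).
THRESHOLD_BAND = (26.0, 35.1)


@dataclass(frozen=True)
class SensorReading:
    """One geotagged temperature reading (timestamps are GMT/UTC)."""

    station_id: str
    timestamp: datetime
    latitude: float
    longitude: float
    lsat: float  # °C

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))

    @property
    def in_sensor_range(self) -> bool:
        lo, hi = SENSOR_RANGE
        return lo <= self.lsat <= hi

    @property
    def gmt_day(self) -> date:
        return self.timestamp.astimezone(timezone.utc).date()


@dataclass(frozen=True)
class AlertConfig:
    """Alerting policy: strict-exceedance threshold and a daily budget."""

    threshold: float  # °C
    max_alerts_per_station_per_day: int = 1

    def __post_init__(self) -> None:
        lo, hi = THRESHOLD_BAND
        if not lo <= self.threshold <= hi:
            warnings.warn(
                f"threshold {self.threshold} °C is outside the usual "
                f"{lo}-{hi} °C bloom-alert band", stacklevel=2,
            )
        if self.max_alerts_per_station_per_day < 1:
            raise ValueError("daily alert budget must be >= 1")


@dataclass(frozen=True)
class AlertEvent:
    """A triggered, geotagged alert."""

    reading: SensorReading
    threshold: float
    message: str
    map_link: str


@dataclass
class AlertRecord:
    """Structured log entry for one emitted alert."""

    event: AlertEvent
    delivered: bool
    attempts: int

    def to_dict(self) -> dict:
        r = self.event.reading
        return {
            "station_id": r.station_id,
            "timestamp": r.timestamp.isoformat(),
            "latitude": r.latitude,
            "longitude": r.longitude,
            "lsat": r.lsat,
            "threshold": self.event.threshold,
            "message": self.event.message,
            "map_link": self.event.map_link,
            "delivered": self.delivered,
            "attempts": self.attempts,
        }


class MessageSink(Protocol):
    """Destination for alert messages (stands where an SMS gateway would)."""

    def send(self, message: str) -> None: ...


class MemorySink:
    def __init__(self) -> None:
        self.messages: list[str] = []

    def send(self, message: str) -> None:
        self.messages.append(message)


class FileSink:
    """Appends one JSON line per message."""

    def __init__(self, path) -> None:
        self.path = Path(path)

    def send(self, message: str) -> None:
        with self.path.open("a") as fh:
            fh.write(json.dumps({"message": message}) + "\n")


# ---------------------------------------------------------------------------
# NMEA GGA parsing


class GgaParseError(ValueError):
    pass


def _checksum(payload: str) -> int:
    value = 0
    for ch in payload:
        value ^= ord(ch)
    return value


def _ddmm_to_degrees(raw: str, hemi: str, degree_digits: int) -> float:
    degrees = float(raw[:degree_digits])
    minutes = float(raw[degree_digits:])
    value = degrees + minutes / 60.0
    if hemi in ("S", "W"):
        value = -value
    return value


def parse_gga(sentence: str) -> tuple[float, float]:
    """Latitude/longitude (signed WGS84 decimal degrees) from a GGA sentence.

    Latitude arrives as ddmm.mmmm and longitude as dddmm.mmmm; minutes are
    divided by 60 and the S/W hemisphere flags negate the sign. The XOR
    checksum is verified; an empty or zero-quality fix is rejected.
    """
    sentence = sentence.strip()
    if not sentence.startswith("$") or "*" not in sentence:
        raise GgaParseError("not a checksummed NMEA sentence")
    payload, _, check = sentence[1:].rpartition("*")
    try:
        expected = int(check, 16)
    except ValueError as exc:
        raise GgaParseError(f"bad checksum field {check!r}") from exc
    if _checksum(payload) != expected:
        raise GgaParseError(
            f"checksum mismatch: computed {_checksum(payload):02X}, sentence says {check}"
        )
    fields = payload.split(",")
    if not fields[0].endswith("GGA") or len(fields) < 7:
        raise GgaParseError("not a GGA sentence")
    lat_raw, lat_hemi, lon_raw, lon_hemi, quality = fields[2:7]
    if not lat_raw or not lon_raw or quality == "0":
        raise GgaParseError("empty or invalid GPS fix")
    if lat_hemi not in ("N", "S") or lon_hemi not in ("E", "W"):
        raise GgaParseError("bad hemisphere flags")
    return (
        _ddmm_to_degrees(lat_raw, lat_hemi, 2),
        _ddmm_to_degrees(lon_raw, lon_hemi, 3),
    )


# ---------------------------------------------------------------------------
# Decision logic


def _map_link(latitude: float, longitude: float) -> str:
    return f"https://maps.google.com/?q={latitude:.5f},{longitude:.5f}"


def format_message(event: AlertEvent) -> str:
    """Deterministic alert text with station, GMT time, LSAT and map link."""
    r = event.reading
    stamp = r.timestamp.astimezone(timezone.utc).strftime("%Y-%m-%d %H:%M:%S GMT")
    return (
        f"HAB ALERT [{r.station_id}] {stamp}: "
        f"LSAT {r.lsat:.2f} C exceeds threshold {event.threshold:.2f} C. "
        f"Location: {event.map_link}"
    )


def evaluate_reading(
    reading: SensorReading,
    config: AlertConfig,
    history: Sequence[AlertEvent],
) -> AlertEvent | None:
    """Alert decision for one reading, given the alerts already emitted.

    Emits iff the LSAT strictly exceeds the threshold, the reading is
    within the sensor's trusted envelope, and the station's daily budget
    (GMT calendar day) is not exhausted. Pure: ``history`` is not mutated.
    """
    if not reading.in_sensor_range:
        logger.warning(
            "reading %.2f C from %s outside sensor envelope %s; excluded",
            reading.lsat, reading.station_id, SENSOR_RANGE,
        )
        return None
    if not reading.lsat > config.threshold:
        return None
    today = reading.gmt_day
    used = sum(
        1 for ev in history
        if ev.reading.station_id == reading.station_id and ev.reading.gmt_day == today
    )
    if used >= config.max_alerts_per_station_per_day:
        return None
    link = _map_link(reading.latitude, reading.longitude)
    event = AlertEvent(reading=reading, threshold=config.threshold, message="", map_link=link)
    return AlertEvent(
        reading=reading, threshold=config.threshold,
        message=format_message(event), map_link=link,
    )


def run_stream(
    readings: Iterable[SensorReading],
    config: AlertConfig,
    sink: MessageSink,
    max_retries: int = 2,
) -> list[AlertRecord]:
    """Replay a sensor stream through the alert logic.

    Readings must be time-ordered per station (rejected with the first
    offending index otherwise). Every emitted alert is pushed to the sink
    exactly once; sink failures are retried up to ``max_retries`` times and
    then logged as undelivered. Returns the structured alert log.
    """
    readings = list(readings)
    last_seen: dict[str, datetime] = {}
    for i, r in enumerate(readings):
        prev = last_seen.get(r.station_id)
        if prev is not None and r.timestamp < prev:
            raise ValueError(f"readings not time-ordered per station: index {i}")
        last_seen[r.station_id] = r.timestamp

    history: list[AlertEvent] = []
    log: list[AlertRecord] = []
    for reading in readings:
        event = evaluate_reading(reading, config, history)
        if event is None:
            continue
        history.append(event)
        attempts = 0
        delivered = False
        while attempts <= max_retries and not delivered:
            attempts += 1
            try:
                sink.send(event.message)
                delivered = True
            except Exception as exc:  # sink failures must not stop the stream
                logger.warning("sink delivery attempt %d failed: %s", attempts, exc)
        if not delivered:
            logger.error("alert for %s undelivered after %d attempts",
                         reading.station_id, attempts)
        log.append(AlertRecord(event=event, delivered=delivered, attempts=attempts))
    return log


def read_readings_csv(path) -> list[SensorReading]:
    """Load readings from CSV columns station_id, timestamp, lat, lon, lsat_c.

    Timestamps are ISO-8601 and interpreted as GMT when naive.
    """
    out: list[SensorReading] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SensorReading(
                station_id=row["station_id"],
                timestamp=datetime.fromisoformat(row["timestamp"]),
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                lsat=float(row["lsat_c"]),
            ))
    return out
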