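"""Data model and I/O for the four-peripheral recording system.

The recording hardware consists of up to four wireless sensor peripherals —
two instrumented insoles (three force-sensitive resistors plus an IMU each)
and two instrumented crutches (uniaxial load cell plus an IMU each) — that
stream serialized JSON packets to a central unit.  The central unit
timestamps every packet on arrival with its own master clock, assembles
synchronized frames across peripherals within an adjustable timeout window,
and persists sessions as tabular CSV.

Frames missing any active peripheral within the timeout window are emitted
with ``complete=False`` so that downstream consumers (gait-phase estimation,
control logic) can refuse to act on partial sensor state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "PERIPHERAL_CHANNELS",
    "PERIPHERALS",
    "SensorPacket",
    "SensorFrame",
    "RecordingSession",
    "PacketParseError",
    "PacketSchemaError",
    "StreamOrderError",
    "CsvFormatError",
    "parse_packet",
    "assemble_frames",
    "default_timeout_window",
    "write_csv",
    "read_csv",
]

#: Channel schema per peripheral kind.  Insoles report the three FSR
#: placements (heel, first and fifth metatarsal), IMU orientation as Euler
#: angles in degrees and angular acceleration in deg/s^2; crutches report
#: the axial load-cell force in newtons plus the same IMU channels.
_INSOLE_CHANNELS = (
    "fsr_heel",
    "fsr_m1",
    "fsr_m5",
    "roll",
    "pitch",
    "yaw",
    "angacc_x",
    "angacc_y",
    "angacc_z",
)
_CRUTCH_CHANNELS = (
    "force_axial",
    "roll",
    "pitch",
    "yaw",
    "angacc_x",
    "angacc_y",
    "angacc_z",
)

PERIPHERAL_CHANNELS: dict[str, tuple[str, ...]] = {
    "left_insole": _INSOLE_CHANNELS,
    "right_insole": _INSOLE_CHANNELS,
    "left_crutch": _CRUTCH_CHANNELS,
    "right_crutch": _CRUTCH_CHANNELS,
}

PERIPHERALS = tuple(PERIPHERAL_CHANNELS)

#: Serialized floating-point values carry four decimal places end to end.
DECIMALS = 4


class PacketParseError(ValueError):
    """Raised when a raw record is not syntactically valid JSON."""


class PacketSchemaError(ValueError):
    """Raised when a packet violates the peripheral channel schema."""


class StreamOrderError(ValueError):
    """Raised when packet arrival times or frame timestamps go backwards."""


class CsvFormatError(ValueError):
    """Raised when a CSV file does not follow the session header contract."""


@dataclass(frozen=True)
class SensorPacket:
    """One deserialized JSON packet from a single peripheral."""

    peripheral_id: str
    arrival_time: float
    payload: dict[str, float]

    def __post_init__(self) -> None:
        if self.peripheral_id not in PERIPHERAL_CHANNELS:
            raise PacketSchemaError(
                f"unknown peripheral id {self.peripheral_id!r}; "
                f"expected one of {sorted(PERIPHERAL_CHANNELS)}"
            )
        if not (math.isfinite(self.arrival_time) and self.arrival_time >= 0):
            raise PacketSchemaError(
                f"arrival_time must be finite and non-negative, got {self.arrival_time}"
            )
        expected = set(PERIPHERAL_CHANNELS[self.peripheral_id])
        missing = sorted(expected - set(self.payload))
        if missing:
            raise PacketSchemaError(
                f"packet from {self.peripheral_id!r} missing channels: {missing}"
            )
        extra = sorted(set(self.payload) - expected)
        if extra:
            raise PacketSchemaError(
                f"packet from {self.peripheral_id!r} has unknown channels: {extra}"
            )
        for name, value in self.payload.items():
            if not math.isfinite(value):
                raise PacketSchemaError(f"non-finite value for channel {name!r}: {value}")


@dataclass(frozen=True)
class SensorFrame:
    """One synchronized row of all channels across the active peripherals.

    Channel names are fully qualified as ``<peripheral_id>_<channel>``
    (e.g. ``left_insole_fsr_heel``).  Missing channels of an incomplete
    frame are simply absent from :attr:`channels`, never encoded as zeros.
    """

    timestamp: float
    channels: dict[str, float]
    complete: bool


@dataclass
class RecordingSession:
    """An ordered sequence of synchronized frames plus session metadata."""

    frames: list[SensorFrame]
    nominal_rate: float
    active_peripherals: frozenset[str]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError(f"nominal_rate must be positive, got {self.nominal_rate}")
        self.active_peripherals = frozenset(self.active_peripherals)
        times = [f.timestamp for f in self.frames]
        for earlier, later in zip(times, times[1:]):
            if later <= earlier:
                raise StreamOrderError(
                    f"frame timestamps must strictly increase ({earlier} -> {later})"
                )

    @property
    def channel_names(self) -> list[str]:
        names: list[str] = []
        for pid in PERIPHERALS:
            if pid in self.active_peripherals:
                names.extend(qualified_channels(pid))
        return names

    def complete_frames(self) -> list[SensorFrame]:
        return [f for f in self.frames if f.complete]


def qualified_channels(peripheral_id: str) -> list[str]:
    """Fully qualified channel names for one peripheral."""
    return [f"{peripheral_id}_{ch}" for ch in PERIPHERAL_CHANNELS[peripheral_id]]


def default_timeout_window(nominal_rate: float) -> float:
    """Default timeout window: two nominal sample intervals.

    One missed packet from a peripheral is tolerated; two in a row mark
    the frame incomplete.
    """
    if nominal_rate <= 0:
        raise ValueError("nominal_rate must be positive")
    return 2.0 / nominal_rate


def parse_packet(raw_record: str, arrival_time: float) -> SensorPacket:
    """Deserialize one JSON packet and stamp it with the master-clock time.

    Numeric payload values are rounded to four decimal places, matching the
    wire format used to keep the wireless link efficient.

    Raises
    ------
    PacketParseError
        If the record is not valid JSON (the byte offset is reported).
    PacketSchemaError
        If the peripheral id is unknown or channels are missing/extra.
    """
    try:
        obj = json.loads(raw_record)
    except json.JSONDecodeError as exc:
        raise PacketParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(obj, dict):
        raise PacketSchemaError("packet must be a JSON object")
    if "peripheral_id" not in obj:
        raise PacketSchemaError("packet lacks a 'peripheral_id' field")
    pid = obj["peripheral_id"]
    payload: dict[str, float] = {}
    for key, value in obj.items():
        if key == "peripheral_id":
            continue
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise PacketSchemaError(f"channel {key!r} has non-numeric value {value!r}")
        payload[key] = round(float(value), DECIMALS)
    return SensorPacket(peripheral_id=pid, arrival_time=float(arrival_time), payload=payload)


def assemble_frames(
    packets: Iterable[SensorPacket],
    active_peripherals: Iterable[str],
    timeout_window: float,
) -> Iterator[SensorFrame]:
    """Group packets into synchronized frames on the master clock.

    Each frame is anchored at the earliest unconsumed packet.  The window
    closes as soon as every active peripheral has reported (the most recent
    packet per peripheral wins), or when the next packet would arrive more
    than ``timeout_window`` after the anchor — in which case the partial
    frame is emitted with ``complete=False``, the safety contract that keeps
    downstream control logic from acting on partial data.

    The frame timestamp is the anchoring packet's arrival time, so assembly
    is causal: no frame is stamped later than any packet it contains.
    """
    active = frozenset(active_peripherals)
    if not active:
        raise ValueError("active_peripherals must not be empty")
    unknown = active - set(PERIPHERAL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown peripherals in active set: {sorted(unknown)}")
    if timeout_window <= 0:
        raise ValueError(f"timeout_window must be positive, got {timeout_window}")

    latest: dict[str, SensorPacket] = {}
    anchor: float | None = None
    last_time = -math.inf

    def flush(anchor_time: float) -> SensorFrame:
        channels: dict[str, float] = {}
        for pid in sorted(latest):
            if pid not in active:
                continue
            for ch, value in latest[pid].payload.items():
                channels[f"{pid}_{ch}"] = value
        complete = active <= set(latest)
        return SensorFrame(timestamp=anchor_time, channels=channels, complete=complete)

    for pkt in packets:
        if pkt.arrival_time < last_time:
            raise StreamOrderError(
                f"packet arrival times must be non-decreasing "
                f"({last_time} -> {pkt.arrival_time})"
            )
        last_time = pkt.arrival_time
        if anchor is not None and pkt.arrival_time - anchor > timeout_window:
            yield flush(anchor)  # timed out waiting: partial frame
            latest = {}
            anchor = None
        if anchor is None:
            anchor = pkt.arrival_time
        latest[pkt.peripheral_id] = pkt  # packets ordered, last wins
        if active <= set(latest):
            yield flush(anchor)  # all peripherals reported: close early
            latest = {}
            anchor = None
    if latest and anchor is not None:
        yield flush(anchor)


_META_COLUMNS = ("timestamp", "complete")


def write_csv(session: RecordingSession, path) -> None:
    """Persist a session as CSV: header row, one row per frame, 4-decimal floats.

    Missing channels of incomplete frames become empty cells.
    """
    if not session.frames:
        raise ValueError("cannot write an empty session")
    columns = list(_META_COLUMNS) + session.channel_names
    rows = []
    for frame in session.frames:
        row: dict[str, object] = {
            "timestamp": frame.timestamp,
            "complete": frame.complete,
        }
        for name in session.channel_names:
            row[name] = frame.channels.get(name, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format=f"%.{DECIMALS}f")


def read_csv(
    path,
    nominal_rate: float = 130.0,
    metadata: Mapping[str, str] | None = None,
) -> RecordingSession:
    """Read a session written by :func:`write_csv` (column-name keyed).

    Empty cells become missing channels on the frame — never zeros — and
    non-monotonic timestamps raise :class:`StreamOrderError`.
    """
    df = pd.read_csv(path)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise CsvFormatError(f"missing required columns: {missing_meta}")
    channel_cols = [c for c in df.columns if c not in _META_COLUMNS]
    known = {name for pid in PERIPHERALS for name in qualified_channels(pid)}
    unexpected = sorted(set(channel_cols) - known)
    if unexpected:
        raise CsvFormatError(f"unexpected channel columns: {unexpected}")

    active = frozenset(
        pid
        for pid in PERIPHERALS
        if any(c.startswith(pid + "_") for c in channel_cols)
    )
    frames: list[SensorFrame] = []
    for rec in df.to_dict("records"):
        channels = {
            c: float(rec[c])
            for c in channel_cols
            if not pd.isna(rec[c])
        }
        frames.append(
            SensorFrame(
                timestamp=float(rec["timestamp"]),
                channels=channels,
                complete=bool(rec["complete"]),
            )
        )
    return RecordingSession(
        frames=frames,
        nominal_rate=nominal_rate,
        active_peripherals=active,
        metadata=dict(metadata or {}),
    )


def session_from_arrays(
    timestamps: Sequence[float],
    channel_arrays: Mapping[str, Sequence[float]],
    nominal_rate: float,
    active_peripherals: Iterable[str],
    metadata: Mapping[str, str] | None = None,
) -> RecordingSession:
    """Build a complete-frame session from dense per-channel arrays."""
    frames = []
    names = list(channel_arrays)
    for i, t in enumerate(timestamps):
        channels = {name: float(channel_arrays[name][i]) for name in names}
        frames.append(SensorFrame(timestamp=float(t), channels=channels, complete=True))
    return RecordingSession(
        frames=frames,
        nominal_rate=nominal_rate,
        active_peripherals=frozenset(active_peripherals),
        metadata=dict(metadata or {}),
    )
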