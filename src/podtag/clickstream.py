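"""Core event types and text-format I/O for click-event data.

Passive acoustic click loggers (C-POD / F-POD class instruments) store one
row per detected ultrasonic transient: its time, estimated carrier
frequency, duration in carrier cycles, and amplitude.  This module defines
the in-memory currency shared by POD-style logs, audio-derived ping lists
and the simulator (:class:`PingEvent` / :class:`ClickStream`), the
candidate tag transmission type (:class:`CodePacket`), and bit-exact
readers/writers for the click-event CSV and the packet-export text format.

Times are seconds from stream start, stored at full double precision and
serialized at 6 decimal places (1 microsecond) — lossless in practice
since pulse-position-modulation bins are millisecond-scale.  Amplitude is
a unitless linear scale; only ratios and coefficients of variation are
ever used downstream, so absolute calibration is deliberately unspecified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PingEvent",
    "ClickStream",
    "CodePacket",
    "ClickStreamError",
    "ClickStreamParseError",
    "ClickStreamValidationError",
    "read_clickstream",
    "write_clickstream",
    "write_packets_text",
    "read_packets_text",
    "CSV_HEADER",
    "PACKET_HEADER",
]

CSV_HEADER = ("time_s", "freq_khz", "n_cycles", "amplitude")

SOURCES = ("pod", "audio", "synthetic")


class ClickStreamError(Exception):
    """Base error for click-stream I/O and validation."""


class ClickStreamParseError(ClickStreamError):
    """A row of a click-event CSV or packet text file could not be parsed."""


class ClickStreamValidationError(ClickStreamError):
    """An event or packet violates a structural invariant."""


@dataclass(frozen=True)
class PingEvent:
    """One logged acoustic transient.

    Parameters
    ----------
    time_s : float
        Seconds from stream start; non-negative.
    freq_khz : float
        Estimated carrier frequency in kHz; positive.
    n_cycles : float
        Duration of the transient expressed in carrier cycles; >= 1.
    amplitude : float
        Linear amplitude in arbitrary units; positive.
    """

    time_s: float
    freq_khz: float
    n_cycles: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_s) and self.time_s >= 0):
            raise ClickStreamValidationError(
                f"time_s must be finite and >= 0, got {self.time_s!r}"
            )
        if not (math.isfinite(self.freq_khz) and self.freq_khz > 0):
            raise ClickStreamValidationError(
                f"freq_khz must be finite and > 0, got {self.freq_khz!r}"
            )
        if not (math.isfinite(self.n_cycles) and self.n_cycles >= 1):
            raise ClickStreamValidationError(
                f"n_cycles must be finite and >= 1, got {self.n_cycles!r}"
            )
        if not (math.isfinite(self.amplitude) and self.amplitude > 0):
            raise ClickStreamValidationError(
                f"amplitude must be finite and > 0, got {self.amplitude!r}"
            )


@dataclass(frozen=True)
class ClickStream:
    """Time-ordered sequence of :class:`PingEvent` with provenance.

    ``events`` are sorted by ``time_s`` (non-decreasing) and every event
    time lies within ``duration_s``.  ``source`` records where the stream
    came from: a POD-style log (``pod``), an audio detector (``audio``) or
    the simulator (``synthetic``).
    """

    events: tuple[PingEvent, ...]
    source: str = "pod"
    stream_id: str = ""
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ClickStreamValidationError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ClickStreamValidationError("events must be sorted by time_s")
        if times and times[-1] > self.duration_s:
            raise ClickStreamValidationError(
                f"event at {times[-1]} s exceeds duration_s={self.duration_s}"
            )

    @classmethod
    def from_events(
        cls,
        events: Iterable[PingEvent],
        source: str = "pod",
        stream_id: str = "",
        duration_s: float | None = None,
    ) -> "ClickStream":
        """Build a stream from events in any order; sorts and infers duration."""
        ev = tuple(sorted(events, key=lambda e: e.time_s))
        if duration_s is None:
            duration_s = ev[-1].time_s if ev else 0.0
        return cls(events=ev, source=source, stream_id=stream_id, duration_s=duration_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> list[float]:
        return [e.time_s for e in self.events]


@dataclass(frozen=True)
class CodePacket:
    """A detected candidate tag transmission: 8 ping times and a quality score.

    ``intervals_s`` are the 7 consecutive differences of ``ping_times_s``;
    ``score`` is 0-100 (high = clean detection); ``n_stray`` counts
    non-primary pings (multipath echoes and strays) that fell inside the
    packet's time span; ``amp_cv`` is the coefficient of variation of the
    8 primary ping amplitudes.
    """

    ping_times_s: tuple[float, ...]
    intervals_s: tuple[float, ...] = field(default=())
    score: float = 100.0
    n_stray: int = 0
    amp_cv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.ping_times_s) != 8:
            raise ClickStreamValidationError(
                f"a code packet carries 8 pings, got {len(self.ping_times_s)}"
            )
        diffs = tuple(
            b - a for a, b in zip(self.ping_times_s, self.ping_times_s[1:])
        )
        if any(d <= 0 for d in diffs):
            raise ClickStreamValidationError("ping times must be strictly ascending")
        if not self.intervals_s:
            object.__setattr__(self, "intervals_s", diffs)
        elif tuple(self.intervals_s) != diffs:
            raise ClickStreamValidationError(
                "intervals_s must equal consecutive ping-time differences"
            )
        if not (0.0 <= self.score <= 100.0):
            raise ClickStreamValidationError(
                f"score must lie in [0, 100], got {self.score}"
            )

    @property
    def first_ping_time_s(self) -> float:
        return self.ping_times_s[0]

    @property
    def span_s(self) -> float:
        return self.ping_times_s[-1] - self.ping_times_s[0]


def read_clickstream(path: str | Path, source_label: str = "pod") -> ClickStream:
    """Read a click-event CSV into a :class:`ClickStream`.

    The file must carry the exact header ``time_s,freq_khz,n_cycles,amplitude``
    (comma separator, decimal point, UTF-8).  Rows may appear in any order;
    the returned stream is sorted ascending by time.  ``duration_s`` is the
    maximum event time (0 for an empty file).

    Raises
    ------
    ClickStreamParseError
        On a missing/mismatched header or a non-numeric row, naming the
        1-based line number.
    ClickStreamValidationError
        When a row violates an event invariant (e.g. negative time).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if tuple(df.columns) != CSV_HEADER:
        raise ClickStreamParseError(
            f"{path}: expected header {','.join(CSV_HEADER)!r}, "
            f"got {','.join(df.columns)!r}"
        )
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            vals = [float(v) for v in row]
        except ValueError as exc:
            raise ClickStreamParseError(f"{path}: malformed row at line {i}: {exc}") from exc
        try:
            events.append(PingEvent(*vals))
        except ClickStreamValidationError as exc:
            raise ClickStreamValidationError(f"{path}: line {i}: {exc}") from exc
    return ClickStream.from_events(events, source=source_label, stream_id=path.stem)


def write_clickstream(stream: ClickStream, path: str | Path) -> None:
    """Write a stream back to the click-event CSV format (6 d.p. times)."""
    df = pd.DataFrame(
        [(e.time_s, e.freq_khz, e.n_cycles, e.amplitude) for e in stream.events],
        columns=list(CSV_HEADER),
    )
    df.to_csv(path, index=False, float_format="%.6f")


PACKET_HEADER = (
    "first_ping_time_s",
    *(f"interval_{k}_s" for k in range(1, 8)),
    "score",
)


def write_packets_text(packets: Sequence[CodePacket], path: str | Path) -> None:
    """Write packets as tab-separated text, one packet per line.

    Columns: first ping time (s), the 7 inter-ping intervals (s, 6 d.p.)
    and the quality score (1 d.p.).  This is the "simple text format"
    suitable for pasting into a spreadsheet; it round-trips through
    :func:`read_packets_text` without loss at the stated precision.
    """
    lines = ["\t".join(PACKET_HEADER)]
    for p in packets:
        fields = [f"{p.first_ping_time_s:.6f}"]
        fields += [f"{iv:.6f}" for iv in p.intervals_s]
        fields.append(f"{p.score:.1f}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_packets_text(path: str | Path) -> list[CodePacket]:
    """Read packets written by :func:`write_packets_text`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != PACKET_HEADER:
        raise ClickStreamParseError(f"{path}: missing or malformed packet header")
    packets = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ClickStreamParseError(
                f"{path}: line {i}: expected 9 tab-separated fields, got {len(parts)}"
            )
        try:
            first = float(parts[0])
            intervals = [float(v) for v in parts[1:8]]
            score = float(parts[8])
        except ValueError as exc:
            raise ClickStreamParseError(f"{path}: malformed row at line {i}: {exc}") from exc
        times = [first]
        for iv in intervals:
            times.append(times[-1] + iv)
        packets.append(CodePacket(ping_times_s=tuple(times), score=score))
    return packets
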