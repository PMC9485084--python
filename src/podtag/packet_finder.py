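"""Search a click stream for PPM code packets.

This mirrors the tag-export step of POD click-logger software: first
discard everything that cannot be a 69 kHz tag ping (band and
cycle-duration filter), then look for the tag's signature — a fixed sync
interval between the first two pings followed by at least six more pings
at data-interval spacing — while tolerating multipath echoes and stray
transients, and score each packet by how clean it is.

The search is anchored on sync pairs and extends each anchor with the
earliest admissible candidate at every step, backtracking when an early
choice cannot be completed into a full packet inside the packet-length
window.  The result for each anchor is therefore the lexicographically
smallest admissible 8-ping subsequence, which is exactly what an
exhaustive search over all admissible subsequences would select — the two
are held equivalent by a brute-force oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .clickstream import ClickStream, CodePacket, PingEvent

__all__ = [
    "FinderConfig",
    "FinderError",
    "band_cycle_filter",
    "classify_multipath",
    "score_packet",
    "find_packets",
    "MULTIPATH",
    "STRAY",
    "PRIMARY_CANDIDATE",
]

MULTIPATH = "multipath"
STRAY = "stray"
PRIMARY_CANDIDATE = "primary_candidate"


class FinderError(Exception):
    """Invalid configuration or arguments for the packet search."""


@dataclass(frozen=True)
class FinderConfig:
    """Parameters of the band filter, packet search and quality score.

    Defaults target 69 kHz V9-class tags: keep only 69-72 kHz pings of at
    least 5 carrier cycles, anchor on a 0.280 s sync interval (+/- 5 ms),
    require 6 further pings at 0.40-0.60 s spacing, and accept packets
    spanning 3.0-3.5 s.  Transients arriving within 8 ms of an accepted
    ping and weaker than it are treated as multipath echoes.  The score
    starts at 100 and loses ``stray_penalty`` per stray/multipath ping in
    the packet span plus ``amp_cv_penalty_scale`` times the coefficient of
    variation of the 8 ping amplitudes, clamped to [0, 100].
    """

    band_lo_khz: float = 69.0
    band_hi_khz: float = 72.0
    min_cycles: float = 5.0
    sync_interval_s: float = 0.280
    sync_tol_s: float = 0.005
    min_subsequent_pings: int = 6
    n_pings_per_packet: int = 8
    packet_len_min_s: float = 3.0
    packet_len_max_s: float = 3.5
    data_interval_min_s: float = 0.40
    data_interval_max_s: float = 0.60
    multipath_window_s: float = 0.008
    stray_penalty: float = 10.0
    amp_cv_penalty_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.band_lo_khz >= self.band_hi_khz:
            raise FinderError("band_lo_khz must be below band_hi_khz")
        if self.sync_tol_s <= 0:
            raise FinderError("sync_tol_s must be positive")
        if self.packet_len_min_s >= self.packet_len_max_s:
            raise FinderError("packet_len_min_s must be below packet_len_max_s")
        if self.data_interval_min_s >= self.data_interval_max_s:
            raise FinderError("data_interval_min_s must be below data_interval_max_s")
        if self.n_pings_per_packet < self.min_subsequent_pings + 2:
            raise FinderError(
                "n_pings_per_packet must cover the sync pair plus "
                "min_subsequent_pings"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FinderConfig":
        """Load a config from YAML; keys are the field names above."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FinderError(f"unknown finder config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}),
            encoding="utf-8",
        )


def band_cycle_filter(stream: ClickStream, cfg: FinderConfig | None = None) -> ClickStream:
    """Keep only events inside the tag band with enough carrier cycles.

    Retains events with ``band_lo_khz <= freq_khz <= band_hi_khz`` (both
    edges inclusive) and ``n_cycles >= min_cycles``; order is preserved.
    Idempotent, and its output is always a subsequence of its input.
    """
    cfg = cfg or FinderConfig()
    kept = tuple(
        e
        for e in stream.events
        if cfg.band_lo_khz <= e.freq_khz <= cfg.band_hi_khz
        and e.n_cycles >= cfg.min_cycles
    )
    return ClickStream(
        events=kept,
        source=stream.source,
        stream_id=stream.stream_id,
        duration_s=stream.duration_s,
    )


def classify_multipath(
    accepted_ping: PingEvent, candidate: PingEvent, cfg: FinderConfig | None = None
) -> str:
    """Label a later transient relative to the last accepted packet ping.

    ``multipath``: within ``multipath_window_s`` of the accepted ping and
    weaker than it (a delayed surface/bottom reflection).  ``stray``: gap
    below the data-interval floor but not multipath.  ``primary_candidate``
    otherwise.
    """
    cfg = cfg or FinderConfig()
    gap = candidate.time_s - accepted_ping.time_s
    if gap <= 0:
        raise FinderError(f"candidate must follow the accepted ping (gap {gap})")
    if gap <= cfg.multipath_window_s and candidate.amplitude < accepted_ping.amplitude:
        return MULTIPATH
    if gap < cfg.data_interval_min_s:
        return STRAY
    return PRIMARY_CANDIDATE


def score_packet(
    pings: "list[PingEvent] | tuple[PingEvent, ...]",
    strays_in_span: int,
    cfg: FinderConfig | None = None,
) -> float:
    """Quality score in [0, 100]: high when the detection is clean.

    ``100 - stray_penalty*strays - amp_cv_penalty_scale*CV`` clamped to
    [0, 100], where CV is the population coefficient of variation of the
    ping amplitudes.  Adding a stray, or any mean-preserving spread of the
    amplitudes, can only lower the score.
    """
    cfg = cfg or FinderConfig()
    amps = [p.amplitude for p in pings]
    mean = sum(amps) / len(amps)
    if mean <= 0:
        raise FinderError("mean ping amplitude must be positive")
    var = sum((a - mean) ** 2 for a in amps) / len(amps)
    cv = math.sqrt(var) / mean
    raw = 100.0 - cfg.stray_penalty * strays_in_span - cfg.amp_cv_penalty_scale * cv
    return min(max(raw, 0.0), 100.0)


def _complete_anchor(
    times: "list[float]", i: int, j: int, cfg: FinderConfig
) -> "list[int] | None":
    """Earliest-candidate completion of anchor (i, j) with backtracking.

    Returns the lexicographically smallest index sequence of length
    ``n_pings_per_packet`` whose consecutive gaps after the sync pair all
    lie in the data-interval window and whose total span satisfies the
    packet-length window, or ``None`` when no completion exists.
    """
    n = len(times)
    target = cfg.n_pings_per_packet
    chosen = [i, j]

    def recurse() -> "list[int] | None":
        if len(chosen) == target:
            span = times[chosen[-1]] - times[chosen[0]]
            if cfg.packet_len_min_s <= span <= cfg.packet_len_max_s:
                return list(chosen)
            return None
        last_t = times[chosen[-1]]
        remaining = target - len(chosen)
        # span feasibility prune
        max_reach = last_t + remaining * cfg.data_interval_max_s
        if max_reach - times[chosen[0]] < cfg.packet_len_min_s:
            return None
        for k in range(chosen[-1] + 1, n):
            gap = times[k] - last_t
            if gap > cfg.data_interval_max_s:
                break
            if gap < cfg.data_interval_min_s:
                continue
            chosen.append(k)
            out = recurse()
            if out is not None:
                return out
            chosen.pop()
        return None

    return recurse()


def find_packets(stream: ClickStream, cfg: FinderConfig | None = None) -> "list[CodePacket]":
    """Find all code packets in a click stream.

    Applies :func:`band_cycle_filter` first (idempotent, so pre-filtered
    input is fine), anchors on every ping pair whose gap is within
    ``sync_tol_s`` of the sync interval, completes each anchor with the
    earliest admissible pings, and resolves overlaps earliest-anchor-wins
    (ties on first-ping time by higher score).  Multipath echoes and
    strays inside a packet's span do not break the interval chain; they
    are counted in ``n_stray`` and reduce the score.
    """
    cfg = cfg or FinderConfig()
    filtered = band_cycle_filter(stream, cfg)
    events = filtered.events
    times = [e.time_s for e in events]
    n = len(times)

    candidates: "list[CodePacket]" = []
    for i in range(n):
        for j in range(i + 1, n):
            gap = times[j] - times[i]
            if gap > cfg.sync_interval_s + cfg.sync_tol_s:
                break
            if abs(gap - cfg.sync_interval_s) > cfg.sync_tol_s:
                continue
            chosen = _complete_anchor(times, i, j, cfg)
            if chosen is None:
                continue
            chosen_set = set(chosen)
            t0, t1 = times[chosen[0]], times[chosen[-1]]
            n_stray = sum(
                1
                for k in range(n)
                if t0 <= times[k] <= t1 and k not in chosen_set
            )
            pings = [events[k] for k in chosen]
            amps = [p.amplitude for p in pings]
            mean = sum(amps) / len(amps)
            cv = math.sqrt(sum((a - mean) ** 2 for a in amps) / len(amps)) / mean
            candidates.append(
                CodePacket(
                    ping_times_s=tuple(times[k] for k in chosen),
                    score=score_packet(pings, n_stray, cfg),
                    n_stray=n_stray,
                    amp_cv=cv,
                )
            )

    # earliest anchor wins; ties on first-ping time resolved by higher score
    candidates.sort(key=lambda p: (p.first_ping_time_s, -p.score))
    accepted: "list[CodePacket]" = []
    for pkt in candidates:
        if any(
            a.ping_times_s[0] <= pkt.first_ping_time_s <= a.ping_times_s[-1]
            for a in accepted
        ):
            continue
        accepted.append(pkt)
    return accepted
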