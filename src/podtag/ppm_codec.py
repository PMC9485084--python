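"""Configurable pulse-position-modulation (PPM) codespace.

Acoustic fish tags identify themselves by the *gaps* between the pings of
a code packet: a fixed sync interval anchors the packet, and each of the
following data intervals carries one symbol as a time offset on a uniform
grid.  Manufacturer codespaces are proprietary and periodically updated,
so this module is generic: a :class:`CodeMap` describes a codespace
(sync interval, symbol grid, checksum rule) and is supplied by the user
as JSON.  A documented example codespace ships for simulation and tests.

Example codespace
-----------------
sync 0.280 s; 6 data intervals; symbol ``s`` (0..7) maps to
``0.455 + 0.008*s`` seconds; the last data symbol is a modular-sum
checksum of the preceding five; acceptance radius ``step/3``.  Full
packets span 3.010-3.346 s, inside the 3-3.5 s envelope of 69 kHz
V9-class tags.  The modular-sum checksum detects any single-symbol error
but is order-insensitive: transpositions of data symbols re-validate and
decode to a different id.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

__all__ = [
    "CodeMap",
    "DecodeResult",
    "CodecError",
    "CodeMapError",
    "encode",
    "decode",
    "load_codemap",
    "save_codemap",
    "example_codemap",
    "CHECKSUM_SUM_MOD",
]

#: The supported checksum rule: last symbol = sum of preceding symbols, mod n_symbols.
CHECKSUM_SUM_MOD = "sum_mod"


class CodecError(Exception):
    """Base error for codespace handling."""


class CodeMapError(CodecError):
    """A codemap file or definition is invalid."""


@dataclass(frozen=True)
class CodeMap:
    """A PPM codespace definition.

    Attributes
    ----------
    sync_interval_s : float
        The fixed first inter-ping gap that anchors packet detection.
    n_data_intervals : int
        Number of symbol-carrying intervals after the sync interval; the
        last one is the checksum symbol.
    base_interval_s, step_s : float
        Symbol ``s`` maps to interval ``base_interval_s + s*step_s``.
    n_symbols : int
        Alphabet size; symbols are 0..n_symbols-1.
    checksum_rule : str
        Only ``"sum_mod"`` is supported: last symbol equals the sum of the
        preceding data symbols modulo ``n_symbols``.
    max_residual_s : float
        Quantization acceptance radius; an interval further than this from
        every grid point is rejected.  Must satisfy
        ``step_s > 2*max_residual_s`` so bins cannot overlap.
    """

    name: str = "example-v9-style"
    sync_interval_s: float = 0.280
    n_data_intervals: int = 6
    base_interval_s: float = 0.455
    step_s: float = 0.008
    n_symbols: int = 8
    checksum_rule: str = CHECKSUM_SUM_MOD
    max_residual_s: float = 0.008 / 3

    def __post_init__(self) -> None:
        if self.checksum_rule != CHECKSUM_SUM_MOD:
            raise CodeMapError(
                f"unsupported checksum_rule {self.checksum_rule!r}; "
                f"only {CHECKSUM_SUM_MOD!r} is implemented"
            )
        if self.n_symbols < 2 or self.n_data_intervals < 2:
            raise CodeMapError("need n_symbols >= 2 and n_data_intervals >= 2")
        if self.step_s <= 0 or self.base_interval_s <= 0 or self.sync_interval_s <= 0:
            raise CodeMapError("intervals and step must be positive")
        if self.max_residual_s <= 0:
            raise CodeMapError("max_residual_s must be positive")
        if self.step_s <= 2 * self.max_residual_s:
            raise CodeMapError(
                f"overlapping bins: step_s={self.step_s} must exceed "
                f"2*max_residual_s={2 * self.max_residual_s}"
            )

    @property
    def n_id_symbols(self) -> int:
        """Data symbols that carry identity (the last is the checksum)."""
        return self.n_data_intervals - 1

    @property
    def id_capacity(self) -> int:
        """Number of distinct encodable tag ids."""
        return self.n_symbols**self.n_id_symbols

    @property
    def n_intervals(self) -> int:
        """Total intervals per packet: sync + data."""
        return 1 + self.n_data_intervals

    def symbol_interval(self, symbol: int) -> float:
        return self.base_interval_s + symbol * self.step_s


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of decoding one interval vector.

    ``status`` is ``"ok"`` (``tag_id`` set) or ``"no_match"`` with
    ``reason`` one of ``bad_sync``, ``off_bin``, ``bad_checksum``.
    """

    status: str
    tag_id: int | None = None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _id_to_symbols(tag_id: int, cmap: CodeMap) -> list[int]:
    symbols = []
    v = tag_id
    for _ in range(cmap.n_id_symbols):
        symbols.append(v % cmap.n_symbols)
        v //= cmap.n_symbols
    symbols.reverse()  # most-significant first
    return symbols


def _symbols_to_id(symbols: list[int], cmap: CodeMap) -> int:
    v = 0
    for s in symbols:
        v = v * cmap.n_symbols + s
    return v


def encode(tag_id: int, cmap: CodeMap) -> list[float]:
    """Encode a tag id as the packet's interval vector (sync first).

    The id is expressed base-``n_symbols`` as ``n_data_intervals - 1``
    symbols, most-significant first; the checksum symbol is appended, and
    each symbol maps onto the interval grid.  ``decode(encode(id)) == id``.
    """
    if not isinstance(tag_id, int) or tag_id < 0 or tag_id >= cmap.id_capacity:
        raise CodecError(
            f"tag_id must be an integer in [0, {cmap.id_capacity}), got {tag_id!r}"
        )
    symbols = _id_to_symbols(tag_id, cmap)
    symbols.append(sum(symbols) % cmap.n_symbols)
    return [cmap.sync_interval_s] + [cmap.symbol_interval(s) for s in symbols]


def decode(intervals: "list[float]", cmap: CodeMap) -> DecodeResult:
    """Decode an interval vector against a codespace.

    Rejects (never silently mis-decodes) unless the sync interval is
    within ``max_residual_s`` of the codespace's sync, every data interval
    quantizes onto the symbol grid within ``max_residual_s``, and the
    checksum validates.
    """
    intervals = list(intervals)
    if len(intervals) != cmap.n_intervals:
        raise CodecError(
            f"expected {cmap.n_intervals} intervals, got {len(intervals)}"
        )
    if any(iv <= 0 for iv in intervals):
        raise CodecError("intervals must be positive")
    if abs(intervals[0] - cmap.sync_interval_s) > cmap.max_residual_s:
        return DecodeResult(status="no_match", reason="bad_sync")
    symbols = []
    for iv in intervals[1:]:
        s = round((iv - cmap.base_interval_s) / cmap.step_s)
        s = min(max(s, 0), cmap.n_symbols - 1)
        if abs(iv - cmap.symbol_interval(s)) > cmap.max_residual_s:
            return DecodeResult(status="no_match", reason="off_bin")
        symbols.append(s)
    data, checksum = symbols[:-1], symbols[-1]
    if checksum != sum(data) % cmap.n_symbols:
        return DecodeResult(status="no_match", reason="bad_checksum")
    return DecodeResult(status="ok", tag_id=_symbols_to_id(data, cmap))


_REQUIRED_FIELDS = (
    "name",
    "sync_interval_s",
    "n_data_intervals",
    "base_interval_s",
    "step_s",
    "n_symbols",
    "checksum_rule",
    "max_residual_s",
)


def load_codemap(path: str | Path) -> CodeMap:
    """Load and validate a codemap from JSON; inverse of :func:`save_codemap`."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CodeMapError(f"{path}: not valid JSON: {exc}") from exc
    missing = [f for f in _REQUIRED_FIELDS if f not in raw]
    if missing:
        raise CodeMapError(f"{path}: missing codemap fields: {', '.join(missing)}")
    extra = [k for k in raw if k not in _REQUIRED_FIELDS]
    if extra:
        raise CodeMapError(f"{path}: unknown codemap fields: {', '.join(extra)}")
    return CodeMap(**raw)


def save_codemap(cmap: CodeMap, path: str | Path) -> None:
    """Write a codemap as JSON; ``load_codemap(save_codemap(m)) == m``."""
    Path(path).write_text(json.dumps(asdict(cmap), indent=2) + "\n", encoding="utf-8")


def example_codemap() -> CodeMap:
    """The documented example codespace (see module docstring)."""
    return CodeMap()
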