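"""Rebuild playable code-packet waveforms from ping intervals.

A click logger stores only event times, not audio; to decode those
detections with standard telemetry equipment (or the software codec in
:mod:`podtag.ppm_codec` via re-detection) the packet is re-synthesized:
a baseline file is created, a single-ping waveform template is pasted so
its envelope peak lands at the lead-in time (default 1000 ms, to keep the
packet clear of start-of-file artefacts), and the remaining seven pings
are pasted at the measured inter-ping intervals.  The default output is a
5 s mono file at 384 kHz.

Placement references the template's envelope peak — the same convention
the detector and simulator use — so intervals survive a reconstruction /
re-detection round trip to within one sample period plus the detector's
peak-time error.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import signal

from .audio import AudioSegment, envelope, write_wav
from .clickstream import CodePacket

__all__ = [
    "ReconstructionConfig",
    "ReconstructError",
    "reconstruct_packet_audio",
    "batch_reconstruct",
]

BASELINES = ("silence", "noise")


class ReconstructError(Exception):
    """Invalid reconstruction inputs or configuration."""


@dataclass(frozen=True)
class ReconstructionConfig:
    """Output format and baseline for packet reconstruction.

    ``baseline='noise'`` adds white Gaussian noise of RMS ``noise_rms``
    (mimicking a baseline cut from a real recording); the default is
    silence, which maximizes decode reliability and determinism.
    """

    output_rate_hz: int = 384_000
    lead_in_s: float = 1.000
    min_duration_s: float = 5.0
    baseline: str = "silence"
    noise_rms: float = 0.0
    tail_pad_s: float = 0.5

    def __post_init__(self) -> None:
        if self.lead_in_s < 0:
            raise ReconstructError("lead_in_s must be >= 0")
        if self.min_duration_s <= self.lead_in_s:
            raise ReconstructError("min_duration_s must exceed lead_in_s")
        if self.baseline not in BASELINES:
            raise ReconstructError(f"baseline must be one of {BASELINES}")
        if self.noise_rms < 0:
            raise ReconstructError("noise_rms must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReconstructionConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ReconstructError(f"unknown reconstruction config keys: {sorted(unknown)}")
        return cls(**raw)


def _resample(template: AudioSegment, rate: int) -> AudioSegment:
    if template.sample_rate_hz == rate:
        return template
    from math import gcd

    g = gcd(rate, template.sample_rate_hz)
    up, down = rate // g, template.sample_rate_hz // g
    samples = signal.resample_poly(template.samples, up, down)
    return AudioSegment(samples=samples, sample_rate_hz=rate)


def reconstruct_packet_audio(
    template: AudioSegment,
    intervals_s: Sequence[float],
    cfg: ReconstructionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AudioSegment:
    """Paste eight copies of a ping template at the given intervals.

    Ping ``k`` is placed so its envelope peak falls at
    ``lead_in_s + sum(intervals[:k])``, rounded to the nearest sample.
    The template is resampled if its rate differs from the output rate.
    Output duration is ``max(min_duration_s, lead_in + sum(intervals) +
    template duration + tail pad)``; samples are clipped to [-1, 1].

    Raises
    ------
    ReconstructError
        If the template is empty, any interval is non-positive, or the
        template is longer than the smallest interval (pings would overlap).
    """
    cfg = cfg or ReconstructionConfig()
    intervals = [float(v) for v in intervals_s]
    if template.n_samples == 0:
        raise ReconstructError("ping template is empty")
    if any(iv <= 0 for iv in intervals):
        raise ReconstructError("intervals must all be positive")
    if template.duration_s >= min(intervals):
        raise ReconstructError(
            f"template duration {template.duration_s:.4f} s would overlap "
            f"the smallest interval {min(intervals):.4f} s"
        )

    rate = cfg.output_rate_hz
    tpl = _resample(template, rate)
    peak_idx = int(np.argmax(envelope(tpl.samples)))

    total_span = sum(intervals)
    duration = max(
        cfg.min_duration_s,
        cfg.lead_in_s + total_span + tpl.duration_s + cfg.tail_pad_s,
    )
    n_out = int(round(duration * rate))

    if cfg.baseline == "noise" and cfg.noise_rms > 0:
        rng = rng or np.random.default_rng()
        out = rng.normal(0.0, cfg.noise_rms, n_out)
    else:
        out = np.zeros(n_out)

    peak_times = np.concatenate(([0.0], np.cumsum(intervals))) + cfg.lead_in_s
    for t_peak in peak_times:
        target = int(round(t_peak * rate))
        start = target - peak_idx
        stop = start + tpl.n_samples
        lo, hi = max(start, 0), min(stop, n_out)
        out[lo:hi] += tpl.samples[lo - start : hi - start]

    np.clip(out, -1.0, 1.0, out=out)
    return AudioSegment(samples=out, sample_rate_hz=rate)


def batch_reconstruct(
    packets: Sequence[CodePacket],
    template: AudioSegment,
    cfg: ReconstructionConfig | None = None,
    out_dir: str | Path = ".",
) -> "list[Path]":
    """Write one reconstructed WAV per packet into ``out_dir``.

    Files are named ``packet_<first ping time, 3 d.p.>.wav``; name
    collisions get an ``_<index>`` suffix.  Returns paths in packet order.
    """
    cfg = cfg or ReconstructionConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: "list[Path]" = []
    seen: "set[str]" = set()
    for idx, pkt in enumerate(packets):
        stem = f"packet_{pkt.first_ping_time_s:.3f}"
        name = f"{stem}.wav"
        if name in seen:
            name = f"{stem}_{idx}.wav"
        seen.add(name)
        seg = reconstruct_packet_audio(template, pkt.intervals_s, cfg)
        path = out_dir / name
        write_wav(seg, path)
        paths.append(path)
    return paths
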