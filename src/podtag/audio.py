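"""Detect tag pings in raw hydrophone audio and extract ping templates.

Any broadband recording sampled fast enough to resolve a 69 kHz carrier
(>= 140 kS/s) can be screened for tag transmissions.  The detector
automates what is otherwise done by eye on spectrograms: band-pass around
the tag carrier, take the analytic envelope, threshold it, and turn each
surviving super-threshold run into a :class:`~podtag.clickstream.PingEvent`
whose time is the envelope peak, whose amplitude is the peak envelope
value, and whose frequency is the spectral peak of the run.

The envelope-peak time convention is shared with the simulator and the
reconstruction module; pulse-position modulation only uses time
*differences*, so any convention works as long as every component agrees.

WAV files are read and written as mono 16-bit PCM (little-endian); for
multi-channel files one channel is selected on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from scipy import fft, signal
from scipy.io import wavfile

from .clickstream import ClickStream, PingEvent

__all__ = [
    "AudioSegment",
    "AudioDetectorConfig",
    "AudioError",
    "UnsupportedRateError",
    "MIN_SAMPLE_RATE_HZ",
    "read_wav",
    "write_wav",
    "validate_audio",
    "detect_pings",
    "extract_ping_template",
]

#: Minimum sample rate able to carry the 69 kHz tag band.
MIN_SAMPLE_RATE_HZ = 140_000


class AudioError(Exception):
    """Base error for audio handling."""


class UnsupportedRateError(AudioError):
    """Sample rate too low to resolve the tag carrier."""


@dataclass(frozen=True)
class AudioSegment:
    """A sampled mono waveform with rate and start offset.

    ``samples`` are finite reals in [-1, 1]; ``start_offset_s`` locates
    sample 0 on the parent recording's clock (0 for standalone files).
    """

    samples: np.ndarray
    sample_rate_hz: int
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate_hz < 1:
            raise AudioError(f"sample_rate_hz must be >= 1, got {self.sample_rate_hz}")
        if samples.ndim != 1:
            raise AudioError("AudioSegment is mono: samples must be 1-D")
        if samples.size and not np.all(np.isfinite(samples)):
            raise AudioError("samples must all be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class AudioDetectorConfig:
    """Band-pass / envelope-threshold detector parameters.

    ``envelope_threshold`` is a fraction of the segment's maximum envelope
    by default; set ``threshold_is_absolute`` to interpret it as an
    absolute envelope level instead.  Runs above threshold separated by
    less than ``merge_gap_s`` are merged; runs shorter than
    ``min_ping_duration_s`` are discarded.
    """

    center_khz: float = 69.0
    half_band_khz: float = 3.0
    envelope_threshold: float = 0.1
    threshold_is_absolute: bool = False
    min_ping_duration_s: float = 0.002
    merge_gap_s: float = 0.001

    def __post_init__(self) -> None:
        if not self.threshold_is_absolute and not (0 < self.envelope_threshold < 1):
            raise AudioError(
                "fractional envelope_threshold must lie strictly in (0, 1)"
            )
        if self.threshold_is_absolute and self.envelope_threshold <= 0:
            raise AudioError("absolute envelope_threshold must be positive")
        if self.half_band_khz <= 0 or self.center_khz <= self.half_band_khz:
            raise AudioError("need 0 < half_band_khz < center_khz")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AudioDetectorConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AudioError(f"unknown detector config keys: {sorted(unknown)}")
        return cls(**raw)


def read_wav(path: str | Path, channel: int = 0) -> AudioSegment:
    """Read a WAV file as float samples in [-1, 1], selecting one channel."""
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        data = data[:, channel]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = np.asarray(data, dtype=np.float64)
    return AudioSegment(samples=samples, sample_rate_hz=int(rate))


def write_wav(segment: AudioSegment, path: str | Path) -> None:
    """Write mono 16-bit PCM, clipping to [-1, 1]."""
    clipped = np.clip(segment.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), segment.sample_rate_hz, pcm)


def validate_audio(segment: AudioSegment) -> None:
    """Require a sample rate able to carry the tag band (>= 140 kS/s)."""
    if segment.sample_rate_hz < MIN_SAMPLE_RATE_HZ:
        raise UnsupportedRateError(
            f"sample rate {segment.sample_rate_hz} Hz is below the "
            f"minimum {MIN_SAMPLE_RATE_HZ} Hz needed to resolve the tag carrier"
        )


def bandpass_sos(cfg: AudioDetectorConfig, sample_rate_hz: int) -> np.ndarray:
    """Second-order sections of the detector's band-pass filter.

    A 4th-order Butterworth around ``center +/- half_band``; comfortably
    exceeds 40 dB rejection one octave from the centre frequency.
    """
    lo = (cfg.center_khz - cfg.half_band_khz) * 1e3
    hi = (cfg.center_khz + cfg.half_band_khz) * 1e3
    nyq = sample_rate_hz / 2
    if hi >= nyq:
        raise AudioError(
            f"band edge {hi} Hz reaches the Nyquist frequency {nyq} Hz"
        )
    return signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate_hz, output="sos")


def envelope(samples: np.ndarray) -> np.ndarray:
    """Analytic (Hilbert) envelope of a real signal.

    Computed at an FFT-friendly padded length and truncated, so the cost
    stays near n log n for any signal length.
    """
    n = samples.size
    if n == 0:
        return samples.copy()
    nfft = int(fft.next_fast_len(n))
    return np.abs(signal.hilbert(samples, N=nfft)[:n])


def _runs_above(mask: np.ndarray) -> "list[tuple[int, int]]":
    """Half-open [start, stop) index runs where mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _dominant_freq_hz(samples: np.ndarray, rate: int) -> float:
    """Spectral-peak frequency of a short run (Hann-windowed rFFT)."""
    if samples.size < 4:
        return 0.0
    nfft = max(samples.size, 8192)  # <= ~47 Hz bins at 384 kS/s
    win = samples * np.hanning(samples.size)
    spec = np.abs(np.fft.rfft(win, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    return float(freqs[int(np.argmax(spec))])


def detect_pings(
    segment: AudioSegment, cfg: AudioDetectorConfig | None = None
) -> ClickStream:
    """Detect tag-band pings in audio and return them as a click stream.

    Pipeline: band-pass to ``center +/- half_band``; Hilbert envelope;
    threshold; merge super-threshold runs separated by less than
    ``merge_gap_s``; drop runs shorter than ``min_ping_duration_s``; emit
    one event per surviving run (time = envelope peak, amplitude = peak
    envelope, frequency = spectral peak, cycles = duration x frequency).
    An all-zero signal yields an empty stream, not an error.
    """
    cfg = cfg or AudioDetectorConfig()
    validate_audio(segment)
    rate = segment.sample_rate_hz
    if segment.n_samples == 0 or not np.any(segment.samples):
        return ClickStream(
            events=(), source="audio", stream_id="", duration_s=segment.duration_s
        )

    sos = bandpass_sos(cfg, rate)
    filtered = signal.sosfiltfilt(sos, segment.samples)
    env = envelope(filtered)

    if cfg.threshold_is_absolute:
        level = cfg.envelope_threshold
    else:
        level = cfg.envelope_threshold * float(env.max())
    mask = env > level
    runs = _runs_above(mask)

    # merge runs separated by short gaps
    merge_gap = int(round(cfg.merge_gap_s * rate))
    merged: "list[tuple[int, int]]" = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    min_len = int(round(cfg.min_ping_duration_s * rate))
    events = []
    for start, stop in merged:
        if stop - start < min_len:
            continue
        peak = start + int(np.argmax(env[start:stop]))
        freq_hz = _dominant_freq_hz(filtered[start:stop], rate)
        if freq_hz <= 0:
            continue
        duration = (stop - start) / rate
        events.append(
            PingEvent(
                time_s=segment.start_offset_s + peak / rate,
                freq_khz=freq_hz / 1e3,
                n_cycles=max(duration * freq_hz, 1.0),
                amplitude=float(env[peak]),
            )
        )
    return ClickStream.from_events(
        events,
        source="audio",
        duration_s=segment.start_offset_s + segment.duration_s,
    )


def extract_ping_template(
    segment: AudioSegment, ping_time_s: float, duration_s: float
) -> AudioSegment:
    """Cut a single-ping template centred on a detected ping.

    The window ``[ping_time - duration/2, ping_time + duration/2]`` must
    lie inside the segment; the cut is returned at the source rate,
    peak-normalized to 0.9 so reconstructions never clip.
    """
    rate = segment.sample_rate_hz
    rel = ping_time_s - segment.start_offset_s
    half = duration_s / 2
    start = int(round((rel - half) * rate))
    stop = int(round((rel + half) * rate))
    if start < 0 or stop > segment.n_samples:
        raise AudioError(
            f"template window [{rel - half:.6f}, {rel + half:.6f}] s falls "
            f"outside the segment (0 to {segment.duration_s:.6f} s)"
        )
    cut = segment.samples[start:stop].copy()
    peak = np.max(np.abs(cut)) if cut.size else 0.0
    if peak == 0:
        raise AudioError("template window contains only silence")
    cut *= 0.9 / peak
    return AudioSegment(
        samples=cut,
        sample_rate_hz=rate,
        start_offset_s=segment.start_offset_s + start / rate,
    )
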