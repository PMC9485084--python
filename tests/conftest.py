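import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from podtag import (
    ClickStream,
    FinderConfig,
    PingEvent,
    encode,
    example_codemap,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def codemap():
    return example_codemap()


@pytest.fixture(scope="session")
def finder_cfg():
    return FinderConfig()


def make_clean_stream(
    intervals, start=0.0, freq_khz=69.5, n_cycles=345.0, amplitude=1.0
):
    """A noise-free stream of one packet laid out at the given intervals."""
    times = [start]
    for iv in intervals:
        times.append(times[-1] + iv)
    events = [
        PingEvent(time_s=t, freq_khz=freq_khz, n_cycles=n_cycles, amplitude=amplitude)
        for t in times
    ]
    return ClickStream.from_events(events, source="synthetic")


@pytest.fixture
def clean_packet_stream(codemap):
    """One clean encoded packet for tag id 668 starting at t = 12 s."""
    return make_clean_stream(encode(668, codemap), start=12.0)


def random_oracle_stream(rng: np.random.Generator, cfg: FinderConfig):
    """A small randomized stream exercising every packet-search code path.

    Mixes 0-2 planted packets (with intervals drawn around the admissible
    windows, sometimes deliberately out of them), multipath-like close
    pairs, and clutter both inside and outside the frequency band, capped
    at 30 events.
    """
    events = []
    t = float(rng.uniform(0, 2))
    for _ in range(int(rng.integers(0, 3))):
        if rng.random() < 0.2:  # occasionally break the sync interval
            sync = cfg.sync_interval_s + float(rng.uniform(-3, 3)) * cfg.sync_tol_s
        else:
            sync = cfg.sync_interval_s + float(rng.uniform(-0.8, 0.8)) * cfg.sync_tol_s
        times = [t, t + sync]
        for _ in range(cfg.n_pings_per_packet - 2):
            if rng.random() < 0.15:  # occasionally leave the admissible window
                gap = float(rng.uniform(0.30, 0.70))
            else:
                gap = float(rng.uniform(0.42, 0.58))
            times.append(times[-1] + gap)
        for tt in times:
            if rng.random() < 0.1:  # occasional out-of-band / short ping
                freq = float(rng.choice([68.8, 72.2]))
                cyc = float(rng.choice([3.0, 40.0]))
            else:
                freq = float(rng.uniform(69.0, 72.0))
                cyc = float(rng.choice([5.0, 40.0, 345.0]))
            events.append(
                PingEvent(
                    time_s=tt,
                    freq_khz=freq,
                    n_cycles=cyc,
                    amplitude=float(rng.uniform(0.2, 2.0)),
                )
            )
            if rng.random() < 0.2:  # multipath-like echo
                events.append(
                    PingEvent(
                        time_s=tt + float(rng.uniform(0.001, 0.01)),
                        freq_khz=freq,
                        n_cycles=cyc,
                        amplitude=float(rng.uniform(0.1, 1.5)),
                    )
                )
        t = times[-1] + float(rng.uniform(1, 3))
    n_clutter = int(rng.integers(0, 8))
    span = max(t, 10.0)
    for _ in range(n_clutter):
        events.append(
            PingEvent(
                time_s=float(rng.uniform(0, span)),
                freq_khz=float(rng.uniform(20, 160)),
                n_cycles=float(rng.uniform(1, 60)),
                amplitude=float(rng.uniform(0.1, 2.0)),
            )
        )
    events = events[:30]
    return ClickStream.from_events(events, source="synthetic")
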