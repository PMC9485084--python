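import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from podtag import (
    ClickStream,
    PingEvent,
    band_cycle_filter,
    classify_multipath,
    find_packets,
    score_packet,
)
from podtag.packet_finder import (
    MULTIPATH,
    PRIMARY_CANDIDATE,
    STRAY,
    FinderConfig,
    FinderError,
)

from .bruteforce import brute_force_packets
from .conftest import make_clean_stream, random_oracle_stream


def ev(t, f=69.5, cyc=40.0, a=1.0):
    return PingEvent(time_s=t, freq_khz=f, n_cycles=cyc, amplitude=a)


class TestBandCycleFilter:
    @pytest.mark.parametrize(
        ("freq", "cyc", "kept"),
        [
            (70.0, 5.0, True),   # minimum cycle count is inclusive
            (69.0, 40.0, True),  # lower band edge inclusive
            (72.0, 40.0, True),  # upper band edge inclusive
            (68.9, 40.0, False),
            (72.1, 40.0, False),
            (70.0, 4.0, False),
        ],
    )
    def test_boundaries(self, finder_cfg, freq, cyc, kept):
        stream = ClickStream.from_events([ev(1.0, f=freq, cyc=cyc)])
        out = band_cycle_filter(stream, finder_cfg)
        assert (len(out) == 1) is kept

    def test_subset_and_idempotent(self, finder_cfg):
        rng = np.random.default_rng(7)
        stream = random_oracle_stream(rng, finder_cfg)
        once = band_cycle_filter(stream, finder_cfg)
        twice = band_cycle_filter(once, finder_cfg)
        assert set(once.events) <= set(stream.events)
        assert twice.events == once.events


class TestClassifyMultipath:
    def test_weaker_echo_within_window(self, finder_cfg):
        a, c = ev(1.0, a=1.0), ev(1.004, a=0.5)
        assert classify_multipath(a, c, finder_cfg) == MULTIPATH

    def test_stronger_close_ping_is_stray(self, finder_cfg):
        a, c = ev(1.0, a=1.0), ev(1.004, a=1.5)
        assert classify_multipath(a, c, finder_cfg) == STRAY

    def test_data_interval_gap_is_primary(self, finder_cfg):
        a, c = ev(1.0), ev(1.455)
        assert classify_multipath(a, c, finder_cfg) == PRIMARY_CANDIDATE

    def test_non_positive_gap_rejected(self, finder_cfg):
        with pytest.raises(FinderError):
            classify_multipath(ev(1.0), ev(1.0), finder_cfg)


class TestScorePacket:
    def test_clean_packet_scores_100(self, finder_cfg):
        pings = [ev(t) for t in range(8)]
        assert score_packet(pings, 0, finder_cfg) == 100.0

    def test_two_strays_cost_twenty(self, finder_cfg):
        pings = [ev(t) for t in range(8)]
        assert score_packet(pings, 2, finder_cfg) == 80.0

    def test_amplitude_spread_penalty(self, finder_cfg):
        # amplitudes [1]*7 + [2]: population CV = 0.3307/1.125
        pings = [ev(t, a=1.0) for t in range(7)] + [ev(7, a=2.0)]
        assert score_packet(pings, 0, finder_cfg) == pytest.approx(70.6, abs=0.1)

    @given(strays=st.integers(0, 8), extra=st.integers(1, 3))
    def test_adding_strays_never_raises_score(self, finder_cfg, strays, extra):
        pings = [ev(t, a=1.0 + 0.05 * t) for t in range(8)]
        assert score_packet(pings, strays + extra, finder_cfg) <= score_packet(
            pings, strays, finder_cfg
        )

    @given(spread=st.floats(0, 0.4), more=st.floats(0.01, 0.5))
    def test_mean_preserving_spread_never_raises_score(self, finder_cfg, spread, more):
        def pings(s):
            amps = [1.0 - s] * 4 + [1.0 + s] * 4
            return [ev(t, a=a) for t, a in enumerate(amps)]

        assert score_packet(pings(spread + more), 0, finder_cfg) <= score_packet(
            pings(spread), 0, finder_cfg
        )


class TestFindPackets:
    def test_clean_default_packet(self, finder_cfg):
        stream = make_clean_stream([0.280] + [0.455] * 6)
        packets = find_packets(stream, finder_cfg)
        assert len(packets) == 1
        pkt = packets[0]
        assert pkt.intervals_s == pytest.approx([0.280] + [0.455] * 6, abs=1e-12)
        assert pkt.score == 100.0
        assert pkt.n_stray == 0

    def test_seven_pings_is_not_a_packet(self, finder_cfg):
        stream = make_clean_stream([0.280] + [0.455] * 5)  # sync pair + 5 more
        assert find_packets(stream, finder_cfg) == []

    def test_multipath_echo_tolerated_and_scored(self, finder_cfg):
        """An echo 4 ms after the second ping at 0.3x amplitude does not
        break the packet: the primary ping times are recovered, the echo
        counts as one stray, and the score drops by one stray penalty."""
        base = make_clean_stream([0.280] + [0.455] * 6)
        echo = PingEvent(time_s=0.284, freq_khz=69.5, n_cycles=40.0, amplitude=0.3)
        stream = ClickStream.from_events(list(base.events) + [echo], source="synthetic")
        packets = find_packets(stream, finder_cfg)
        assert len(packets) == 1
        pkt = packets[0]
        assert pkt.ping_times_s == tuple(e.time_s for e in base.events)
        assert pkt.n_stray == 1
        assert pkt.score == pytest.approx(90.0)

    def test_invariants_hold_on_random_streams(self, finder_cfg):
        rng = np.random.default_rng(11)
        for _ in range(50):
            stream = random_oracle_stream(rng, finder_cfg)
            for pkt in find_packets(stream, finder_cfg):
                assert len(pkt.ping_times_s) == 8
                assert abs(pkt.intervals_s[0] - finder_cfg.sync_interval_s) <= finder_cfg.sync_tol_s
                assert (
                    finder_cfg.packet_len_min_s
                    <= pkt.span_s
                    <= finder_cfg.packet_len_max_s
                )
                assert 0 <= pkt.score <= 100
                for iv in pkt.intervals_s[1:]:
                    assert (
                        finder_cfg.data_interval_min_s
                        <= iv
                        <= finder_cfg.data_interval_max_s
                    )

    def test_matches_brute_force_oracle(self, finder_cfg):
        """Exhaustive-search equivalence on 200 randomized small streams."""
        rng = np.random.default_rng(2024)
        n_nonempty = 0
        for _ in range(200):
            stream = random_oracle_stream(rng, finder_cfg)
            got = [p.ping_times_s for p in find_packets(stream, finder_cfg)]
            expected = brute_force_packets(stream, finder_cfg)
            assert got == expected
            n_nonempty += bool(expected)
        assert n_nonempty >= 20  # the generator must actually exercise packets


class TestFinderConfig:
    def test_invalid_band_rejected(self):
        with pytest.raises(FinderError):
            FinderConfig(band_lo_khz=72.0, band_hi_khz=69.0)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = FinderConfig(sync_tol_s=0.004, stray_penalty=5.0)
        p = tmp_path / "finder.yaml"
        cfg.to_yaml(p)
        assert FinderConfig.from_yaml(p) == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "finder.yaml"
        p.write_text("sync_tol_ms: 5\n")
        with pytest.raises(FinderError, match="unknown"):
            FinderConfig.from_yaml(p)
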