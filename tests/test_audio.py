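import numpy as np
import pytest
from scipy import signal

from podtag import (
    AudioDetectorConfig,
    AudioSegment,
    detect_pings,
    extract_ping_template,
    read_wav,
    validate_audio,
    write_wav,
)
from podtag.audio import AudioError, UnsupportedRateError, bandpass_sos


def tone_burst(rate, t_center, duration, freq_hz, amp=0.5, total_s=2.0, noise=0.0, seed=0):
    """A raised-cosine gated sinusoid burst centred at t_center, in noise."""
    rng = np.random.default_rng(seed)
    n = int(total_s * rate)
    out = rng.normal(0, noise, n) if noise else np.zeros(n)
    nb = int(duration * rate)
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(nb) / (nb - 1)))
    t = np.arange(nb) / rate
    burst = amp * env * np.sin(2 * np.pi * freq_hz * t)
    start = int(t_center * rate) - (nb - 1) // 2
    out[start : start + nb] += burst
    return AudioSegment(samples=np.clip(out, -1, 1), sample_rate_hz=rate)


class TestValidateAudio:
    @pytest.mark.parametrize("rate", [384_000, 144_000, 140_000])
    def test_supported_rates_pass(self, rate):
        validate_audio(AudioSegment(samples=np.zeros(10), sample_rate_hz=rate))

    def test_low_rate_rejected_naming_minimum(self):
        seg = AudioSegment(samples=np.zeros(10), sample_rate_hz=96_000)
        with pytest.raises(UnsupportedRateError, match="140000"):
            validate_audio(seg)


class TestDetectPings:
    def test_single_burst_time_and_frequency(self):
        """A 5 ms 69 kHz burst centred at 1.0025 s is found with sub-0.5 ms
        timing error and 0.5 kHz frequency error."""
        seg = tone_burst(384_000, 1.0025, 0.005, 69_000, noise=0.01)
        stream = detect_pings(seg)
        assert len(stream) == 1
        e = stream.events[0]
        assert abs(e.time_s - 1.0025) <= 0.5e-3
        assert e.freq_khz == pytest.approx(69.0, abs=0.5)
        assert e.n_cycles >= 5

    def test_noise_only_with_absolute_threshold(self):
        rng = np.random.default_rng(3)
        seg = AudioSegment(
            samples=rng.normal(0, 0.01, 384_000), sample_rate_hz=384_000
        )
        cfg = AudioDetectorConfig(envelope_threshold=0.2, threshold_is_absolute=True)
        assert len(detect_pings(seg, cfg)) == 0

    def test_two_bursts_recover_the_sync_gap(self):
        rate = 384_000
        rng = np.random.default_rng(5)
        n = int(2.0 * rate)
        out = rng.normal(0, 0.005, n)
        for tc in (0.8, 0.8 + 0.280):
            b = tone_burst(rate, tc, 0.005, 69_000, total_s=2.0).samples
            out += b
        stream = detect_pings(AudioSegment(samples=np.clip(out, -1, 1), sample_rate_hz=rate))
        assert len(stream) == 2
        gap = stream.events[1].time_s - stream.events[0].time_s
        assert gap == pytest.approx(0.280, abs=1e-3)

    def test_all_zero_signal_is_empty_not_error(self):
        seg = AudioSegment(samples=np.zeros(200_000), sample_rate_hz=384_000)
        assert len(detect_pings(seg)) == 0

    def test_low_rate_input_rejected(self):
        seg = AudioSegment(samples=np.zeros(1000), sample_rate_hz=48_000)
        with pytest.raises(UnsupportedRateError):
            detect_pings(seg)


class TestBandpassContract:
    def test_at_least_40db_rejection_one_octave_out(self):
        cfg = AudioDetectorConfig()
        rate = 384_000
        sos = bandpass_sos(cfg, rate)
        for f in (cfg.center_khz * 1e3 / 2, cfg.center_khz * 1e3 * 2):
            w, h = signal.sosfreqz(sos, worN=[2 * np.pi * f / rate])
            # sosfiltfilt applies the filter twice
            atten_db = -40 * np.log10(np.abs(h[0]) + 1e-300)
            assert atten_db >= 40


class TestExtractPingTemplate:
    def test_window_is_cut_and_normalized(self):
        seg = tone_burst(384_000, 1.0, 0.005, 69_000)
        tpl = extract_ping_template(seg, 1.0, 0.010)
        assert tpl.duration_s == pytest.approx(0.010, abs=1e-5)
        assert np.max(np.abs(tpl.samples)) == pytest.approx(0.9)

    def test_out_of_bounds_window_rejected(self):
        seg = tone_burst(384_000, 1.0, 0.005, 69_000, total_s=1.01)
        with pytest.raises(AudioError, match="outside"):
            extract_ping_template(seg, 1.005, 0.020)

    def test_template_redetected_in_isolation(self):
        seg = tone_burst(384_000, 1.0, 0.005, 69_000)
        tpl = extract_ping_template(seg, 1.0, 0.010)
        padded = AudioSegment(
            samples=np.concatenate([np.zeros(40_000), tpl.samples, np.zeros(40_000)]),
            sample_rate_hz=tpl.sample_rate_hz,
        )
        assert len(detect_pings(padded)) == 1


class TestWavIO:
    def test_roundtrip_16bit_pcm(self, tmp_path):
        seg = tone_burst(384_000, 0.5, 0.005, 69_000, total_s=1.0)
        p = tmp_path / "x.wav"
        write_wav(seg, p)
        back = read_wav(p)
        assert back.sample_rate_hz == 384_000
        assert back.n_samples == seg.n_samples
        assert np.max(np.abs(back.samples - seg.samples)) < 2 / 32768

    def test_multichannel_reads_selected_channel(self, tmp_path):
        from scipy.io import wavfile

        rate = 192_000
        left = np.zeros(1000, dtype=np.int16)
        right = (np.ones(1000) * 1000).astype(np.int16)
        wavfile.write(str(tmp_path / "st.wav"), rate, np.stack([left, right], axis=1))
        seg = read_wav(tmp_path / "st.wav", channel=1)
        assert seg.samples[0] == pytest.approx(1000 / 32768)
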