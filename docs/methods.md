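# Methods

## The signal model

A coded acoustic tag transmits a *code packet*: 8 short ultrasonic pings
(nominal 69 kHz carrier, ~5 ms each) spanning 3–3.5 s. Identity is carried
by pulse position modulation — the 7 inter-ping intervals. The first
interval is a fixed *sync* gap (0.280 s for the tag family targeted by the
defaults); the remaining 6 are data intervals drawn from a uniform symbol
grid. `podtag` treats the codespace as configuration (`CodeMap`): sync
interval, number of data intervals, base interval, grid step, alphabet
size, checksum rule and quantization acceptance radius. The shipped
example codespace uses 6 data intervals with 8 symbols mapped to
`0.455 + 0.008·s` seconds, a modular-sum checksum as the last symbol, and
an acceptance radius of `step/3` (≈ 2.67 ms), giving 8⁵ = 32 768 ids and
packet spans of 3.010–3.346 s. Real manufacturer codespaces are
proprietary and periodically updated; decoding real data requires a
user-supplied codemap JSON.

The modular-sum checksum detects every single-symbol error (any one-bin
shift changes the sum by a non-zero amount mod 8) but is order-insensitive:
transposing two data symbols re-validates and decodes to the permuted id.
This limitation is deliberate — it is the simplest rule with single-error
detection — and is documented by a test that enumerates the transposition
case.

### Decoder

`decode` rejects unless (i) the sync interval is within the acceptance
radius, (ii) every data interval quantizes onto the grid within the
radius, and (iii) the checksum validates; failures return a structured
`no_match` with reason `bad_sync`, `off_bin` or `bad_checksum`. Because
the grid step exceeds twice the radius (enforced at codemap load), no two
valid interval vectors lie within the radius of each other: the decoder
can refuse but never silently mis-decode inside its acceptance region.

## Packet search in click streams

POD-class click loggers store one row per transient (time, frequency
estimate, duration in carrier cycles, amplitude). The search has three
stages, all parameters config-exposed (`FinderConfig`):

1. **Band/cycle filter** — keep 69–72 kHz (both edges inclusive) with
   ≥ 5 cycles. The 69–72 kHz default follows the logging band observed for
   69 kHz tags on these instruments; frequency estimates sit at or above
   the carrier. (Field reports also quote "69 ± 2 kHz" for the carrier
   itself; the band is a config field for instruments that bin
   differently.)
2. **Anchored subsequence search** — every ping pair whose gap is within
   ±5 ms of the sync interval anchors a candidate. The anchor is extended
   through the remaining events, always preferring the earliest candidate
   whose gap from the previously accepted ping lies in the admissible
   data-interval window \[0.40, 0.60\] s, with backtracking when an early
   choice cannot complete into 8 pings inside the 3.0–3.5 s packet-length
   window. The result per anchor is the lexicographically smallest
   admissible 8-ping subsequence — identical to what exhaustive
   enumeration selects, which a brute-force oracle verifies on 200
   randomized streams. Backtracking (rather than one-shot greedy
   extension) is what makes that equivalence exact: all-earliest choices
   can undershoot the packet-length floor even when an admissible packet
   exists. Overlapping candidates are resolved earliest-anchor-wins, ties
   on first-ping time by higher score.
   The data-interval window is our choice consistent with 8 pings spanning
   3–3.5 s (6 data intervals averaging 0.45–0.54 s); the ±5 ms sync
   tolerance is far above logger timing jitter and far below the symbol
   grid spacing.
3. **Multipath tolerance and scoring** — transients inside a packet's span
   that are not part of the accepted 8 do not break the interval chain.
   `classify_multipath` labels a transient *multipath* when it arrives
   within 8 ms of an accepted ping and is weaker (a surface/bottom
   reflection), *stray* when it is early but not echo-like. Both kinds are
   counted in `n_stray`. The score is
   `clamp(100 − 10·n_stray − 100·CV, 0, 100)` with CV the population
   coefficient of variation of the 8 ping amplitudes — a linear-penalty
   definition of "high if the data is clean, falls with strays and
   amplitude variability"; the actual vendor-software score scale is
   unpublished, so only this qualitative behavior is reproduced, and both
   weights are config fields. Missing-ping tolerance is deliberately zero:
   packets require all 8 pings, since a 7-ping candidate cannot carry a
   verifiable code.

## Audio detection

Raw recordings need ≥ 140 kS/s to resolve the tag band (hard-checked).
The detector band-passes to 69 ± 3 kHz (4th-order Butterworth,
zero-phase forward-backward application; > 40 dB rejection one octave from
centre, verified by a frequency-response test), takes the Hilbert
envelope (computed at an FFT-friendly padded length), thresholds at a
fraction of the maximum envelope (default 0.1; an absolute level is
available for noise-floor-referenced work), merges runs separated by
< 1 ms, drops runs shorter than 2 ms, and emits one event per run: time =
envelope peak, amplitude = peak envelope, frequency = Hann-windowed
spectral peak (≈ 47 Hz resolution at 384 kS/s), cycles = duration ×
frequency.

**Ping-time convention.** Everywhere in the package a ping's time is its
*envelope peak*, not its onset — detector, simulator and reconstruction
all agree. PPM uses only time differences, so any consistent convention
yields the same intervals; the peak is robust to threshold choice, whereas
onset shifts with SNR.

## Waveform reconstruction

`reconstruct_packet_audio` rebuilds a playable packet from a single-ping
template plus 7 intervals: output at 384 kHz (resampling the template
polyphase if needed), duration `max(5 s, lead-in + span + template +
0.5 s tail)`, first ping's envelope peak at the 1000 ms lead-in (to keep
the packet clear of start-of-file artefacts) and each subsequent peak at
the cumulative intervals, rounded to the nearest sample. Templates are
peak-normalized to 0.9, so a silent-baseline reconstruction can never
clip. The baseline defaults to silence for determinism and decode
reliability; a Gaussian-noise baseline is available to mimic baselines cut
from real recordings. Round trip (reconstruct → detect → difference)
recovers intervals to within one sample period plus the detector's peak
error; in practice well under 1 ms.

## The simulator

The simulator emulates the *study conditions* of a receiver-vs-logger
field comparison, not full ocean acoustics:

* **Schedule** — one packet per transmit period (default 10 s; ranging
  tags transmit every 10 s, fish tags commonly every minute or slower),
  starting at a seeded uniform phase. Every packet that *starts* within
  the scenario duration emits all 8 pings, so the transmitted count is
  exactly `floor((duration − phase)/period) + 1`.
* **Propagation** — sonar-equation transmission loss
  `TL = k·log₁₀ r + α·r`, defaults k = 20 (spherical spreading) and
  α = 0.025 dB/m (order of magnitude for ~69 kHz seawater absorption).
  This is a monotone, tunable stand-in; real sites vary enormously with
  depth, sediment and weather, which is precisely why only scalar knobs
  are exposed.
* **Reception** — source level 147 dB re 1 µPa @ 1 m (typical for this
  tag class); a ping is logged when `SL − TL + ε ≥ threshold`, with ε a
  per-ping Gaussian dB jitter (default σ = 2 dB) standing in for fading
  and noise variability — without it detection would be a step function in
  range instead of the smooth roll-off real receivers show. Default
  profiles: 85 dB for a purpose-built receiver, 100 dB for a broadband
  click logger, which under the default propagation give detection ranges
  of roughly 400 m vs 100–200 m.
* **Logged frequency** — the logger's frequency estimate for a 69 kHz tag
  sits at or above the carrier (that is what makes a 69–72 kHz export
  filter work); the default logged estimate is 69.5 ± 0.2 kHz, shared by
  the audio synthesis so both routes' measured frequencies fall inside the
  filter band.
* **Clutter and multipath** — Poisson background clicks (default
  0.1 s⁻¹) uniform over 20–160 kHz and over a 30 dB amplitude range above
  threshold; multipath as a fixed list of (delay, relative dB) echoes per
  ping. No ray tracing, Doppler, or environmental covariates.
* **Audio route** — pings are raised-cosine (Hann) gated sinusoid bursts
  (default 5 ms) in white Gaussian noise. The full-window raised cosine
  gives the burst a unique envelope peak at its centre, which the
  peak-time convention requires; a flat-topped burst would leave the peak
  position undefined to within the flat-top width.
* **Seeding** — one master seed per scenario; `SeedSequence` children with
  fixed indices drive the schedule, clutter and audio-noise streams, so
  the click and audio routes of one scenario share identical truth ping
  times and all outputs are bit-reproducible.

### What the simulator does *not* capture

Real POD data adds frequency-sweep structure within clicks, biological
click trains (dolphin/porpoise echolocation) that are temporally clustered
rather than Poisson, clock drift, tag collisions when several fish are
present, and site-dependent propagation. Passing the simulated experiments
therefore demonstrates the *algorithmic* correctness of the
filter–search–reconstruct–decode chain and its noise/multipath tolerance,
not field-grade detection performance.

## Experiments

* **Accuracy** — 16 distinct ids sampled from the codespace, one tag at a
  time at 5 m range, clean settings (no clutter, σ = 0.5 dB jitter);
  each tag runs the full click route including reconstruction and
  re-detection. Expected outcome: 16/16 correct, zero misidentifications —
  the decoder's refuse-don't-guess design makes misidentification the
  failure mode to guard against.
* **Range** — 7 ranges (100–500 m), 10-minute streams at a 10 s transmit
  period, both receiver profiles, ≥ 3 reps (20 in the validation suite).
  The detection proportion falls with range and the high-threshold profile
  never out-ranges the low-threshold one. Because clutter-induced search
  losses occur at every range, saturated ranges are exact ties in
  expectation; the monotonicity check therefore tests for *no
  statistically significant increase* (one-sided pooled two-proportion
  comparison, z = 3) rather than comparing noisy estimates exactly.

## Numerical choices and degenerate inputs

* Times are double-precision seconds; text serialization at 6 d.p. (1 µs),
  lossless relative to millisecond PPM bins. Packet text carries 7
  intervals at 6 d.p. and the score at 1 d.p.
* Band edges and the cycle minimum are inclusive; the symbol quantizer
  rounds to the nearest bin and then applies the residual test, so an
  interval beyond the last bin fails as `off_bin` rather than wrapping.
* Empty inputs are answers, not errors: an empty click stream yields zero
  packets, an all-zero audio segment yields zero events, an empty packet
  list writes a header-only export.
* WAV I/O is mono 16-bit PCM; multi-channel recordings are read one
  selected channel at a time. Reconstruction output is clipped to [−1, 1]
  (unreachable with the normalized template and silent baseline).
* Validation-suite problem sizes: 200 randomized ≤ 30-event streams for
  the search oracle, all 32 768 ids for the codec, 50 seeded scenarios for
  route equivalence (audio at 160 kS/s, reconstruction at 192 kS/s — both
  well above the 140 kS/s floor), 20 reps × 7 ranges for the range curve.

## Known limitations

* The example checksum cannot catch symbol transpositions (documented
  above); real codespaces likely use stronger, undisclosed diagnostics.
* A clutter click that lands in-band inside a packet's data window can
  capture the earliest-candidate search and cost that packet its decode
  (the true packet is suppressed by the overlap rule). At the default
  clutter rate this costs well under 1 % of packets; raising
  `min_cycles` or narrowing the band suppresses it further.
* Single-channel processing only; no bearing estimation from towed arrays,
  no real-time streaming, and no attempt to reproduce proprietary
  deck-box quality criteria.
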