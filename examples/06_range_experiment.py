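"""Simulated detection-range comparison of two receiver profiles.

A test tag transmits every 10 s for 10 minutes at each range; the
proportion of packets recovered and correctly decoded is tabulated for a
purpose-built receiver profile (85 dB detection threshold) and a
broadband click-logger profile (100 dB).
"""

from podtag import run_range_experiment

df = run_range_experiment(reps=5, seed=31)
table = (
    df.groupby(["profile", "range_m"])["proportion"].mean().unstack(level="range_m")
)
print(table.round(3).to_string())
# the proportion falls with range for both profiles; the high-threshold
# logger profile loses the tag by ~200 m while the receiver profile holds
# detections out to roughly 400 m — the qualitative receiver-vs-POD contrast
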