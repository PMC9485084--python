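"""Simulated identification-accuracy experiment.

Sixteen distinct tags are 'lowered in turn' at close range; each one's
click stream is searched, the best packet's waveform is rebuilt from a
stored template, pings are re-detected on the reconstruction, and the
intervals are decoded.  Prints the identification tally.
"""

from podtag import run_accuracy_experiment

report = run_accuracy_experiment(n_tags=16, seed=20)
print(f"tags tested:      {report.n_tags}")
print(f"correct ids:      {report.n_correct}")
print(f"misidentified:    {report.n_misidentified}")
print(f"failed to decode: {report.n_no_match}")
print(f"undetected:       {report.n_undetected}")
# clean close-range conditions should identify all 16 tags with zero
# misidentifications — the decoder refuses rather than guesses
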