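"""Encode a tag id as ping intervals and decode it back.

A tag's identity is carried by pulse position modulation: five data
symbols (base 8) plus a modular-sum checksum, each mapped to an
inter-ping interval on an 8 ms grid above 0.455 s, behind a fixed
0.280 s sync interval.
"""

from podtag import decode, encode, example_codemap

codemap = example_codemap()

tag_id = 668
intervals = encode(tag_id, codemap)
print(f"tag {tag_id} -> intervals (s): {[round(v, 3) for v in intervals]}")
# the first value is the sync interval; the last data symbol is the checksum

result = decode(intervals, codemap)
print(f"decoded: {result.status}, tag_id={result.tag_id}")

# a 4 ms error on one interval exceeds the step/3 acceptance radius:
perturbed = list(intervals)
perturbed[3] += 0.004
print(f"perturbed by +4 ms: {decode(perturbed, codemap).status} "
      f"({decode(perturbed, codemap).reason})")
# the decoder refuses rather than risking a wrong id
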