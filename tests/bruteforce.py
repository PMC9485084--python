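"""Independent brute-force reference for the packet search.

Enumerates *every* admissible 8-element subsequence of a click stream
(exhaustive recursion, no early exit), then applies the documented
selection rule: per sync anchor keep the lexicographically smallest
subsequence, order candidates by first-ping time (ties by higher score),
and suppress anchors falling inside an already-accepted packet's span.
Used only as a test oracle for ``podtag.packet_finder.find_packets``.
"""

from podtag.clickstream import ClickStream
from podtag.packet_finder import FinderConfig, score_packet


def _admissible_subsequences(times, cfg: FinderConfig):
    """All index tuples (i0..i7) satisfying the sync, data-interval and
    packet-length windows; exhaustive, collects every solution."""
    n = len(times)
    out = []

    def extend(seq):
        if len(seq) == cfg.n_pings_per_packet:
            span = times[seq[-1]] - times[seq[0]]
            if cfg.packet_len_min_s <= span <= cfg.packet_len_max_s:
                out.append(tuple(seq))
            return
        for k in range(seq[-1] + 1, n):
            gap = times[k] - times[seq[-1]]
            if cfg.data_interval_min_s <= gap <= cfg.data_interval_max_s:
                extend(seq + [k])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(times[j] - times[i] - cfg.sync_interval_s) <= cfg.sync_tol_s:
                extend([i, j])
    return out


def brute_force_packets(stream: ClickStream, cfg: FinderConfig):
    """Reference packet set: list of ping-time tuples, in accepted order."""
    events = [
        e
        for e in stream.events
        if cfg.band_lo_khz <= e.freq_khz <= cfg.band_hi_khz
        and e.n_cycles >= cfg.min_cycles
    ]
    times = [e.time_s for e in events]
    subsequences = _admissible_subsequences(times, cfg)

    best_per_anchor = {}
    for seq in subsequences:
        anchor = (seq[0], seq[1])
        if anchor not in best_per_anchor or seq < best_per_anchor[anchor]:
            best_per_anchor[anchor] = seq

    candidates = []
    for seq in best_per_anchor.values():
        chosen = set(seq)
        t0, t1 = times[seq[0]], times[seq[-1]]
        n_stray = sum(
            1 for k in range(len(times)) if t0 <= times[k] <= t1 and k not in chosen
        )
        score = score_packet([events[k] for k in seq], n_stray, cfg)
        candidates.append((times[seq[0]], -score, tuple(times[k] for k in seq)))

    candidates.sort()
    accepted = []
    for first, _neg_score, ping_times in candidates:
        if any(a[0] <= first <= a[-1] for a in accepted):
            continue
        accepted.append(ping_times)
    return accepted
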