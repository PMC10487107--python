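"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and pysam) so that
implementation and oracle can only agree by computing the same thing.
"""

from __future__ import annotations

import re
from collections import defaultdict

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def walk_read(start: int, cigar: str, sequence: str):
    """Yield (ref_pos, base) for every aligned base of one read.

    Hand-rolled CIGAR walk: M/=/X consume both, I/S consume query only,
    D/N consume reference only, H/P consume neither.
    """
    rpos = start
    qpos = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "M=X":
            for k in range(n):
                yield rpos + k, sequence[qpos + k]
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
        # H, P: consume nothing


def brute_force_pileup(reads, contig: str) -> dict[int, dict[str, int]]:
    """Per-position base counts by walking every read and position."""
    counts: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for read in reads:
        for rpos, base in walk_read(read.start, read.cigar, read.sequence):
            counts[rpos][base.upper()] += 1
    return {pos: dict(c) for pos, c in counts.items()}


def brute_force_sites(pileup: dict[int, dict[str, int]], ref_bases: str):
    """Enumerate A>G / T>C candidate sites from raw per-position counts.

    Returns {position: (edit_type, edit_count, depth)}.
    """
    out = {}
    for pos, counts in pileup.items():
        ref = ref_bases[pos]
        depth = sum(counts.values())
        if ref == "A" and counts.get("G", 0) > 0:
            out[pos] = ("AG", counts["G"], depth)
        elif ref == "T" and counts.get("C", 0) > 0:
            out[pos] = ("TC", counts["C"], depth)
    return out


def hand_kaplan_meier(times, events):
    """Product-limit by direct enumeration over distinct event times."""
    pairs = sorted(zip(times, events))
    distinct_event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    steps = []
    for t in distinct_event_times:
        n_at_risk = sum(1 for time, _ in pairs if time >= t)
        d = sum(1 for time, e in pairs if time == t and e == 1)
        s *= 1.0 - d / n_at_risk
        steps.append((t, s, n_at_risk, d))
    return steps


def hand_logrank_chi2(times_a, events_a, times_b, events_b):
    """O/E/Var accumulation using the hypergeometric moments per table."""
    all_event_times = sorted(
        {t for t, e in zip(list(times_a) + list(times_b),
                           list(events_a) + list(events_b)) if e == 1}
    )
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in all_event_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        n = n_a + n_b
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        # hypergeometric: draw d deaths from n subjects, n_a of them in A
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += (d * (n_a / n) * (1 - n_a / n) * (n - d)) / (n - 1)
    if variance == 0:
        return 0.0
    return (observed_a - expected_a) ** 2 / variance


def hand_spearman(x, y):
    """1 - 6*sum(d^2) / (n(n^2-1)); valid only without ties."""
    n = len(x)
    rank_x = {v: i + 1 for i, v in enumerate(sorted(x))}
    rank_y = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rank_x[a] - rank_y[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def hand_paired_t(diffs):
    """t = mean(d) / (sd(d) / sqrt(n)), two-sided p from scipy's t sf."""
    import math
    from scipy import stats

    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2.0 * stats.t.sf(abs(t), df=n - 1)
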