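"""Independent brute-force oracles used by the test suite.

Each oracle restates the operation it checks from first principles in a
different style (linear scans, regex, per-window recounts) and shares no code
with the package modules it validates.
"""

from __future__ import annotations

import re
from itertools import groupby


# -- interval overlap --------------------------------------------------------

def linear_scan_overlaps(features, chrom, start, end):
    """Features overlapping [start, end] (1-based inclusive) by linear scan."""
    hits = []
    for f in features:
        if f.chrom != chrom:
            continue
        if min(f.end, end) - max(f.start, start) + 1 >= 1:
            hits.append(f)
    return sorted(hits, key=lambda f: (f.start, f.te_id))


# -- proportional counting ---------------------------------------------------

def recount_from_truth(truth_df, te_ids):
    """Copy-level counts re-accumulated directly from a truth table."""
    counts = {t: 0.0 for t in te_ids}
    for w in truth_df["expected_weights"]:
        if not w:
            continue
        for part in w.split(";"):
            te, val = part.rsplit(":", 1)
            counts[te] += float(val)
    return counts


def groupby_family_sums(copy_counts, family_of):
    """Family sums via plain dict accumulation (vs pandas groupby)."""
    out = {}
    for te_id, v in copy_counts.items():
        fam = family_of[te_id]
        out[fam] = out.get(fam, 0.0) + v
    return out


# -- HRE scanning ------------------------------------------------------------

_MODULE_RE = re.compile(r"(?=([ACGT](GAA|TTC)[ACGT]))")


def regex_modules(seq):
    """(start, orientation) of every nGAAn/nTTCn 5-mer, overlaps included."""
    return [(m.start(), m.group(2)) for m in _MODULE_RE.finditer(seq.upper())]


def greedy_modules(seq):
    """Left-to-right overlap resolution re-stated independently."""
    out = []
    blocked_until = -1
    for start, orient in regex_modules(seq):
        if start > blocked_until:
            out.append((start, orient))
            blocked_until = start + 4
    return out


def oracle_clusters(modules, max_gap=5):
    clusters = [[]]
    for m in modules:
        if clusters[-1] and m[0] - (clusters[-1][-1][0] + 5) > max_gap:
            clusters.append([])
        clusters[-1].append(m)
    return [c for c in clusters if c]


def oracle_classify(cluster):
    """Rule table re-derived from scratch over (start, orientation) pairs.

    Head-to-tail runs are found by checking every contiguous sub-run
    (quadratic, unlike the package's single pass).
    """
    n = len(cluster)
    if n == 0:
        return "NONE"
    starts = [s for s, _ in cluster]
    orients = [o for _, o in cluster]

    def is_run(i, j):  # cluster[i..j] all head-to-tail
        return all(starts[x + 1] - starts[x] == 5 for x in range(i, j))

    longest = max(
        (j - i + 1 for i in range(n) for j in range(i, n) if is_run(i, j)),
        default=1,
    )
    gaps = [starts[x + 1] - starts[x] - 5 for x in range(n - 1)]
    if longest >= 4:
        return "P4"
    if longest == 3:
        return "P3"
    if n >= 3 and longest <= 2 and 5 in gaps and len(set(orients)) == 2:
        return "GAP"
    if n >= 3 and all(g == 5 for g in gaps) and len(set(orients)) == 1:
        return "STEP"
    if n == 2 and gaps[0] == 0 and orients == ["TTC", "GAA"]:
        return "PROTO"
    return "NONE"


def oracle_scan(seq, max_gap=5, overlap_policy="greedy"):
    """Full independent scan: list of (type, first_start, last_end)."""
    mods = greedy_modules(seq) if overlap_policy == "greedy" else regex_modules(seq)
    calls = []
    for cl in oracle_clusters(mods, max_gap):
        t = oracle_classify(cl)
        if t != "NONE":
            calls.append((t, cl[0][0], cl[-1][0] + 5))
    return calls


# -- shadowing ---------------------------------------------------------------

def naive_window_identity(query_gapped, subject_gapped, window):
    """Per-anchor identity by explicit per-window recount."""
    pairs = [
        (q.upper(), s.upper())
        for q, s in zip(query_gapped, subject_gapped)
        if q != "-"
    ]
    idents = []
    for p in range(len(pairs) - window + 1):
        m = sum(
            1
            for q, s in pairs[p : p + window]
            if q == s and q in "ACGT" and s in "ACGT"
        )
        idents.append(100.0 * m / window)
    return idents


def naive_segments(idents, window, qlen, cutoff, min_len):
    """Run-length scan + extension + merge, written as an explicit loop."""
    flags = [v >= cutoff for v in idents]
    raw = []
    pos = 0
    for above, grp in groupby(flags):
        span = len(list(grp))
        if above and span >= min_len:
            raw.append((pos, min(pos + span - 1 + window, qlen)))
        pos += span
    merged = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
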