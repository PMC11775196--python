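"""Independent brute-force oracles used across the test suite.

Each oracle re-derives a quantity by the most transparent method available
(enumeration, all-pairs comparison, prefix sums by hand) and deliberately
shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def bfdr_bruteforce(avg_p, avg_spec, prey_ids, bait_ids):
    """BFDR by explicit sort and prefix sums, returned in input order."""
    idx = list(range(len(avg_p)))
    idx.sort(key=lambda i: (-avg_p[i], -avg_spec[i], prey_ids[i], bait_ids[i]))
    out = [0.0] * len(avg_p)
    running_sum = 0.0
    running_max = 0.0
    for rank, i in enumerate(idx, start=1):
        running_sum += 1.0 - avg_p[i]
        running_max = max(running_max, running_sum / rank)
        out[i] = running_max
    return out


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    current_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        current_min = min(current_min, pvals[i] * n / rank)
        adj[i] = current_min
    return adj


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by explicit summation of binomial coefficients."""
    total = math.comb(N, n)
    s = 0
    for j in range(k, min(K, n) + 1):
        s += math.comb(K, j) * math.comb(N - K, n - j)
    return s / total


def overlap_groups_quadratic(peaksets):
    """Connected overlap components by all-pairs comparison + union-find."""
    items = []
    for label, peaks in peaksets.items():
        for p in peaks:
            items.append((label, p))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][1], items[j][1]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                union(i, j)
    groups = {}
    for i, (label, _) in enumerate(items):
        groups.setdefault(find(i), set()).add(label)
    counts = {}
    for labels in groups.values():
        counts[frozenset(labels)] = counts.get(frozenset(labels), 0) + 1
    return counts


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def scan_motif_bruteforce(genome, half5="TTGGC", half3="GCCAA", spacers=range(3, 8), max_mm=1):
    """Every (chrom, start, spacer, strand) by sliding-window enumeration.

    Returns {(chrom, start, k): strand} with '+' winning duplicate keys,
    matching the merge rule (the 0-mismatch motif is its own reverse
    complement, so both strands can fire at one locus).
    """
    def forward_hits(seq, k, wlen):
        found = []
        for start in range(len(seq) - wlen + 1):
            if (
                _mismatches(seq[start : start + len(half5)], half5) <= max_mm
                and _mismatches(seq[start + len(half5) + k : start + wlen], half3) <= max_mm
            ):
                found.append(start)
        return found

    hits = {}
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        rc_seq = revcomp(seq)
        L = len(seq)
        for k in sorted(set(spacers)):
            wlen = len(half5) + k + len(half3)
            for start in forward_hits(seq, k, wlen):
                hits[(chrom, start, k)] = "+"
            # a minus-strand site is a plus-strand site of the reverse
            # complement sequence; map its start back to genome coordinates
            for start in forward_hits(rc_seq, k, wlen):
                hits.setdefault((chrom, L - start - wlen, k), "-")
    return hits
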