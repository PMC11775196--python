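"""ChIP-seq targetome construction and comparison.

Peak overlap uses the at-least-one-shared-base rule on 0-based half-open
intervals; multi-set overlap is resolved by connected components of the
overlap graph so that each physical region is counted once (the
findOverlapsOfPeaks convention).  Peak annotation is nearest-TSS with a
deterministic lexicographic tie-break.  The NFI motif scanner matches the
palindromic half-sites TTGGC / GCCAA around a degenerate spacer of variable
length, with a per-half mismatch budget; N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModelRecord, GenomicInterval

__all__ = [
    "OverlapResult",
    "MotifHit",
    "SignalMatrix",
    "overlap_peaks",
    "annotate_peaks",
    "top_targets",
    "classify_binding",
    "signal_matrix",
    "scan_motif",
    "motif_enrichment",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# overlap algebra
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Connected overlap groups of labeled peak sets.

    Each group is a maximal set of mutually-connected peaks (>= 1 shared
    base, transitively); its region is the frozenset of set labels present.
    ``region_counts`` counts groups per region, the multi-set Venn numbers.
    """

    groups: list[list[tuple[str, GenomicInterval]]]
    region_counts: dict[frozenset[str], int]

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)


def overlap_peaks(peaksets: Mapping[str, Sequence[GenomicInterval]]) -> OverlapResult:
    """Group peaks from all sets into connected overlap components."""
    tagged: list[tuple[str, GenomicInterval]] = []
    for label, peaks in peaksets.items():
        tagged.extend((label, p) for p in peaks)
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[0]))

    groups: list[list[tuple[str, GenomicInterval]]] = []
    current: list[tuple[str, GenomicInterval]] = []
    cur_chrom, cur_end = None, -1
    for label, iv in tagged:
        if current and iv.chrom == cur_chrom and iv.start < cur_end:
            current.append((label, iv))
            cur_end = max(cur_end, iv.end)
        else:
            if current:
                groups.append(current)
            current = [(label, iv)]
            cur_chrom, cur_end = iv.chrom, iv.end
    if current:
        groups.append(current)

    counts: dict[frozenset[str], int] = {}
    for g in groups:
        region = frozenset(label for label, _ in g)
        counts[region] = counts.get(region, 0) + 1
    return OverlapResult(groups=groups, region_counts=counts)


def classify_binding(
    cond_a: Sequence[GenomicInterval],
    cond_b: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Lost / shared / gained classification of condition A's peaks vs B's.

    lost: A-peaks overlapping no B-peak; shared: A-peaks overlapping at
    least one; gained: B-peaks overlapping no A-peak.  lost + shared
    partition A, so |lost| + |shared| == |A|.
    """

    def hits_any(query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]) -> list[bool]:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in subject:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        arrs = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda v: v.start)
            starts = np.array([v.start for v in ivs])
            # running max of ends lets a single bisect answer "any overlap?"
            max_ends = np.maximum.accumulate(np.array([v.end for v in ivs]))
            arrs[chrom] = (starts, max_ends)
        out = []
        for q in query:
            if q.chrom not in arrs:
                out.append(False)
                continue
            starts, max_ends = arrs[q.chrom]
            i = int(np.searchsorted(starts, q.end, side="left"))
            out.append(i > 0 and bool(max_ends[i - 1] > q.start))
        return out

    a_hits = hits_any(cond_a, cond_b)
    b_hits = hits_any(cond_b, cond_a)
    return {
        "lost": [p for p, h in zip(cond_a, a_hits) if not h],
        "shared": [p for p, h in zip(cond_a, a_hits) if h],
        "gained": [p for p, h in zip(cond_b, b_hits) if not h],
    }


# ---------------------------------------------------------------------------
# annotation and targetomes
# ---------------------------------------------------------------------------

def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModelRecord],
) -> list[str | None]:
    """Assign each peak the gene whose TSS is nearest its center.

    Ties (equidistant TSSs, or several genes sharing one TSS) resolve to the
    lexicographically smallest gene_id.  Peaks on a chromosome with no genes
    get ``None``.
    """
    per_chrom: dict[str, dict[int, str]] = {}
    for g in genes:
        best = per_chrom.setdefault(g.chrom, {})
        if g.tss not in best or g.gene_id < best[g.tss]:
            best[g.tss] = g.gene_id
    arrays: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, tss_map in per_chrom.items():
        pos = np.array(sorted(tss_map))
        ids = [tss_map[p] for p in pos]
        arrays[chrom] = (pos, ids)

    out: list[str | None] = []
    for peak in peaks:
        if peak.chrom not in arrays:
            out.append(None)
            continue
        pos, ids = arrays[peak.chrom]
        c = peak.center
        i = int(np.searchsorted(pos, c))
        candidates: list[tuple[int, str]] = []
        if i > 0:
            candidates.append((abs(c - int(pos[i - 1])), ids[i - 1]))
        if i < len(pos):
            candidates.append((abs(int(pos[i]) - c), ids[i]))
        d_min = min(d for d, _ in candidates)
        out.append(min(g for d, g in candidates if d == d_min))
    return out


def top_targets(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModelRecord],
    n: int = 500,
) -> set[str]:
    """Distinct genes annotated to the n highest-scoring peaks.

    Peaks rank by score descending with (chrom, start) ascending as the
    deterministic tie-break; unannotated peaks contribute nothing.
    """
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))[:n]
    return {g for g in annotate_peaks(ranked, genes) if g is not None}


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Binned mean coverage around peak centers, rows sorted by signal."""

    matrix: np.ndarray  # (n_peaks, n_bins)
    peaks: list[GenomicInterval]  # in row order
    bin_offsets: np.ndarray  # left edge of each bin relative to center
    profile: np.ndarray = field(init=False)  # column means
    row_order: list[int] = field(default_factory=list)  # rows as input indices

    def __post_init__(self) -> None:
        self.profile = self.matrix.mean(axis=0) if len(self.matrix) else np.zeros(0)


class _Coverage:
    """Prefix-integral view of non-overlapping (start, end, value) intervals."""

    def __init__(self, intervals: Sequence[tuple[int, int, float]]):
        ivs = sorted(intervals)
        self.starts = np.array([s for s, _, _ in ivs], dtype=float)
        self.ends = np.array([e for _, e, _ in ivs], dtype=float)
        self.vals = np.array([v for _, _, v in ivs], dtype=float)
        areas = (self.ends - self.starts) * self.vals
        self.cum = np.concatenate([[0.0], np.cumsum(areas)])

    def integral_to(self, x: np.ndarray) -> np.ndarray:
        """Integral of the coverage step function over (-inf, x]."""
        x = np.asarray(x, dtype=float)
        i = np.searchsorted(self.starts, x, side="right") - 1
        out = np.where(i >= 0, self.cum[np.maximum(i, 0)], 0.0)
        inside = i >= 0
        ii = np.maximum(i, 0)
        partial = self.vals[ii] * np.clip(np.minimum(x, self.ends[ii]) - self.starts[ii], 0, None)
        return out + np.where(inside, partial, 0.0)


def signal_matrix(
    coverage: Mapping[str, Sequence[tuple[int, int, float]]],
    peaks: Sequence[GenomicInterval],
    window: int = 5000,
    bin_width: int = 50,
    reference_order: Sequence[int] | None = None,
) -> SignalMatrix:
    """Mean coverage in fixed bins across [center - window, center + window).

    Rows are ordered by each peak's own mean signal (descending, stable) or,
    when ``reference_order`` (indices into ``peaks``) is given, by that
    ordering — the convention when one sample's heatmap is displayed
    relative to a reference sample's ranking.
    """
    if window % bin_width != 0:
        raise ValueError("bin_width must divide window")
    n_bins = 2 * window // bin_width
    offsets = -window + bin_width * np.arange(n_bins)
    covs = {chrom: _Coverage(ivs) for chrom, ivs in coverage.items()}
    mat = np.zeros((len(peaks), n_bins))
    for idx, peak in enumerate(peaks):
        cov = covs.get(peak.chrom)
        if cov is None or len(cov.starts) == 0:
            continue
        edges = peak.center + np.concatenate([offsets, [window]]).astype(float)
        integ = cov.integral_to(edges)
        mat[idx] = np.diff(integ) / bin_width
    if reference_order is not None:
        order = list(reference_order)
        if sorted(order) != list(range(len(peaks))):
            raise ValueError("reference_order must be a permutation of peak indices")
    else:
        means = mat.mean(axis=1)
        order = sorted(range(len(peaks)), key=lambda i: -means[i])
    return SignalMatrix(
        matrix=mat[order],
        peaks=[peaks[i] for i in order],
        bin_offsets=offsets,
        row_order=order,
    )


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # 0-based position of the first half-site base
    strand: str
    spacer_len: int
    n_mismatches: int
    matched_sequence: str


def _half_mismatches(arr: np.ndarray, offset: int, half: bytes, n_pos: int) -> np.ndarray:
    """Mismatch count of a fixed half-site at every window start (vectorized)."""
    mm = np.zeros(n_pos, dtype=np.int8)
    for j, ch in enumerate(half):
        mm += arr[offset + j : offset + j + n_pos] != ch
    return mm


def scan_motif(
    genome: Mapping[str, str],
    half5: str = "TTGGC",
    half3: str = "GCCAA",
    spacers: Iterable[int] = range(3, 8),
    max_mismatch_per_half: int = 1,
) -> list[MotifHit]:
    """Find half5-N{k}-half3 sites on both strands with mismatch budgets.

    A window matches the minus strand when its reverse complement matches
    the pattern.  With zero mismatches the canonical NFI motif is its own
    reverse complement, so duplicate hits at the same (chrom, start, spacer)
    are merged keeping the plus-strand record.  N matches nothing.
    """
    half5 = half5.upper()
    half3 = half3.upper()
    rc5 = reverse_complement(half5).encode()
    rc3 = reverse_complement(half3).encode()
    b5, b3 = half5.encode(), half3.encode()
    len5, len3 = len(half5), len(half3)

    hits: dict[tuple[str, int, int], MotifHit] = {}
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for k in sorted(set(spacers)):
            wlen = len5 + k + len3
            n_pos = len(arr) - wlen + 1
            if n_pos <= 0:
                continue
            mm5_f = _half_mismatches(arr, 0, b5, n_pos)
            mm3_f = _half_mismatches(arr, len5 + k, b3, n_pos)
            fwd = (mm5_f <= max_mismatch_per_half) & (mm3_f <= max_mismatch_per_half)
            # minus strand: rc(window) == pattern  <=>  window starts with
            # rc(half3) and ends with rc(half5), budgets per original half
            mm3_r = _half_mismatches(arr, 0, rc3, n_pos)
            mm5_r = _half_mismatches(arr, len3 + k, rc5, n_pos)
            rev = (mm5_r <= max_mismatch_per_half) & (mm3_r <= max_mismatch_per_half)
            for pos in np.flatnonzero(fwd):
                pos = int(pos)
                hits[(chrom, pos, k)] = MotifHit(
                    chrom, pos, "+", k, int(mm5_f[pos] + mm3_f[pos]), seq[pos : pos + wlen]
                )
            for pos in np.flatnonzero(rev):
                pos = int(pos)
                key = (chrom, pos, k)
                if key not in hits:  # + strand record wins on duplicates
                    hits[key] = MotifHit(
                        chrom, pos, "-", k, int(mm5_r[pos] + mm3_r[pos]), seq[pos : pos + wlen]
                    )
    return [hits[k] for k in sorted(hits)]


def motif_enrichment(
    peaks: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    n_shuffles: int = 100,
    seed: int = 0,
    **scan_params,
) -> dict[str, float]:
    """Fraction of peaks containing >= 1 motif hit, with an empirical p-value.

    The null re-places equal-length intervals uniformly per chromosome;
    p = (1 + #{shuffles with fraction >= observed}) / (1 + n_shuffles).
    """
    hits = scan_motif(genome, **scan_params)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {h.chrom for h in hits}:
        hs = sorted((h.start, h.start + len(h.matched_sequence)) for h in hits if h.chrom == chrom)
        starts = np.array([s for s, _ in hs])
        ends = np.array([e for _, e in hs])
        by_chrom[chrom] = (starts, ends)

    def fraction(intervals: Sequence[tuple[str, int, int]]) -> float:
        if not intervals:
            return 0.0
        n_hit = 0
        for chrom, s, e in intervals:
            if chrom not in by_chrom:
                continue
            starts, ends = by_chrom[chrom]
            lo = int(np.searchsorted(starts, s, side="left"))
            hi = int(np.searchsorted(starts, e, side="right"))
            if lo < hi and bool((ends[lo:hi] <= e).any()):
                n_hit += 1
        return n_hit / len(intervals)

    observed = fraction([(p.chrom, p.start, p.end) for p in peaks])
    rng = np.random.default_rng(seed)
    n_ge = 0
    chrom_len = {c: len(genome[c]) for c in genome}
    for _ in range(n_shuffles):
        placed = []
        for p in peaks:
            width = p.end - p.start
            L = chrom_len.get(p.chrom, 0)
            if L < width:
                continue
            s = int(rng.integers(0, L - width + 1))
            placed.append((p.chrom, s, s + width))
        if fraction(placed) >= observed:
            n_ge += 1
    p_emp = (1 + n_ge) / (1 + n_shuffles)
    return {"fraction_with_hit": observed, "p_empirical": p_emp, "n_hits_genome": float(len(hits))}
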