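"""Interactome comparison: Venn partitions, replicate correlation, isoform
differential enrichment, localization profiling, interaction-distance
(stability) scores, time-point shifts, and dot-plot table preparation.

The isoform differential follows the volcano-plot convention for spectral
counts: per prey, log2 fold change of (mean+1) pseudocounted counts between
the short and full-length isoform, a Welch two-sample test on log2(count+1)
across replicates, Benjamini-Hochberg adjustment over all tested preys, and
classification at |log2FC| >= 1 with adjusted p < 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hci_filtering import HCIRecord
from .io_formats import RunTable

__all__ = [
    "VennPartition",
    "DifferentialResult",
    "LocalizationProfile",
    "StabilityScore",
    "venn",
    "replicate_correlation",
    "differential_isoform",
    "localization_profile",
    "stability_scores",
    "timepoint_shift",
    "dotplot_table",
]


@dataclass
class VennPartition:
    """Exclusive region -> members, over a family of labeled sets."""

    regions: dict[frozenset[str], set]

    def count(self, *labels: str) -> int:
        return len(self.regions.get(frozenset(labels), set()))

    def members(self, *labels: str) -> set:
        return set(self.regions.get(frozenset(labels), set()))

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())


def venn(sets: Mapping[str, Iterable]) -> VennPartition:
    """All 2^k - 1 exclusive regions of a family of labeled sets."""
    families = {label: set(members) for label, members in sets.items()}
    labels = sorted(families)
    regions: dict[frozenset[str], set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = set()
    universe = set().union(*families.values()) if families else set()
    for element in universe:
        present = frozenset(l for l in labels if element in families[l])
        regions[present].add(element)
    return VennPartition(regions=regions)


def replicate_correlation(runs: RunTable, run_a: str, run_b: str) -> float:
    """Pearson r between two runs' prey-aligned count vectors (zeros filled)."""
    preys = sorted(
        {p for (rid, p) in runs.counts if rid in (run_a, run_b)}
    )
    if len(preys) < 2:
        raise ValueError("need at least 2 preys detected across the two runs")
    a = np.array([runs.get_count(run_a, p) for p in preys], dtype=float)
    b = np.array([runs.get_count(run_b, p) for p in preys], dtype=float)
    r, _ = stats.pearsonr(a, b)
    return float(r)


@dataclass
class DifferentialResult:
    prey_id: str
    log2fc: float
    p: float
    p_adj: float
    klass: str  # up | down | ns

    def __post_init__(self) -> None:
        if self.klass not in ("up", "down", "ns"):
            raise ValueError(f"invalid class {self.klass!r}")


def _welch_log2(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p on log2(count+1); 1.0 when both groups are constant."""
    import warnings

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if np.allclose(la.std(), 0) and np.allclose(lb.std(), 0):
        return 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
    with warnings.catch_warnings():
        # near-identical replicate vectors trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(la, lb, equal_var=False)
    return 1.0 if np.isnan(p) else float(p)


def differential_isoform(
    runs: RunTable,
    bait_full: str,
    bait_short: str,
    lfc_min: float = 1.0,
    padj_max: float = 0.5,
    test: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> list[DifferentialResult]:
    """Volcano-style differential prey enrichment between two isoform baits.

    log2fc = log2((mean_short + 1) / (mean_full + 1)); swapping the baits
    negates every fold change and swaps the up/down classes.
    """
    test = test or _welch_log2
    runs_full = [r.run_id for r in runs.test_runs() if r.bait_id == bait_full]
    runs_short = [r.run_id for r in runs.test_runs() if r.bait_id == bait_short]
    if len(runs_full) < 2 or len(runs_short) < 2:
        raise ValueError("both baits need at least 2 replicate runs")
    preys = sorted(
        {p for (rid, p) in runs.counts if rid in set(runs_full) | set(runs_short) and runs.counts[(rid, p)] > 0}
    )
    results: list[DifferentialResult] = []
    pvals: list[float] = []
    for prey in preys:
        a = np.array([runs.get_count(rid, prey) for rid in runs_full], dtype=float)
        b = np.array([runs.get_count(rid, prey) for rid in runs_short], dtype=float)
        lfc = float(np.log2((b.mean() + 1.0) / (a.mean() + 1.0)))
        p = test(a, b)
        results.append(DifferentialResult(prey, lfc, p, p_adj=1.0, klass="ns"))
        pvals.append(p)
    if pvals:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for res, q in zip(results, p_adj):
            res.p_adj = float(q)
            if res.p_adj < padj_max and res.log2fc >= lfc_min:
                res.klass = "up"
            elif res.p_adj < padj_max and res.log2fc <= -lfc_min:
                res.klass = "down"
    return results


@dataclass
class LocalizationProfile:
    """Compartment scores in [0,1], max-normalized so the top compartment is 1."""

    scores: dict[str, float]


def localization_profile(
    hci_preys: Iterable[str],
    reference_map: Mapping[str, Sequence[tuple[str, float]]],
) -> LocalizationProfile:
    """MS-microscopy style profile: sum annotation scores of the interactors
    mapped to each compartment, then normalize by the maximum."""
    raw: dict[str, float] = {}
    for prey in set(hci_preys):
        for compartment, score in reference_map.get(prey, ()):
            raw[compartment] = raw.get(compartment, 0.0) + float(score)
    top = max(raw.values(), default=0.0)
    if top <= 0:
        return LocalizationProfile(scores={c: 0.0 for c in raw})
    return LocalizationProfile(scores={c: v / top for c, v in raw.items()})


@dataclass
class StabilityScore:
    """Bounded interaction-distance score from bait-normalized PSM values.

    s = nAPMS / (nAPMS + nBioID) where n is the prey's PSM divided by the
    bait's own PSM in the same run, averaged over that assay's runs.  s near
    1 marks stable (pulldown-visible) partners, s near 0 proximal-only ones.
    """

    prey_id: str
    s: float
    n_apms: float
    n_bioid: float
    one_sided: bool = False


def stability_scores(runs: RunTable, bait: str) -> list[StabilityScore]:
    """Per-prey stability score for a bait assayed by both AP-MS and BioID.

    The score is invariant to jointly rescaling all counts in a run (the
    bait normalization divides any run-level scale out).  Preys detected in
    only one assay get the boundary score (1 for AP-MS-only, 0 for
    BioID-only) and are flagged ``one_sided``.
    """
    by_assay: dict[str, list[str]] = {"APMS": [], "BIOID": []}
    for r in runs.test_runs():
        if r.bait_id == bait and r.assay in by_assay:
            by_assay[r.assay].append(r.run_id)
    if not by_assay["APMS"] or not by_assay["BIOID"]:
        raise ValueError(f"bait {bait!r} must be present in both assays")
    for assay, ids in by_assay.items():
        for rid in ids:
            if runs.get_count(rid, bait) <= 0:
                raise ValueError(f"bait self-PSM must be > 0 in run {rid!r}")

    def normalized_mean(prey: str, ids: list[str]) -> float:
        vals = [runs.get_count(rid, prey) / runs.get_count(rid, bait) for rid in ids]
        return float(np.mean(vals))

    preys = sorted(
        {
            p
            for (rid, p) in runs.counts
            if rid in set(by_assay["APMS"]) | set(by_assay["BIOID"])
            and p != bait
            and runs.counts[(rid, p)] > 0
        }
    )
    out: list[StabilityScore] = []
    for prey in preys:
        n_a = normalized_mean(prey, by_assay["APMS"])
        n_b = normalized_mean(prey, by_assay["BIOID"])
        if n_a + n_b <= 0:
            continue
        if n_a == 0 or n_b == 0:
            out.append(StabilityScore(prey, 1.0 if n_b == 0 else 0.0, n_a, n_b, one_sided=True))
        else:
            out.append(StabilityScore(prey, n_a / (n_a + n_b), n_a, n_b))
    return out


def timepoint_shift(
    hcis_t1: Mapping[str, Iterable[str]],
    hcis_t2: Mapping[str, Iterable[str]],
) -> dict[str, dict[str, set[str]]]:
    """Per-bait gained / lost / kept prey sets between two time-points."""
    out: dict[str, dict[str, set[str]]] = {}
    for bait in sorted(set(hcis_t1) | set(hcis_t2)):
        a = set(hcis_t1.get(bait, ()))
        b = set(hcis_t2.get(bait, ()))
        out[bait] = {"lost": a - b, "kept": a & b, "gained": b - a}
    return out


def dotplot_table(
    hcis: Mapping[tuple[str, str, float], Sequence[HCIRecord]],
    complex_members: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Long table for dot-plot rendering (abundance = AvgSpec, score = BFDR).

    ``relative_abundance`` is each prey's avg_spec divided by its maximum
    avg_spec over baits within the same (assay, time) stratum, so it lies in
    (0, 1].  When ``complex_members`` is given, rows are restricted to preys
    belonging to any of the given complexes and tagged with the complex name.
    """
    member_of: dict[str, str] | None = None
    if complex_members is not None:
        member_of = {}
        for term, genes in complex_members.items():
            for g in genes:
                member_of.setdefault(g.upper(), term)

    rows = []
    for (bait, assay, time), records in sorted(hcis.items()):
        for r in records:
            if member_of is not None and r.prey_id.upper() not in member_of:
                continue
            rows.append(
                {
                    "bait_id": bait,
                    "prey_id": r.prey_id,
                    "assay": assay,
                    "labeling_time_h": time,
                    "avg_spec": r.interaction.avg_spec,
                    "bfdr": r.interaction.bfdr,
                    "complex": member_of.get(r.prey_id.upper()) if member_of else None,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["bait_id", "prey_id", "assay", "labeling_time_h", "avg_spec", "bfdr", "complex"],
    )
    if df.empty:
        df["relative_abundance"] = pd.Series(dtype=float)
        return df
    df["relative_abundance"] = df["avg_spec"] / df.groupby(
        ["assay", "labeling_time_h", "prey_id"]
    )["avg_spec"].transform("max")
    return df
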