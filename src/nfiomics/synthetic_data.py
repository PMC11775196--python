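"""Synthetic multi-bait proximity-labeling / AP-MS datasets with ground truth.

The generator emulates the statistical structure a spectral-count
interactomics analysis assumes: a handful of baits assayed in biological
triplicate at two biotinylation times, planted true interactors with high
negative-binomially distributed counts, a low-count background over all
preys, frequency-structured contaminants that also show up in GFP-style
negative controls, bait self-counts that shrink at the long labeling time
while the background (the biotinylated pool) broadens, and toy genomes with
NFI half-site motifs planted under ChIP peaks.

Counts are negative binomial rather than Poisson because spectral counts
are overdispersed; the Poisson is recovered as the size parameter grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    ControlLibrary,
    GenomicInterval,
    RunRecord,
    RunTable,
    build_control_library,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_interactome",
    "simulate_peaks",
    "simulate_isoform_pair",
    "recovery_metrics",
]

_NFI_BAITS = ("NFIA", "NFIB", "NFIC", "NFIX")


@dataclass
class SimulationConfig:
    """Study-design parameters for the interactome simulator.

    Defaults mirror a four-bait UltraID design: biological triplicates, six
    GFP control runs, two biotinylation times (3 h and 16 h), strong planted
    interactors (mean 50 PSM) over a sparse background (mean 0.5 PSM), and a
    contaminant stratum seen in half the control runs.  At the long labeling
    time the bait's own PSM drops (``time_effect_bait`` < 1) while the
    biotinylated background pool broadens (``time_effect_breadth`` > 1).
    """

    n_baits: int = 4
    n_preys: int = 100
    n_true_per_bait: int = 10
    frac_shared_true: float = 0.25
    n_replicates: int = 3
    n_control_runs: int = 6
    signal_mean: float = 50.0
    background_mean: float = 0.5
    contaminant_fraction: float = 0.10
    contaminant_frequency: float = 0.50
    contaminant_mean: float = 10.0
    bait_self_mean: float = 150.0
    labeling_times_h: tuple[float, ...] = (3.0, 16.0)
    time_effect_bait: float = 0.6
    time_effect_breadth: float = 1.5
    dispersion: float = 2.0
    assay: str = "BIOID"
    cell_line: str = "HEK293"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.signal_mean, self.background_mean, self.contaminant_mean, self.bait_self_mean) <= 0:
            raise ValueError("all means must be > 0")
        for name in ("frac_shared_true", "contaminant_fraction", "contaminant_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_true_per_bait > self.n_preys:
            raise ValueError("n_true_per_bait cannot exceed n_preys")
        if not self.labeling_times_h:
            raise ValueError("need at least one labeling time")


@dataclass
class GroundTruth:
    """Everything planted by a simulator, for parameter-recovery checks."""

    true_pairs: set[tuple[str, str, float]] = field(default_factory=set)
    contaminant_preys: set[str] = field(default_factory=set)
    planted_motif_sites: list[tuple[str, int, int, str]] = field(default_factory=list)
    diff_up_preys: set[str] = field(default_factory=set)
    diff_down_preys: set[str] = field(default_factory=set)
    bait_ids: tuple[str, ...] = ()


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative binomial with the given mean and size (overdispersion) parameter."""
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, n)


def _bait_names(n: int) -> list[str]:
    if n <= len(_NFI_BAITS):
        return list(_NFI_BAITS[:n])
    return list(_NFI_BAITS) + [f"BAIT{i}" for i in range(len(_NFI_BAITS) + 1, n + 1)]


def simulate_interactome(
    config: SimulationConfig,
) -> tuple[RunTable, ControlLibrary, GroundTruth]:
    """Simulate a multi-bait run table, its GFP control library, and truth.

    Planted true pairs draw NB(signal_mean); every other test cell draws
    the NB background.  A ``frac_shared_true`` fraction of each bait's true
    preys is common to all baits.  Contaminant preys appear in any run
    (control or test, bait-independent) with probability
    ``contaminant_frequency``, at NB(contaminant_mean).  The bait itself is
    recovered in its own runs at ``bait_self_mean`` PSM, scaled by
    ``time_effect_bait`` at the long time-point, where the background mean
    is scaled up by ``time_effect_breadth``.
    """
    rng = np.random.default_rng(config.seed)
    baits = _bait_names(config.n_baits)
    preys = [f"PREY{i:04d}" for i in range(1, config.n_preys + 1)]

    n_shared = int(round(config.frac_shared_true * config.n_true_per_bait))
    shared_true = preys[:n_shared]
    specific: dict[str, list[str]] = {}
    cursor = n_shared
    for b in baits:
        k = config.n_true_per_bait - n_shared
        if cursor + k > len(preys):
            raise ValueError("not enough preys for the requested true-pair layout")
        specific[b] = preys[cursor : cursor + k]
        cursor += k
    n_contam = int(round(config.contaminant_fraction * config.n_preys))
    contam_pool = [p for p in preys[cursor:]]
    if n_contam > len(contam_pool):
        raise ValueError("not enough non-true preys for the requested contaminant fraction")
    contaminants = set(contam_pool[:n_contam])

    long_time = max(config.labeling_times_h)
    runs: list[RunRecord] = []
    for b in baits:
        for t in config.labeling_times_h:
            for rep in range(1, config.n_replicates + 1):
                runs.append(
                    RunRecord(
                        run_id=f"{b}_{config.assay}_t{t:g}_r{rep}",
                        bait_id=b,
                        assay=config.assay,
                        labeling_time_h=t,
                        cell_line=config.cell_line,
                        replicate=rep,
                        is_control=False,
                    )
                )
    for rep in range(1, config.n_control_runs + 1):
        runs.append(
            RunRecord(
                run_id=f"GFP_ctrl_r{rep}",
                bait_id="GFP",
                assay=config.assay,
                labeling_time_h=config.labeling_times_h[0],
                cell_line=config.cell_line,
                replicate=rep,
                is_control=True,
            )
        )

    truth = GroundTruth(contaminant_preys=set(contaminants), bait_ids=tuple(baits))
    for b in baits:
        for t in config.labeling_times_h:
            for p in shared_true + specific[b]:
                truth.true_pairs.add((b, p, t))

    counts: dict[tuple[str, str], int] = {}
    for r in runs:
        is_long = (not r.is_control) and r.labeling_time_h == long_time and len(config.labeling_times_h) > 1
        bg_mean = config.background_mean * (config.time_effect_breadth if is_long else 1.0)
        true_set = set() if r.is_control else {
            p for (b, p, t) in truth.true_pairs if b == r.bait_id and t == r.labeling_time_h
        }
        for p in preys:
            if p in true_set:
                c = int(_nb_draw(rng, config.signal_mean, config.dispersion, 1)[0])
            elif p in contaminants:
                present = rng.random() < config.contaminant_frequency
                c = int(_nb_draw(rng, config.contaminant_mean, config.dispersion, 1)[0]) if present else 0
            else:
                c = int(_nb_draw(rng, bg_mean, config.dispersion, 1)[0])
            if c > 0:
                counts[(r.run_id, p)] = c
        if not r.is_control:
            self_mean = config.bait_self_mean * (config.time_effect_bait if is_long else 1.0)
            c = int(max(1, _nb_draw(rng, self_mean, config.dispersion, 1)[0]))
            counts[(r.run_id, r.bait_id)] = c

    table = RunTable(runs=runs, counts=counts)
    library = build_control_library(table)
    return table, library, truth


def simulate_peaks(
    n_baits: int,
    genome_lengths: Mapping[str, int],
    n_peaks: int,
    frac_shared: float,
    motif_spacer_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
    peak_width: int = 200,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, str], GroundTruth]:
    """Toy genomes with per-bait peak sets and one planted NFI motif per peak.

    Shared peaks sit at identical coordinates in every bait's set; all
    physical peak regions are mutually non-overlapping so overlap counting
    has an unambiguous truth.  Each peak carries one TTGGC-N{k}-GCCAA site
    at its center with k drawn from ``motif_spacer_distribution`` (default:
    canonical k=5 with probability 0.6, k in {3,4,6,7} at 0.1 each); the
    rest of the genome is i.i.d. uniform ACGT.
    """
    if not 0.0 <= frac_shared <= 1.0:
        raise ValueError("frac_shared must be in [0,1]")
    if motif_spacer_distribution is None:
        motif_spacer_distribution = {3: 0.1, 4: 0.1, 5: 0.6, 6: 0.1, 7: 0.1}
    spacers = sorted(motif_spacer_distribution)
    weights = np.array([motif_spacer_distribution[k] for k in spacers], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("spacer distribution must have positive mass")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    baits = _bait_names(n_baits)
    n_shared = int(round(frac_shared * n_peaks))
    n_total = n_shared + n_baits * (n_peaks - n_shared)

    # non-overlapping placement on a slot grid, slots allocated by length
    gap = peak_width  # guaranteed clearance between adjacent peaks
    slot = peak_width + gap
    slots: list[tuple[str, int]] = []
    for chrom in sorted(genome_lengths):
        L = genome_lengths[chrom]
        for i in range(L // slot):
            slots.append((chrom, i * slot + gap // 2))
    if len(slots) < n_total:
        raise ValueError(
            f"genome too short: {n_total} peaks requested but only {len(slots)} "
            f"non-overlapping slots of width {peak_width} available"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    placements = [slots[i] for i in chosen]

    genome = {
        chrom: rng.choice(np.array(list("ACGT")), size=genome_lengths[chrom])
        for chrom in sorted(genome_lengths)
    }
    truth = GroundTruth(bait_ids=tuple(baits))

    def make_peak(chrom: str, start: int) -> GenomicInterval:
        k = int(rng.choice(spacers, p=weights))
        motif = "TTGGC" + "".join(rng.choice(np.array(list("ACGT")), size=k)) + "GCCAA"
        pos = start + (peak_width - len(motif)) // 2
        genome[chrom][pos : pos + len(motif)] = list(motif)
        truth.planted_motif_sites.append((chrom, pos, k, "+"))
        score = float(rng.uniform(1.0, 1000.0))
        return GenomicInterval(chrom, start, start + peak_width, score=score)

    shared = [make_peak(c, s) for c, s in placements[:n_shared]]
    peaksets: dict[str, list[GenomicInterval]] = {}
    cursor = n_shared
    for b in baits:
        own = [make_peak(c, s) for c, s in placements[cursor : cursor + (n_peaks - n_shared)]]
        cursor += n_peaks - n_shared
        peaksets[b] = sorted(shared + own)

    genome_str = {chrom: "".join(arr) for chrom, arr in genome.items()}
    return peaksets, genome_str, truth


def simulate_isoform_pair(
    config: SimulationConfig,
    n_diff_up: int = 20,
    n_diff_down: int = 20,
    effect_log2fc: float = 3.0,
    seed: int | None = None,
) -> tuple[RunTable, GroundTruth]:
    """Two isoform baits sharing a prey pool, with planted differential preys.

    Baits ``ISO_FL`` (full length) and ``ISO_SHORT`` see every prey at
    NB(signal_mean); ``n_diff_up`` preys have their mean multiplied by
    2**effect_log2fc in the short isoform and ``n_diff_down`` divided by it.
    """
    if n_diff_up + n_diff_down > config.n_preys:
        raise ValueError("more differential preys than preys")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    preys = [f"PREY{i:04d}" for i in range(1, config.n_preys + 1)]
    up = set(preys[:n_diff_up])
    down = set(preys[n_diff_up : n_diff_up + n_diff_down])
    factor = 2.0 ** effect_log2fc

    runs: list[RunRecord] = []
    for b in ("ISO_FL", "ISO_SHORT"):
        for rep in range(1, config.n_replicates + 1):
            runs.append(
                RunRecord(
                    run_id=f"{b}_r{rep}",
                    bait_id=b,
                    assay=config.assay,
                    labeling_time_h=config.labeling_times_h[0],
                    cell_line=config.cell_line,
                    replicate=rep,
                    is_control=False,
                )
            )
    counts: dict[tuple[str, str], int] = {}
    for r in runs:
        for p in preys:
            mean = config.signal_mean
            if r.bait_id == "ISO_SHORT":
                if p in up:
                    mean *= factor
                elif p in down:
                    mean /= factor
            c = int(_nb_draw(rng, mean, config.dispersion, 1)[0])
            if c > 0:
                counts[(r.run_id, p)] = c
    truth = GroundTruth(diff_up_preys=up, diff_down_preys=down, bait_ids=("ISO_FL", "ISO_SHORT"))
    return RunTable(runs=runs, counts=counts), truth


def recovery_metrics(
    called: set[tuple[str, str, float]],
    truth: GroundTruth,
) -> dict[str, float]:
    """Sensitivity and empirical FDR of called (bait, prey, time) pairs.

    Bait self-recoveries (prey == bait) are ignored on both sides: the bait
    finding itself is not an interaction call.
    """
    called = {(b, p, t) for (b, p, t) in called if b != p}
    true = truth.true_pairs
    tp = len(called & true)
    fp = len(called - true)
    sensitivity = tp / len(true) if true else float("nan")
    fdr = fp / len(called) if called else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "tp": tp, "fp": fp, "n_true": len(true)}
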