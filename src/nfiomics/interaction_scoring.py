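"""Bait-prey spectral-count scoring with protein-level Bayesian FDR.

Each replicate count x for a candidate pair is scored with a two-component
Poisson posterior under equal priors:

    p(x) = f1(x) / (f0(x) + f1(x))

where f0 is Poisson with the prey's control mean (floored at a small
pseudo-count) and f1 is Poisson with the pair's mean test count, clamped
from below by the control mean so that only *enrichment over control* is
evidence (a depleted prey is not an interaction).  The Bayesian FDR of a
pair is the running mean of (1 - avg_p) down the avg_p-ranked list, made
monotone by a cumulative maximum — the standard spectral-count BFDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .io_formats import ControlLibrary, RunTable

__all__ = ["ScoredInteraction", "ScoringParams", "score_pair", "compute_bfdr", "score_run_table"]

#: pseudo-floor on the control mean so f0 is never degenerate at zero
DEFAULT_PSEUDO_FLOOR = 0.1


@dataclass
class ScoringParams:
    pseudo_floor: float = DEFAULT_PSEUDO_FLOOR


@dataclass
class ScoredInteraction:
    """One scored bait-prey pair within an (assay, labeling-time) stratum."""

    bait_id: str
    prey_id: str
    assay: str
    labeling_time_h: float
    avg_spec: float
    rep_probs: list[float] = field(default_factory=list)
    avg_p: float = 0.0
    bfdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.avg_spec < 0:
            raise ValueError("avg_spec must be >= 0")
        if not 0.0 <= self.avg_p <= 1.0:
            raise ValueError("avg_p must be in [0, 1]")


def score_pair(
    test_counts: Sequence[int],
    control_mean: float,
    pseudo_floor: float = DEFAULT_PSEUDO_FLOOR,
) -> tuple[list[float], float]:
    """Posterior interaction probability per replicate, and their mean.

    When the mean test count does not exceed the control mean the signal
    rate clamps to the background rate, f0 == f1, and every replicate
    scores an uninformative 0.5.
    """
    if len(test_counts) == 0:
        raise ValueError("test_counts must be non-empty")
    if control_mean < 0:
        raise ValueError("control_mean must be >= 0")
    x = np.asarray(test_counts, dtype=float)
    mu0 = max(control_mean, pseudo_floor)
    mu1 = max(float(x.mean()), mu0)
    log_f0 = poisson.logpmf(x, mu0)
    log_f1 = poisson.logpmf(x, mu1)
    # p = f1/(f0+f1) computed in log space for stability
    probs = 1.0 / (1.0 + np.exp(log_f0 - log_f1))
    return probs.tolist(), float(probs.mean())


def compute_bfdr(scored: list[ScoredInteraction]) -> list[ScoredInteraction]:
    """Fill ``bfdr`` for a scored set; returns a new list in input order.

    Records are ranked by avg_p descending (ties: higher avg_spec first,
    then lexicographic prey_id, then bait_id for full determinism); the
    i-th BFDR is the mean of (1 - avg_p) over the top i records, then a
    cumulative maximum enforces monotonicity down the ranking.
    """
    if not scored:
        return []
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i].avg_p, -scored[i].avg_spec, scored[i].prey_id, scored[i].bait_id),
    )
    one_minus_p = np.array([1.0 - scored[i].avg_p for i in order])
    running = np.cumsum(one_minus_p) / np.arange(1, len(order) + 1)
    bfdr_ranked = np.maximum.accumulate(running)
    out: list[ScoredInteraction] = list(scored)
    for rank, idx in enumerate(order):
        out[idx] = replace(scored[idx], bfdr=float(bfdr_ranked[rank]))
    return out


def score_run_table(
    runs: RunTable,
    controls: ControlLibrary,
    params: ScoringParams | None = None,
) -> list[ScoredInteraction]:
    """Score every detected bait-prey pair; BFDR per (assay, time) stratum.

    Test runs are grouped by (bait, assay, labeling time); AP-MS runs
    collapse to a single time stratum (labeling time is meaningless for a
    stable pulldown).  A pair is scored when any replicate in its group has
    a nonzero count; replicate vectors are zero-filled across the group's
    runs.  Control means come from the control library per prey.
    """
    params = params or ScoringParams()
    groups: dict[tuple[str, str, float], list[str]] = {}
    for r in runs.test_runs():
        time = 0.0 if r.assay == "APMS" else float(r.labeling_time_h)
        groups.setdefault((r.bait_id, r.assay, time), []).append(r.run_id)

    prey_by_run: dict[str, set[str]] = {}
    for (rid, prey), c in runs.counts.items():
        if c > 0:
            prey_by_run.setdefault(rid, set()).add(prey)

    scored: list[ScoredInteraction] = []
    for (bait, assay, time), run_ids in sorted(groups.items()):
        preys = sorted(set().union(*(prey_by_run.get(rid, set()) for rid in run_ids)))
        for prey in preys:
            counts = [runs.get_count(rid, prey) for rid in run_ids]
            rep_probs, avg_p = score_pair(counts, controls.mean(prey), params.pseudo_floor)
            scored.append(
                ScoredInteraction(
                    bait_id=bait,
                    prey_id=prey,
                    assay=assay,
                    labeling_time_h=time,
                    avg_spec=float(np.mean(counts)),
                    rep_probs=rep_probs,
                    avg_p=avg_p,
                )
            )

    # BFDR is computed within each (assay, time) stratum across baits
    out: list[ScoredInteraction] = []
    strata = sorted({(s.assay, s.labeling_time_h) for s in scored})
    for stratum in strata:
        subset = [s for s in scored if (s.assay, s.labeling_time_h) == stratum]
        out.extend(compute_bfdr(subset))
    return out
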