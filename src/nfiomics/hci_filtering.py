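"""The high-confidence-interaction (HCI) filtering ledger.

A scored bait-prey pair survives into the HCI set by passing, in order:

1. primary BFDR cut — BFDR <= 0.01 for proximity labeling (BioID/UltraID),
   <= 0.05 for AP-MS;
2. cross-bait rescue (BioID strata only) — a pair failing the cut is kept
   when the same prey passed for any other bait in the same stratum AND the
   failing bait actually detected the prey (avg_spec > 0; absence cannot be
   rescued);
3. contaminant filter — a prey detected in more than 20% of the negative
   control library is removed unless its average spectral count exceeds 3x
   the library's mean count for that prey (frequency exactly 0.20 survives:
   the cut is strict);
4. minimum abundance — average spectral count strictly below 3 is removed
   (exactly 3 survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .interaction_scoring import ScoredInteraction
from .io_formats import ControlLibrary

__all__ = [
    "FilterConfig",
    "HCIRecord",
    "primary_bfdr_filter",
    "rescue_across_baits",
    "contaminant_filter",
    "min_count_filter",
    "call_hcis",
    "validation_summary",
    "summarize_known_novel",
    "audit_frame",
]


@dataclass
class FilterConfig:
    bfdr_max_bioid: float = 0.01
    bfdr_max_apms: float = 0.05
    contaminant_freq_max: float = 0.20
    override_fold: float = 3.0
    min_avg_spec: float = 3.0
    rescue_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("bfdr_max_bioid", "bfdr_max_apms", "contaminant_freq_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.override_fold <= 0 or self.min_avg_spec < 0:
            raise ValueError("override_fold must be > 0 and min_avg_spec >= 0")


@dataclass
class HCIRecord:
    """A scored interaction annotated with its terminal filtering state."""

    interaction: ScoredInteraction
    passed_primary: bool = False
    rescued: bool = False
    contaminant_overridden: bool = False
    removed_reason: str = "none"  # none | bfdr | contaminant | min_count

    @property
    def is_hci(self) -> bool:
        return self.removed_reason == "none"

    @property
    def bait_id(self) -> str:
        return self.interaction.bait_id

    @property
    def prey_id(self) -> str:
        return self.interaction.prey_id


def _bfdr_threshold(assay: str, config: FilterConfig) -> float:
    return config.bfdr_max_bioid if assay == "BIOID" else config.bfdr_max_apms


def primary_bfdr_filter(scored: Sequence[ScoredInteraction], config: FilterConfig) -> list[HCIRecord]:
    """Inclusive BFDR cut per assay; failures provisionally removed as 'bfdr'."""
    out = []
    for s in scored:
        ok = s.bfdr <= _bfdr_threshold(s.assay, config)
        out.append(HCIRecord(s, passed_primary=ok, removed_reason="none" if ok else "bfdr"))
    return out


def rescue_across_baits(records: list[HCIRecord], config: FilterConfig) -> list[HCIRecord]:
    """Rescue BioID pairs whose prey passed the primary cut with another bait.

    Operates within (assay, time) strata; requires detection (avg_spec > 0)
    in the rescued bait.  A rescued record clears its 'bfdr' removal but
    keeps passed_primary=False.
    """
    if not config.rescue_enabled:
        return records
    passed_preys: dict[tuple[str, float], dict[str, set[str]]] = {}
    for r in records:
        s = r.interaction
        if s.assay != "BIOID" or not r.passed_primary:
            continue
        stratum = passed_preys.setdefault((s.assay, s.labeling_time_h), {})
        stratum.setdefault(s.prey_id, set()).add(s.bait_id)
    for r in records:
        s = r.interaction
        if s.assay != "BIOID" or r.passed_primary or r.removed_reason != "bfdr":
            continue
        baits = passed_preys.get((s.assay, s.labeling_time_h), {}).get(s.prey_id, set())
        if (baits - {s.bait_id}) and s.avg_spec > 0:
            r.rescued = True
            r.removed_reason = "none"
    return records


def contaminant_filter(
    records: list[HCIRecord], library: ControlLibrary, config: FilterConfig
) -> list[HCIRecord]:
    """Drop frequent control-library preys unless strongly over-represented."""
    for r in records:
        if r.removed_reason != "none":
            continue
        s = r.interaction
        freq = library.frequency(s.prey_id)
        if freq > config.contaminant_freq_max:
            lib_mean = library.mean(s.prey_id)
            if s.avg_spec > config.override_fold * lib_mean:
                r.contaminant_overridden = True
            else:
                r.removed_reason = "contaminant"
    return records


def min_count_filter(records: list[HCIRecord], config: FilterConfig) -> list[HCIRecord]:
    """Remove pairs averaging strictly fewer than ``min_avg_spec`` PSMs."""
    for r in records:
        if r.removed_reason == "none" and r.interaction.avg_spec < config.min_avg_spec:
            r.removed_reason = "min_count"
    return records


def call_hcis(
    scored: Sequence[ScoredInteraction],
    library: ControlLibrary,
    config: FilterConfig | None = None,
) -> tuple[dict[tuple[str, str, float], list[HCIRecord]], list[HCIRecord]]:
    """Run the full ledger; returns (per-bait-stratum HCI sets, audit records).

    Ledger order: primary BFDR -> cross-bait rescue -> contaminant filter ->
    minimum count.  The audit list holds every input record with its
    terminal state; the HCI mapping keys are (bait, assay, time).
    """
    config = config or FilterConfig()
    records = primary_bfdr_filter(scored, config)
    records = rescue_across_baits(records, config)
    records = contaminant_filter(records, library, config)
    records = min_count_filter(records, config)
    hcis: dict[tuple[str, str, float], list[HCIRecord]] = {}
    for r in records:
        if r.is_hci:
            s = r.interaction
            hcis.setdefault((s.bait_id, s.assay, s.labeling_time_h), []).append(r)
    return hcis, records


def audit_frame(records: Sequence[HCIRecord]) -> pd.DataFrame:
    """One row per scored record with flags and terminal state."""
    return pd.DataFrame(
        [
            {
                "bait_id": r.interaction.bait_id,
                "prey_id": r.interaction.prey_id,
                "assay": r.interaction.assay,
                "labeling_time_h": r.interaction.labeling_time_h,
                "avg_spec": r.interaction.avg_spec,
                "avg_p": r.interaction.avg_p,
                "bfdr": r.interaction.bfdr,
                "passed_primary": r.passed_primary,
                "rescued": r.rescued,
                "contaminant_overridden": r.contaminant_overridden,
                "removed_reason": r.removed_reason,
            }
            for r in records
        ]
    )


def validation_summary(per_bait: Iterable[tuple[int, int]]) -> float:
    """Pooled validation percentage: 100 * sum(validated) / sum(tested)."""
    pairs = list(per_bait)
    tested = sum(t for _, t in pairs)
    if tested <= 0:
        raise ValueError("no tested interactions")
    validated = sum(v for v, _ in pairs)
    if any(v < 0 or t < 0 or v > t for v, t in pairs):
        raise ValueError("each (validated, tested) pair needs 0 <= validated <= tested")
    return 100.0 * validated / tested


def summarize_known_novel(
    hcis: dict[tuple[str, str, float], list[HCIRecord]],
    reference_pairs: set[tuple[str, str]],
) -> pd.DataFrame:
    """Per bait/assay/time: known (in reference, either direction), novel, total.

    total == known + novel always holds; it is the bookkeeping identity of a
    known/novel interactor table.
    """
    rows = []
    for (bait, assay, time), records in sorted(hcis.items()):
        known = 0
        for r in records:
            b, p = r.bait_id.upper(), r.prey_id.upper()
            if (b, p) in reference_pairs or (p, b) in reference_pairs:
                known += 1
        total = len(records)
        rows.append(
            {
                "bait_id": bait,
                "assay": assay,
                "labeling_time_h": time,
                "known": known,
                "novel": total - known,
                "total": total,
            }
        )
    return pd.DataFrame(rows, columns=["bait_id", "assay", "labeling_time_h", "known", "novel", "total"])
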