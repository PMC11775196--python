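"""End-to-end orchestration: simulate -> score -> filter -> compare -> chip.

A pipeline run is driven by a nested config (usually YAML), writes every
intermediate in the package's TSV dialects under one output directory, and
emits a JSON manifest recording inputs, outputs, parameters and SHA-256
checksums per stage.  Reruns with the same config and seed reproduce
identical checksums: the master seed fans out to per-stage seeds by stable
hashing of stage names, so toggling one stage never perturbs another's
random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any, Mapping

import pandas as pd

from . import chip_integration as chip
from . import interactome_analysis as ia
from .hci_filtering import FilterConfig, audit_frame, call_hcis, summarize_known_novel
from .interaction_scoring import ScoredInteraction, ScoringParams, score_run_table
from .io_formats import (
    write_bed,
    write_control_library,
    write_gene_models,
    write_genome_fasta,
    write_run_table,
)
from .synthetic_data import SimulationConfig, simulate_interactome, simulate_peaks

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed", "load_config"]

log = logging.getLogger("nfiomics.pipeline")

_STAGES = ("simulate", "score", "filter", "compare", "chip")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class ChipStageConfig:
    n_baits: int = 4
    n_peaks: int = 40
    frac_shared: float = 0.4
    genome_length: int = 60000
    peak_width: int = 200
    top_n: int = 20
    seed: int = 0


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "nfiomics_run"
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    simulate: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    scoring: ScoringParams = dataclasses.field(default_factory=ScoringParams)
    chip: ChipStageConfig = dataclasses.field(default_factory=ChipStageConfig)


def _build_dataclass(cls, data: Mapping[str, Any], context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise PipelineError(f"{context}: unknown config key(s) {sorted(unknown)}")
    coerced = dict(data)
    if "labeling_times_h" in coerced and coerced["labeling_times_h"] is not None:
        coerced["labeling_times_h"] = tuple(coerced["labeling_times_h"])
    return cls(**coerced)


def load_config(data: Mapping[str, Any]) -> PipelineConfig:
    """Validate a nested mapping (e.g. parsed YAML) into a PipelineConfig.

    Unknown keys are rejected at every level.
    """
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise PipelineError(f"config: unknown top-level key(s) {sorted(unknown)}")
    cfg = PipelineConfig()
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    if "stages" in data:
        unknown = set(data["stages"]) - set(_STAGES)
        if unknown:
            raise PipelineError(f"config.stages: unknown stage(s) {sorted(unknown)}")
        cfg.stages.update({k: bool(v) for k, v in data["stages"].items()})
    if "simulate" in data:
        cfg.simulate = _build_dataclass(SimulationConfig, data["simulate"], "config.simulate")
    if "filter" in data:
        cfg.filter = _build_dataclass(FilterConfig, data["filter"], "config.filter")
    if "scoring" in data:
        cfg.scoring = _build_dataclass(ScoringParams, data["scoring"], "config.scoring")
    if "chip" in data:
        cfg.chip = _build_dataclass(ChipStageConfig, data["chip"], "config.chip")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def scored_frame(scored: list[ScoredInteraction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bait_id": s.bait_id,
                "prey_id": s.prey_id,
                "assay": s.assay,
                "labeling_time_h": s.labeling_time_h,
                "avg_spec": s.avg_spec,
                "avg_p": s.avg_p,
                "bfdr": s.bfdr,
            }
            for s in scored
        ]
    )


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in dependency order; return the manifest."""
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def record(stage: str, outputs: dict[str, str], params: Mapping[str, Any]) -> None:
        manifest["stages"][stage] = {
            "parameters": dict(params),
            "outputs": {k: {"path": p, "sha256": _sha256(p)} for k, p in outputs.items()},
            "status": "ok",
        }
        log.info("stage %s: %d output(s)", stage, len(outputs))

    table = library = truth = None
    scored = None
    hcis = records = None

    if config.stages.get("simulate", True):
        try:
            sim_cfg = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
            table, library, truth = simulate_interactome(sim_cfg)
            runs_path = os.path.join(outdir, "runs.tsv")
            controls_path = os.path.join(outdir, "controls.tsv")
            truth_path = os.path.join(outdir, "truth_pairs.tsv")
            write_run_table(table, runs_path)
            write_control_library(library, controls_path)
            with open(truth_path, "w") as fh:
                fh.write("bait_id\tprey_id\tlabeling_time_h\n")
                for b, p, t in sorted(truth.true_pairs):
                    fh.write(f"{b}\t{p}\t{t:g}\n")
            record(
                "simulate",
                {"runs": runs_path, "controls": controls_path, "truth": truth_path},
                dataclasses.asdict(sim_cfg),
            )
        except Exception as e:
            raise PipelineError(f"stage simulate failed: {e}") from e

    if config.stages.get("score", True):
        if table is None or library is None:
            raise PipelineError("stage score failed: no run table (enable the simulate stage)")
        try:
            scored = score_run_table(table, library, config.scoring)
            scored_path = os.path.join(outdir, "scored.tsv")
            _write_tsv(scored_frame(scored), scored_path)
            record("score", {"scored": scored_path}, dataclasses.asdict(config.scoring))
        except Exception as e:
            raise PipelineError(f"stage score failed: {e}") from e

    if config.stages.get("filter", True):
        if scored is None or library is None:
            raise PipelineError("stage filter failed: no scored interactions (enable score)")
        try:
            hcis, records = call_hcis(scored, library, config.filter)
            hci_rows = []
            for (bait, assay, time), recs in sorted(hcis.items()):
                for r in recs:
                    hci_rows.append(
                        {
                            "bait_id": bait,
                            "prey_id": r.prey_id,
                            "assay": assay,
                            "labeling_time_h": time,
                            "avg_spec": r.interaction.avg_spec,
                            "bfdr": r.interaction.bfdr,
                            "rescued": r.rescued,
                            "contaminant_overridden": r.contaminant_overridden,
                        }
                    )
            hci_path = os.path.join(outdir, "hci.tsv")
            audit_path = os.path.join(outdir, "audit.tsv")
            _write_tsv(pd.DataFrame(hci_rows), hci_path)
            _write_tsv(audit_frame(records), audit_path)
            record("filter", {"hci": hci_path, "audit": audit_path}, dataclasses.asdict(config.filter))
        except Exception as e:
            raise PipelineError(f"stage filter failed: {e}") from e

    if config.stages.get("compare", True):
        if hcis is None:
            raise PipelineError("stage compare failed: no HCI sets (enable filter)")
        try:
            times = sorted({t for (_, _, t) in hcis})
            venn_rows = []
            for t in times:
                sets = {
                    bait: {r.prey_id for r in recs}
                    for (bait, assay, tt), recs in hcis.items()
                    if tt == t
                }
                part = ia.venn(sets)
                for region, members in sorted(part.regions.items(), key=lambda kv: sorted(kv[0])):
                    venn_rows.append(
                        {
                            "labeling_time_h": t,
                            "region": "&".join(sorted(region)),
                            "count": len(members),
                        }
                    )
            venn_path = os.path.join(outdir, "venn.tsv")
            _write_tsv(pd.DataFrame(venn_rows), venn_path)
            shift_path = os.path.join(outdir, "timepoint_shift.tsv")
            shift_rows = []
            if len(times) >= 2:
                t1, t2 = times[0], times[-1]
                h1 = {b: {r.prey_id for r in recs} for (b, _, t), recs in hcis.items() if t == t1}
                h2 = {b: {r.prey_id for r in recs} for (b, _, t), recs in hcis.items() if t == t2}
                for bait, classes in ia.timepoint_shift(h1, h2).items():
                    for klass, preys in classes.items():
                        shift_rows.append({"bait_id": bait, "class": klass, "n": len(preys)})
            _write_tsv(pd.DataFrame(shift_rows, columns=["bait_id", "class", "n"]), shift_path)
            record("compare", {"venn": venn_path, "timepoint_shift": shift_path}, {})
        except Exception as e:
            raise PipelineError(f"stage compare failed: {e}") from e

    if config.stages.get("chip", True):
        try:
            cc = dataclasses.replace(config.chip, seed=stage_seed(config.seed, "chip"))
            peaksets, genome, peak_truth = simulate_peaks(
                n_baits=cc.n_baits,
                genome_lengths={"chr1": cc.genome_length},
                n_peaks=cc.n_peaks,
                frac_shared=cc.frac_shared,
                seed=cc.seed,
                peak_width=cc.peak_width,
            )
            genome_path = os.path.join(outdir, "genome.fa")
            write_genome_fasta(genome, genome_path)
            bed_paths = {}
            for bait, peaks in peaksets.items():
                p = os.path.join(outdir, f"peaks_{bait}.bed")
                write_bed(peaks, p)
                bed_paths[f"peaks_{bait}"] = p
            overlap = chip.overlap_peaks(peaksets)
            overlap_path = os.path.join(outdir, "overlap.tsv")
            _write_tsv(
                pd.DataFrame(
                    [
                        {"region": "&".join(sorted(region)), "count": n}
                        for region, n in sorted(
                            overlap.region_counts.items(), key=lambda kv: sorted(kv[0])
                        )
                    ]
                ),
                overlap_path,
            )
            # toy gene models: one gene per 2 kb so every peak annotates
            genes = [
                chip.GeneModelRecord(f"GENE{i:04d}", "chr1", i * 2000, "+")
                for i in range(cc.genome_length // 2000)
            ]
            genes_path = os.path.join(outdir, "genes.tsv")
            write_gene_models(genes, genes_path)
            targets_rows = []
            for bait, peaks in peaksets.items():
                for g in sorted(chip.top_targets(peaks, genes, n=cc.top_n)):
                    targets_rows.append({"bait_id": bait, "gene_id": g})
            targets_path = os.path.join(outdir, "targets.tsv")
            _write_tsv(pd.DataFrame(targets_rows, columns=["bait_id", "gene_id"]), targets_path)
            hits = chip.scan_motif(genome)
            hits_path = os.path.join(outdir, "motif_hits.tsv")
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "chrom": h.chrom,
                            "start": h.start,
                            "strand": h.strand,
                            "spacer_len": h.spacer_len,
                            "n_mismatches": h.n_mismatches,
                            "sequence": h.matched_sequence,
                        }
                        for h in hits
                    ],
                    columns=["chrom", "start", "strand", "spacer_len", "n_mismatches", "sequence"],
                ),
                hits_path,
            )
            record(
                "chip",
                {
                    "genome": genome_path,
                    **bed_paths,
                    "overlap": overlap_path,
                    "genes": genes_path,
                    "targets": targets_path,
                    "motif_hits": hits_path,
                },
                dataclasses.asdict(cc),
            )
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage chip failed: {e}") from e

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
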