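"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated with ``\\n`` line endings and no index
column.  Genomic coordinates are 0-based half-open (the BED convention)
everywhere inside the package; any 1-based dialect must be converted at the
boundary.  Gene symbols are upper-cased before joins because human (NFIA)
and mouse (Nfia) casing coexist in the field's reference resources.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RunRecord",
    "RunTable",
    "ControlLibrary",
    "GenomicInterval",
    "GeneModelRecord",
    "read_run_table",
    "write_run_table",
    "build_control_library",
    "read_control_library",
    "write_control_library",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_reference_interactions",
    "write_reference_interactions",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_models",
    "write_gene_models",
    "read_genome_fasta",
    "write_genome_fasta",
]

ASSAYS = ("APMS", "BIOID")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass(frozen=True)
class RunRecord:
    """Metadata for one MS run: who the bait was and how it was assayed.

    ``labeling_time_h`` is the biotinylation window for proximity labeling;
    it is ignored by downstream math for AP-MS runs (stable pulldowns have
    no labeling time).
    """

    run_id: str
    bait_id: str
    assay: str
    labeling_time_h: float
    cell_line: str
    replicate: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.labeling_time_h < 0:
            raise ValueError("labeling_time_h must be non-negative")


@dataclass
class RunTable:
    """Per-run metadata plus sparse spectral counts (PSM units).

    ``counts`` maps ``(run_id, prey_id)`` to a non-negative integer count;
    missing pairs mean zero.
    """

    runs: list[RunRecord]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            dup = sorted({r for r in run_ids if run_ids.count(r) > 1})
            raise FormatError(f"duplicate run_id(s): {dup}")
        known = set(run_ids)
        for (rid, prey), c in self.counts.items():
            if rid not in known:
                raise FormatError(f"count references undeclared run_id {rid!r}")
            if c < 0:
                raise FormatError(f"negative count for run {rid!r}, prey {prey!r}")

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def preys(self) -> list[str]:
        return sorted({p for (_, p) in self.counts})

    def get_count(self, run_id: str, prey_id: str) -> int:
        return self.counts.get((run_id, prey_id), 0)

    def run(self, run_id: str) -> RunRecord:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(run_id)

    def test_runs(self) -> list[RunRecord]:
        return [r for r in self.runs if not r.is_control]

    def control_runs(self) -> list[RunRecord]:
        return [r for r in self.runs if r.is_control]

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame, one row per populated (run, prey) cell."""
        meta = {r.run_id: r for r in self.runs}
        rows = [
            {
                "run_id": rid,
                "bait_id": meta[rid].bait_id,
                "assay": meta[rid].assay,
                "labeling_time_h": meta[rid].labeling_time_h,
                "cell_line": meta[rid].cell_line,
                "replicate": meta[rid].replicate,
                "is_control": meta[rid].is_control,
                "prey_id": prey,
                "count": c,
            }
            for (rid, prey), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "run_id", "bait_id", "assay", "labeling_time_h",
                "cell_line", "replicate", "is_control", "prey_id", "count",
            ],
        )


@dataclass
class ControlLibrary:
    """Per-prey detection frequency and mean count across negative controls.

    ``mean_count`` averages over ALL control runs, zeros included, matching
    how a CRAPome-style frequency table is tabulated.
    """

    n_control_runs: int
    detection_frequency: dict[str, float] = field(default_factory=dict)
    mean_count: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_control_runs < 1:
            raise ValueError("n_control_runs must be positive")
        for p, f in self.detection_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"detection frequency out of [0,1] for {p!r}")
        for p, m in self.mean_count.items():
            if m < 0:
                raise ValueError(f"negative mean count for {p!r}")

    def frequency(self, prey_id: str) -> float:
        return self.detection_frequency.get(prey_id, 0.0)

    def mean(self, prey_id: str) -> float:
        return self.mean_count.get(prey_id, 0.0)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional score and name."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one shared base (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModelRecord:
    """A gene reduced to its TSS, for nearest-TSS peak annotation."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# run tables
# ---------------------------------------------------------------------------

_LONG_COLUMNS = [
    "run_id", "bait_id", "assay", "labeling_time_h",
    "cell_line", "replicate", "is_control", "prey_id", "count",
]


def _coerce_count(value, context: str) -> int:
    try:
        c = int(value)
    except (TypeError, ValueError):
        raise FormatError(f"non-integer count {value!r} at {context}") from None
    if c < 0:
        raise FormatError(f"negative count {c} at {context}")
    return c


def read_run_table(path: str | os.PathLike, dialect: str = "long_tsv") -> RunTable:
    """Read spectral counts in the long TSV or SAINT three-file dialect.

    ``long_tsv``: one row per populated (run, prey) cell with full run
    metadata repeated.  ``saint_triplet``: *path* is a directory holding
    ``interaction.txt`` (run, bait, prey, count), ``prey.txt`` (prey, gene)
    and ``bait.txt`` (run, bait, T|C); replicate numbers are assigned by
    order of appearance within each bait, assay defaults to BIOID and the
    labeling time to 0 because the triplet does not carry them.
    """
    if dialect == "long_tsv":
        return _read_long_tsv(path)
    if dialect == "saint_triplet":
        return _read_saint_triplet(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long_tsv(path) -> RunTable:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "prey_id": str})
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long run table missing column(s): {missing}")
    runs: dict[str, RunRecord] = {}
    counts: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rid = str(row.run_id)
        rec = RunRecord(
            run_id=rid,
            bait_id=str(row.bait_id),
            assay=str(row.assay),
            labeling_time_h=float(row.labeling_time_h),
            cell_line=str(row.cell_line),
            replicate=int(row.replicate),
            is_control=_parse_bool(row.is_control),
        )
        if rid in runs:
            if runs[rid] != rec:
                raise FormatError(f"conflicting metadata for run_id {rid!r} (row {i})")
        else:
            runs[rid] = rec
        key = (rid, str(row.prey_id))
        if key in counts:
            raise FormatError(f"duplicate (run, prey) cell {key} (row {i})")
        counts[key] = _coerce_count(row.count, f"row {i}")
    control_baits = {r.bait_id for r in runs.values() if r.is_control}
    test_baits = {r.bait_id for r in runs.values() if not r.is_control}
    mixed = control_baits & test_baits
    if mixed:
        import warnings

        warnings.warn(
            f"bait(s) {sorted(mixed)} labeled both control and non-control",
            stacklevel=2,
        )
    return RunTable(runs=list(runs.values()), counts=counts)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise FormatError(f"cannot parse boolean {v!r}")


def _read_saint_triplet(path) -> RunTable:
    d = os.fspath(path)
    inter = pd.read_csv(
        os.path.join(d, "interaction.txt"), sep="\t", header=None,
        names=["run_id", "bait_id", "prey_id", "count"],
        dtype={"run_id": str, "bait_id": str, "prey_id": str},
    )
    bait = pd.read_csv(
        os.path.join(d, "bait.txt"), sep="\t", header=None,
        names=["run_id", "bait_id", "tc"], dtype=str,
    )
    runs: list[RunRecord] = []
    rep_counter: dict[str, int] = {}
    for row in bait.itertuples(index=False):
        rep_counter[row.bait_id] = rep_counter.get(row.bait_id, 0) + 1
        is_control = row.tc.strip().upper() == "C"
        runs.append(
            RunRecord(
                run_id=row.run_id,
                bait_id=row.bait_id,
                assay="BIOID",
                labeling_time_h=0.0,
                cell_line="NA",
                replicate=rep_counter[row.bait_id],
                is_control=is_control,
            )
        )
    counts: dict[tuple[str, str], int] = {}
    for i, row in enumerate(inter.itertuples(index=False), start=1):
        counts[(row.run_id, row.prey_id)] = _coerce_count(row.count, f"interaction.txt row {i}")
    return RunTable(runs=runs, counts=counts)


def write_run_table(table: RunTable, path: str | os.PathLike, dialect: str = "long_tsv") -> None:
    if dialect == "long_tsv":
        table.to_frame().to_csv(path, sep="\t", index=False)
        return
    if dialect == "saint_triplet":
        d = os.fspath(path)
        os.makedirs(d, exist_ok=True)
        meta = {r.run_id: r for r in table.runs}
        with open(os.path.join(d, "interaction.txt"), "w") as fh:
            for (rid, prey), c in sorted(table.counts.items()):
                fh.write(f"{rid}\t{meta[rid].bait_id}\t{prey}\t{c}\n")
        with open(os.path.join(d, "bait.txt"), "w") as fh:
            for r in table.runs:
                fh.write(f"{r.run_id}\t{r.bait_id}\t{'C' if r.is_control else 'T'}\n")
        preys = table.preys
        with open(os.path.join(d, "prey.txt"), "w") as fh:
            for p in preys:
                fh.write(f"{p}\t{p}\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def build_control_library(table: RunTable) -> ControlLibrary:
    """Tabulate prey detection frequency and mean count over control runs."""
    controls = table.control_runs()
    if not controls:
        raise ValueError("run table has no control runs")
    n = len(controls)
    ids = [r.run_id for r in controls]
    det: dict[str, int] = {}
    total: dict[str, int] = {}
    for (rid, prey), c in table.counts.items():
        if rid in set(ids) and c > 0:
            det[prey] = det.get(prey, 0) + 1
            total[prey] = total.get(prey, 0) + c
    return ControlLibrary(
        n_control_runs=n,
        detection_frequency={p: k / n for p, k in det.items()},
        mean_count={p: t / n for p, t in total.items()},
    )


def write_control_library(lib: ControlLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_control_runs={lib.n_control_runs}\n")
        fh.write("prey_id\tdetection_frequency\tmean_count\n")
        for p in sorted(set(lib.detection_frequency) | set(lib.mean_count)):
            fh.write(f"{p}\t{lib.frequency(p):.10g}\t{lib.mean(p):.10g}\n")


def read_control_library(path) -> ControlLibrary:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#n_control_runs="):
            raise FormatError("control library must start with '#n_control_runs=N'")
        n = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"prey_id": str})
    return ControlLibrary(
        n_control_runs=n,
        detection_frequency=dict(zip(df["prey_id"], df["detection_frequency"].astype(float))),
        mean_count=dict(zip(df["prey_id"], df["mean_count"].astype(float))),
    )


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED5; column 5 is the score when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from None
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 else 0.0
            try:
                out.append(GenomicInterval(chrom, start, end, score, name))
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt_num(iv.score)}\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.10g}"


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Read bedGraph coverage; intervals may not overlap within a chrom."""
    cov: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: need 4 bedGraph columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from None
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            cov.setdefault(chrom, []).append((start, end, float(parts[3])))
    for chrom, ivs in cov.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping bedGraph intervals on {chrom} near {s2}")
    return cov


def write_bedgraph(cov: Mapping[str, list[tuple[int, int, float]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            for s, e, v in sorted(cov[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_num(v)}\n")


# ---------------------------------------------------------------------------
# reference interactions, gene sets, gene models, genomes
# ---------------------------------------------------------------------------

def read_reference_interactions(path) -> set[tuple[str, str]]:
    """Two-column bait-gene / prey-gene TSV -> directed pair set.

    Pairs are stored directed (bait, prey) with upper-cased symbols;
    known/novel lookups must check both directions because database pairs
    are undirected while bait/prey roles are experimental.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"reference interaction line needs 2 columns: {line!r}")
            pairs.add((parts[0].upper(), parts[1].upper()))
    return pairs


def write_reference_interactions(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ... per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs term, description, >=1 gene")
            term = parts[0]
            if term in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate term {term!r}")
            sets[term] = {g.upper() for g in parts[2:] if g}
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(set(sets[term])))
            fh.write(f"{term}\tna\t{genes}\n")


def read_gene_models(path) -> list[GeneModelRecord]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise FormatError(f"gene model table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
        raise FormatError(f"duplicate gene_id(s): {dup}")
    return [
        GeneModelRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_gene_models(genes: Iterable[GeneModelRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_genome_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
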