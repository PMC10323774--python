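"""Readers/writers for the genomic and tabular formats the pipeline consumes.

All coordinates are 0-based half-open (BED semantics); GTF input is converted
on read. The transcription start site (TSS) of a minus-strand gene is its
rightmost coordinate.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default chromosome allow-list: human autosomes plus X.
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


class MalformedRecordError(ValueError):
    """A line in an input file could not be parsed."""


class EmptyModelError(ValueError):
    """No usable gene models remain after parsing/filtering."""


@dataclass(frozen=True)
class GeneModel:
    """A single representative transcript for a gene.

    ``exons`` are half-open [start, end) intervals, sorted and pairwise
    disjoint. ``tss`` is the span start on the + strand and the span end on
    the − strand (the biological 5' end).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        expected_tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} inconsistent with strand "
                f"{self.strand} span (expected {expected_tss})"
            )

    @property
    def exon_length_bp(self) -> int:
        """Total exonic length (the gene's exon-model length)."""
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ReadSet:
    """Aligned read placements for one assay in one sample.

    ``total_reads`` is the library size used for depth normalisation and
    always equals ``len(intervals)``.
    """

    mark_or_assay: str
    sample_id: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return len(self.intervals)

    def midpoints_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted read midpoints per chromosome (float, for binning)."""
        by_chrom: dict[str, list[float]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start + end) / 2.0)
        return {c: np.sort(np.asarray(v, dtype=float)) for c, v in by_chrom.items()}


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in years and event indicator (1=death)."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.sample_id}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _parse_bed12(path: Path) -> dict[str, dict[str, tuple]]:
    """Parse BED12 into {gene_id: {transcript_key: (chrom, strand, exons)}}.

    The BED ``name`` field is interpreted as ``gene_id`` or
    ``gene_id|transcript_id``; lines sharing a gene_id are alternative
    transcripts.
    """
    genes: dict[str, dict[str, tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise MalformedRecordError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(parts)}"
                )
            try:
                chrom, start = parts[0], int(parts[1])
                name, strand = parts[3], parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise MalformedRecordError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            gene_id, _, tx_id = name.partition("|")
            genes.setdefault(gene_id, {})[tx_id or name] = (chrom, strand, exons)
    return genes


def _parse_gtf(path: Path) -> dict[str, dict[str, tuple]]:
    """Parse GTF exon records into the same per-gene transcript map."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if df.empty:
        return {}
    exons = df[df["Feature"] == "exon"]
    genes: dict[str, dict[str, tuple]] = {}
    for (gene_id, tx_id), grp in exons.groupby(["gene_id", "transcript_id"]):
        grp = grp.sort_values("Start")
        chrom = str(grp["Chromosome"].iloc[0])
        strand = str(grp["Strand"].iloc[0])
        ivals = tuple(zip(grp["Start"].astype(int), grp["End"].astype(int)))
        genes.setdefault(gene_id, {})[tx_id] = (chrom, strand, ivals)
    return genes


def read_gene_models(
    path: str | Path,
    seed: int | None = None,
    chromosomes: Sequence[str] | None = DEFAULT_CHROMOSOMES,
) -> list[GeneModel]:
    """Read gene models from GTF or BED12, one transcript per gene.

    When a gene has several transcripts one is selected uniformly at random
    under ``seed`` (the selection is logged). Genes outside the chromosome
    allow-list are dropped; pass ``chromosomes=None`` to keep everything.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        per_gene = _parse_gtf(path)
    else:
        per_gene = _parse_bed12(path)
    if chromosomes is not None:
        allowed = set(chromosomes)
        per_gene = {
            g: {t: rec for t, rec in txs.items() if rec[0] in allowed}
            for g, txs in per_gene.items()
        }
        per_gene = {g: txs for g, txs in per_gene.items() if txs}
    if not per_gene:
        raise EmptyModelError(f"no gene models found in {path}")

    rng = random.Random(seed)
    models = []
    for gene_id in sorted(per_gene):
        txs = per_gene[gene_id]
        tx_id = rng.choice(sorted(txs)) if len(txs) > 1 else next(iter(txs))
        if len(txs) > 1:
            logger.debug("gene %s: selected transcript %s of %d", gene_id, tx_id, len(txs))
        chrom, strand, exons = txs[tx_id]
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        models.append(GeneModel(gene_id, chrom, strand, tss, exons))
    return models


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (one line per model)."""
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offsets = ",".join(str(s - start) for s, _ in m.exons)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{start}\t{end}\t0\t{len(m.exons)}\t{sizes}\t{offsets}\n"
            )


def write_gtf(
    models: Iterable[GeneModel],
    path: str | Path,
    extra_transcripts: dict[str, list[tuple[tuple[int, int], ...]]] | None = None,
) -> None:
    """Write gene models as GTF (1-based closed on disk).

    ``extra_transcripts`` maps gene_id to additional exon tuples, emitted as
    alternative transcripts of the same gene.
    """
    with open(path, "w") as fh:
        for m in models:
            all_tx = [m.exons] + list((extra_transcripts or {}).get(m.gene_id, []))
            for k, exons in enumerate(all_tx, 1):
                tx = f"{m.gene_id}.t{k}"
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{tx}";'
                span = (exons[0][0], exons[-1][1])
                fh.write(
                    f"{m.chrom}\thmrisk\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{m.chrom}\thmrisk\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Read intervals (BED)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, label: str, sample_id: str = "",
                   unique: bool = False) -> ReadSet:
    """Read a 3+ column BED of read placements into a :class:`ReadSet`.

    Records with start >= end are rejected; the rejected count is logged as a
    warning. ``unique=True`` drops exact-duplicate placements (a simple
    duplicate-read filter; off by default since whether the upstream data
    were deduplicated is usually unknown).
    """
    intervals: list[tuple[str, int, int]] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedRecordError(
                    f"{path}:{lineno}: BED requires >= 3 columns"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                rejected += 1
                continue
            intervals.append((chrom, start, end))
    if rejected:
        logger.warning("%s: rejected %d records with start >= end", path, rejected)
    if unique:
        intervals = sorted(set(intervals))
    return ReadSet(mark_or_assay=label, sample_id=sample_id or Path(path).stem,
                   intervals=intervals)


def write_intervals(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in readset.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_intervals_bam(path: str | Path, label: str, sample_id: str = "") -> ReadSet:
    """Optional BAM support; requires pysam (install extra ``hmrisk[bam]``)."""
    import pysam

    intervals = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            intervals.append((rec.reference_name, rec.reference_start, rec.reference_end))
    return ReadSet(label, sample_id or Path(path).stem, intervals)


# ---------------------------------------------------------------------------
# Tabular
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    try:
        df = df.astype(float)
    except ValueError:
        bad = df.apply(pd.to_numeric, errors="coerce")
        row, col = next(zip(*np.where(bad.isna())))
        raise ValueError(
            f"{path}: non-numeric value at gene {df.index[row]!r}, "
            f"sample {df.columns[col]!r}"
        ) from None
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    # default float repr is shortest-round-trip, so values survive bit-exactly
    df.to_csv(path, sep="\t")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table (sample_id, time, event) into a DataFrame.

    Validates each row through :class:`SurvivalRecord`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    for rec in df.itertuples(index=False):
        SurvivalRecord(str(rec.sample_id), float(rec.time), int(rec.event))
    return df.set_index("sample_id")[["time", "event"]].astype({"time": float, "event": int})


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index()
    out.columns = ["sample_id", "time", "event"]
    out.to_csv(path, sep="\t", index=False)
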