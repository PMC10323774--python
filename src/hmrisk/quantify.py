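"""Expression quantification and binned signal profiles around the TSS.

Expression from read placements follows the RPKM convention
``L_j = n_j * 1e9 / (N * l_j)`` with ``n_j`` the reads whose midpoint falls
in an exon of gene ``j``, ``N`` the library size and ``l_j`` the exon-model
length. Chromatin-mark signal is quantified on a fixed grid of 100 bins of
100 bp covering TSS-5kb .. TSS+5kb, oriented 5'->3' along the gene, and
normalised the same way per bin: ``H = n_bin * 1e9 / (N * l_bin)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneModel, ReadSet

logger = logging.getLogger(__name__)

N_BINS = 100
BIN_WIDTH = 100
FLANK = N_BINS * BIN_WIDTH // 2  # 5 kb each side of the TSS


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a tumor/normal label per sample.

    ``unit`` tags the scale ("RPKM" for cell-line read data, "TPM" or a
    log-scale label for cohort matrices accepted as-is).
    """

    values: pd.DataFrame
    condition: pd.Series  # sample -> {"tumor", "normal"}
    unit: str = "RPKM"

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be >= 0")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]


@dataclass
class BinSignalTensor:
    """Normalised signal H indexed by (mark, sample, gene, bin).

    ``values`` has shape (n_marks, n_samples, n_genes, n_bins);
    ``total_reads[mark, sample]`` records the library sizes used for
    normalisation.
    """

    values: np.ndarray
    marks: list[str]
    samples: list[str]
    genes: list[str]
    total_reads: np.ndarray
    clipped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = (len(self.marks), len(self.samples), len(self.genes), N_BINS)
        if self.values.shape != expect:
            raise ValueError(f"tensor shape {self.values.shape} != {expect}")
        if (self.values < 0).any():
            raise ValueError("signal must be non-negative")

    def sel(self, mark: str) -> np.ndarray:
        """(n_samples, n_genes, n_bins) slice for one mark."""
        return self.values[self.marks.index(mark)]

    def mean_over_samples(self) -> np.ndarray:
        """(n_marks, n_genes, n_bins) mean across samples."""
        return self.values.mean(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with columns mark, sample, gene, bin, H."""
        m, s, g, b = np.meshgrid(
            np.arange(len(self.marks)), np.arange(len(self.samples)),
            np.arange(len(self.genes)), np.arange(N_BINS), indexing="ij",
        )
        return pd.DataFrame({
            "mark": np.asarray(self.marks)[m.ravel()],
            "sample": np.asarray(self.samples)[s.ravel()],
            "gene": np.asarray(self.genes)[g.ravel()],
            "bin": b.ravel() + 1,
            "H": self.values.ravel(),
        })

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame,
                        total_reads: Mapping[tuple[str, str], int] | None = None
                        ) -> "BinSignalTensor":
        marks = sorted(df["mark"].unique())
        samples = sorted(df["sample"].unique())
        genes = sorted(df["gene"].unique())
        values = np.zeros((len(marks), len(samples), len(genes), N_BINS))
        mi = {m: i for i, m in enumerate(marks)}
        si = {s: i for i, s in enumerate(samples)}
        gi = {g: i for i, g in enumerate(genes)}
        values[
            df["mark"].map(mi), df["sample"].map(si), df["gene"].map(gi), df["bin"] - 1
        ] = df["H"].to_numpy()
        tr = np.zeros((len(marks), len(samples)), dtype=int)
        if total_reads:
            for (m, s), n in total_reads.items():
                tr[mi[m], si[s]] = n
        return cls(values, marks, samples, genes, tr)


@dataclass
class SignalChangeMatrix:
    """log2 tumor/normal ratio of sample-mean signal, per (mark, gene, bin)."""

    values: np.ndarray  # (n_marks, n_genes, n_bins)
    marks: list[str]
    genes: list[str]
    pseudocount: float

    def feature_frame(self, marks: Sequence[str] | None = None) -> pd.DataFrame:
        """Genes x (mark:bin) wide table for model fitting."""
        marks = list(marks) if marks is not None else self.marks
        cols, data = [], []
        for m in marks:
            if m not in self.marks:
                raise KeyError(f"unknown mark {m!r}")
            idx = self.marks.index(m)
            cols.extend(f"{m}:bin{b + 1}" for b in range(N_BINS))
            data.append(self.values[idx])
        return pd.DataFrame(np.hstack(data), index=self.genes, columns=cols)


# ---------------------------------------------------------------------------
# Expression (cell-line read data)
# ---------------------------------------------------------------------------

def count_exonic_reads(reads: ReadSet, genes: Sequence[GeneModel]) -> pd.Series:
    """Reads whose midpoint falls inside an exon, per gene."""
    mids = reads.midpoints_by_chrom()
    counts = {}
    for g in genes:
        chrom_mids = mids.get(g.chrom)
        n = 0
        if chrom_mids is not None:
            for start, end in g.exons:
                lo = np.searchsorted(chrom_mids, start, side="left")
                hi = np.searchsorted(chrom_mids, end, side="left")
                n += hi - lo
        counts[g.gene_id] = n
    return pd.Series(counts, name=reads.sample_id)


def compute_expression(reads: ReadSet, genes: Sequence[GeneModel]) -> pd.Series:
    """RPKM-style expression per gene: ``n_j * 1e9 / (N * l_j)``."""
    if reads.total_reads == 0:
        raise ValueError("cannot normalise expression with zero total reads")
    for g in genes:
        if g.exon_length_bp <= 0:
            raise ValueError(f"gene {g.gene_id} has zero exon length")
    n_j = count_exonic_reads(reads, genes)
    l_j = pd.Series({g.gene_id: g.exon_length_bp for g in genes})
    return n_j * 1e9 / (reads.total_reads * l_j)


def expression_matrix(
    readsets: Mapping[str, ReadSet],
    genes: Sequence[GeneModel],
    condition: Mapping[str, str],
    unit: str = "RPKM",
) -> ExpressionMatrix:
    """Assemble per-replicate expression into an :class:`ExpressionMatrix`."""
    values = pd.DataFrame({sid: compute_expression(rs, genes)
                           for sid, rs in readsets.items()})
    return ExpressionMatrix(values, pd.Series(dict(condition)), unit)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def make_bins(gene: GeneModel) -> tuple[np.ndarray, bool]:
    """The gene's 100 half-open 100-bp windows over TSS +/- 5 kb.

    Returns (windows, clipped): ``windows`` is a (100, 2) array ordered
    5'->3' along the gene (reversed genomic order on the − strand); windows
    extending past the chromosome start are clipped at 0 and flagged.
    """
    lo = gene.tss - FLANK
    edges = lo + BIN_WIDTH * np.arange(N_BINS + 1)
    windows = np.stack([edges[:-1], edges[1:]], axis=1)
    clipped = lo < 0
    if clipped:
        windows = np.clip(windows, 0, None)
    if gene.strand == "-":
        windows = windows[::-1]
    return windows, clipped


def quantify_bin_signals(
    readsets: Mapping[tuple[str, str], ReadSet],
    genes: Sequence[GeneModel],
) -> BinSignalTensor:
    """Build the (mark, sample, gene, bin) signal tensor from read placements.

    Reads are assigned to the bin containing their midpoint; reads on a
    different chromosome than the gene are never counted.
    """
    marks = sorted({m for m, _ in readsets})
    samples = sorted({s for _, s in readsets})
    gene_ids = [g.gene_id for g in genes]
    values = np.zeros((len(marks), len(samples), len(gene_ids), N_BINS))
    total = np.zeros((len(marks), len(samples)), dtype=int)

    grids = []
    clipped = []
    for g in genes:
        w, c = make_bins(g)
        grids.append(w)
        if c:
            clipped.append(g.gene_id)
    if clipped:
        logger.warning("windows clipped at chromosome start for %d genes", len(clipped))

    for (mark, sample), rs in readsets.items():
        if rs.total_reads == 0:
            raise ValueError(f"zero total reads for ({mark}, {sample})")
        mi, si = marks.index(mark), samples.index(sample)
        total[mi, si] = rs.total_reads
        mids = rs.midpoints_by_chrom()
        for gi, (g, windows) in enumerate(zip(genes, grids)):
            chrom_mids = mids.get(g.chrom)
            if chrom_mids is None:
                continue
            # windows are contiguous on the genomic axis; histogram on edges
            genomic = windows if g.strand == "+" else windows[::-1]
            edges = np.append(genomic[:, 0], genomic[-1, 1])
            counts = np.diff(np.searchsorted(chrom_mids, edges, side="left"))
            if g.strand == "-":
                counts = counts[::-1]
            widths = windows[:, 1] - windows[:, 0]
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(widths > 0,
                             counts * 1e9 / (rs.total_reads * np.maximum(widths, 1)),
                             0.0)
            values[mi, si, gi] = h
    return BinSignalTensor(values, marks, samples, gene_ids, total,
                           clipped_genes=clipped)


# ---------------------------------------------------------------------------
# Tumor/normal comparison
# ---------------------------------------------------------------------------

def _check_aligned(tumor: BinSignalTensor, normal: BinSignalTensor) -> None:
    for attr in ("marks", "genes"):
        a, b = getattr(tumor, attr), getattr(normal, attr)
        if a != b:
            missing = sorted(set(a).symmetric_difference(b))
            raise ValueError(f"{attr} mismatch between tensors: {missing}")


def signal_change(
    tumor: BinSignalTensor,
    normal: BinSignalTensor,
    pseudocount: float = 1.0,
) -> SignalChangeMatrix:
    """log2((mean tumor + eps) / (mean normal + eps)) per (mark, gene, bin)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    _check_aligned(tumor, normal)
    mt = tumor.mean_over_samples()
    mn = normal.mean_over_samples()
    vals = np.log2((mt + pseudocount) / (mn + pseudocount))
    return SignalChangeMatrix(vals, list(tumor.marks), list(tumor.genes), pseudocount)


def compare_profiles(
    tumor: BinSignalTensor,
    normal: BinSignalTensor,
    genes: Sequence[str],
    marks: Sequence[str],
    delta: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-bin tumor/normal comparison for selected genes and marks.

    Returns a long table (gene, mark, bin, mean_tumor, mean_normal, log2_change,
    flagged, region) where ``region`` labels maximal runs of contiguous flagged
    bins ("start-end" in 1-based bin numbers, empty for unflagged bins).
    """
    if not genes or not marks:
        raise ValueError("gene and mark subsets must be non-empty")
    _check_aligned(tumor, normal)
    for g in genes:
        if g not in tumor.genes:
            raise KeyError(f"unknown gene {g!r}")
    for m in marks:
        if m not in tumor.marks:
            raise KeyError(f"unknown mark {m!r}")
    mt = tumor.mean_over_samples()
    mn = normal.mean_over_samples()
    rows = []
    for m in marks:
        mi = tumor.marks.index(m)
        for g in genes:
            gi = tumor.genes.index(g)
            t, n = mt[mi, gi], mn[mi, gi]
            change = np.log2((t + pseudocount) / (n + pseudocount))
            flagged = np.abs(change) > delta
            region = [""] * N_BINS
            b = 0
            while b < N_BINS:
                if flagged[b]:
                    e = b
                    while e + 1 < N_BINS and flagged[e + 1]:
                        e += 1
                    label = f"{b + 1}-{e + 1}"
                    for k in range(b, e + 1):
                        region[k] = label
                    b = e + 1
                else:
                    b += 1
            rows.append(pd.DataFrame({
                "gene": g, "mark": m, "bin": np.arange(1, N_BINS + 1),
                "mean_tumor": t, "mean_normal": n, "log2_change": change,
                "flagged": flagged, "region": region,
            }))
    return pd.concat(rows, ignore_index=True)
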