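"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a tumor/normal cell-line pair with replicated
chromatin-mark ChIP reads, replicate expression tables, and a survival
cohort:

* gene models are non-overlapping, mixed-strand, 1-10 exons;
* each mark has a spatial profile over the 100 TSS-flanking bins —
  promoter-peaked (bins 45-55), gene-body ramp (bins 51-100), or broad —
  and per-bin read counts are negative binomial (ChIP counts are
  overdispersed);
* for the causal marks (default H3K36me3 and H3K79me2) the tumor gene-body
  intensity is scaled by ``2**(effect * log2FC)`` of the gene's planted
  expression change, so expression change is driven by exactly those marks;
* cohort survival times are exponential with hazard
  ``lambda0 * exp(sum_j coef_j * x_j)`` over planted driver genes, with
  uniform censoring calibrated to the requested censored fraction.

Everything is deterministic under the master seed; the planted truths are
written to a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import GeneModel, ReadSet, write_gtf, write_intervals, write_matrix, write_survival
from .quantify import N_BINS, ExpressionMatrix, make_bins

#: The 11 marks profiled in both cell lines.
DEFAULT_MARKS = (
    "H2AFZ", "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me3",
    "H3K27ac", "H3K27me3", "H3K36me3", "H3K79me2", "H4K20me1",
)

DEFAULT_PROFILES = {
    "H2AFZ": "promoter", "H3K4me1": "promoter", "H3K4me2": "promoter",
    "H3K4me3": "promoter", "H3K9ac": "promoter", "H3K27ac": "promoter",
    "H3K9me3": "broad", "H3K27me3": "broad", "H4K20me1": "broad",
    "H3K36me3": "body", "H3K79me2": "body",
}

#: Default planted driver coefficients (log hazard per expression unit),
#: magnitudes typical of a fitted nine-gene signature.
DEFAULT_DRIVER_COEFS = (
    -0.288, -0.139, 0.499, -0.216, 0.378, -0.290, -0.443, -0.103, -0.100,
)


@dataclass
class SimConfig:
    n_genes: int = 300
    marks: tuple[str, ...] = DEFAULT_MARKS
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    n_replicates: int = 2            # ChIP replicates per condition, per mark
    n_expr_replicates: int = 4       # expression replicates per condition
    causal_marks: tuple[str, ...] = ("H3K36me3", "H3K79me2")
    effect: float = 1.0              # log2 signal change per log2 expression change
    frac_up: float = 0.2
    frac_down: float = 0.2
    reads_per_gene: float = 100.0    # mean signal reads per gene per sample
    mark_sigma: float = 1.0          # lognormal sd of gene-level mark intensity
    background_per_bin: float = 0.2  # mean background reads per bin
    dispersion: float = 0.3          # NB: var = mu + dispersion * mu^2
    replicate_sd: float = 0.25       # log2 sd of replicate expression noise
    cohort_n: int = 400
    cohort_normal_frac: float = 0.1
    cohort_sd: float = 1.0           # sd of cohort log-scale expression
    dropout_frac: float = 0.05       # genes given zeros in some cohort samples
    n_drivers: int = 9
    driver_coefs: tuple[float, ...] = DEFAULT_DRIVER_COEFS
    censoring: float = 0.3
    median_survival_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_up + self.frac_down > 1:
            raise ValueError("DEG fractions must sum to <= 1")
        if not 0 <= self.censoring < 1:
            raise ValueError("censoring fraction must be in [0, 1)")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        unknown = set(self.causal_marks) - set(self.marks)
        if unknown:
            raise ValueError(f"causal marks not in mark list: {sorted(unknown)}")


def _rng_for(cfg: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, key)))


# ---------------------------------------------------------------------------
# Gene models and planted expression truth
# ---------------------------------------------------------------------------

def gen_gene_models(cfg: SimConfig, chrom: str = "chr1",
                    chrom_length: int = 500_000_000) -> list[GeneModel]:
    """Non-overlapping gene models with mixed strands and 1-10 exons."""
    rng = _rng_for(cfg, 1)
    slot = 40_000  # gene span max 15 kb + flanks; keeps windows off neighbours
    if 10_000 + cfg.n_genes * slot > chrom_length:
        raise ValueError("chromosome too short for the requested gene count")
    models = []
    for i in range(cfg.n_genes):
        start = 10_000 + i * slot + int(rng.integers(0, 5_000))
        span = int(rng.integers(2_000, 15_000))
        n_exons = int(rng.integers(1, 11))
        cuts = np.sort(rng.choice(np.arange(1, span // 100), size=2 * n_exons - 2,
                                  replace=False)) * 100 if n_exons > 1 else np.array([], int)
        bounds = np.concatenate([[0], cuts, [span]])
        exons = tuple(
            (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
            for k in range(n_exons)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        models.append(GeneModel(f"G{i:04d}", chrom, strand, tss, exons))
    return models


def plant_truth(cfg: SimConfig) -> pd.DataFrame:
    """Planted per-gene truth: class (up/down/ns) and expression log2FC."""
    rng = _rng_for(cfg, 2)
    n_up = round(cfg.n_genes * cfg.frac_up)
    n_down = round(cfg.n_genes * cfg.frac_down)
    klass = np.array(["ns"] * cfg.n_genes, dtype=object)
    perm = rng.permutation(cfg.n_genes)
    klass[perm[:n_up]] = "up"
    klass[perm[n_up:n_up + n_down]] = "down"
    log2fc = np.where(
        klass == "up", rng.uniform(1.5, 4.0, cfg.n_genes),
        np.where(klass == "down", -rng.uniform(1.5, 4.0, cfg.n_genes),
                 rng.normal(0.0, 0.15, cfg.n_genes)),
    )
    # log2 expression scale of well-expressed genes, so the planted down
    # shifts rarely clip a cohort value to zero
    baseline = rng.uniform(5.0, 9.0, cfg.n_genes)
    return pd.DataFrame(
        {"klass": klass, "log2fc": log2fc, "baseline": baseline},
        index=[f"G{i:04d}" for i in range(cfg.n_genes)],
    )


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

_BIN_IDX = np.arange(N_BINS)


def _profile_weights(shape: str) -> np.ndarray:
    """Per-bin weight vector (sums to 1) in 5'->3' bin order."""
    if shape == "promoter":
        w = np.exp(-0.5 * ((_BIN_IDX + 1 - 50.5) / 3.0) ** 2)
    elif shape == "body":
        w = np.where(_BIN_IDX + 1 > 50, (_BIN_IDX + 1 - 50) / 50.0, 0.0)
    elif shape == "broad":
        w = np.ones(N_BINS)
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    return w / w.sum()


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def gen_hm_reads(
    cfg: SimConfig,
    genes: list[GeneModel],
    truth: pd.DataFrame,
    read_length: int = 100,
) -> dict[str, dict[tuple[str, str], ReadSet]]:
    """ChIP read placements per (mark, sample) for both conditions.

    Returns ``{"tumor": {(mark, sample): ReadSet}, "normal": {...}}``;
    sample ids are ``<condition>_rep<k>``. Read midpoints fall in the bin
    that generated them.
    """
    if all(_profile_weights(cfg.profiles[m]).sum() == 0 for m in cfg.marks):
        raise ValueError("zero intensity everywhere")
    rng = _rng_for(cfg, 3)
    grids = [make_bins(g)[0] for g in genes]
    log2fc = truth["log2fc"].to_numpy()
    # per (gene, mark) relative intensity, shared by all samples; ChIP
    # gene-level signals are heavy-tailed, so the spread is wide
    lam = np.exp(rng.normal(0.0, cfg.mark_sigma, size=(len(genes), len(cfg.marks))))
    out: dict[str, dict[tuple[str, str], ReadSet]] = {"tumor": {}, "normal": {}}
    half = read_length // 2
    for mi, mark in enumerate(cfg.marks):
        w = _profile_weights(cfg.profiles[mark])
        causal = mark in cfg.causal_marks
        for condition in ("tumor", "normal"):
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{condition}_rep{rep}"
                intervals: list[tuple[str, int, int]] = []
                for gi, g in enumerate(genes):
                    mu = cfg.reads_per_gene * lam[gi, mi] * w + cfg.background_per_bin
                    if causal and condition == "tumor":
                        body = _BIN_IDX + 1 > 50
                        mu = np.where(
                            body,
                            (mu - cfg.background_per_bin)
                            * 2.0 ** (cfg.effect * log2fc[gi])
                            + cfg.background_per_bin,
                            mu,
                        )
                    counts = _nb_draw(rng, mu, cfg.dispersion)
                    windows = grids[gi]
                    for b in np.nonzero(counts)[0]:
                        lo, hi = windows[b]
                        mids = rng.integers(lo, hi, size=counts[b])
                        intervals.extend(
                            (g.chrom, int(m - half), int(m + read_length - half))
                            for m in mids
                        )
                out[condition][(mark, sample)] = ReadSet(mark, sample, intervals)
    return out


# ---------------------------------------------------------------------------
# Expression and cohort
# ---------------------------------------------------------------------------

def gen_expression(cfg: SimConfig, truth: pd.DataFrame) -> ExpressionMatrix:
    """Replicate cell-line expression with the planted fold changes.

    Values are on a linear RPKM-like scale: ``2**(baseline +/- log2FC/2 +
    replicate noise)``; with ``replicate_sd=0`` the planted fold changes are
    exact.
    """
    rng = _rng_for(cfg, 4)
    cols, vals, cond = [], [], {}
    for condition, sign in (("tumor", 0.5), ("normal", -0.5)):
        for rep in range(1, cfg.n_expr_replicates + 1):
            sample = f"{condition}_rep{rep}"
            noise = rng.normal(0.0, cfg.replicate_sd, cfg.n_genes)
            log2val = truth["baseline"] + sign * truth["log2fc"] + noise
            cols.append(sample)
            vals.append(2.0 ** log2val)
            cond[sample] = condition
    values = pd.DataFrame(dict(zip(cols, vals)), index=truth.index)
    return ExpressionMatrix(values, pd.Series(cond), unit="RPKM")


def gen_cohort_expression(cfg: SimConfig, truth: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort expression matrix (log-scale units) and condition labels.

    Tumor samples carry the planted fold change; a random ``dropout_frac``
    of non-driver genes is zeroed in a random 15% of tumor samples to give
    the expressed-in-most-samples filter something to remove.
    """
    rng = _rng_for(cfg, 5)
    n_norm = round(cfg.cohort_n * cfg.cohort_normal_frac)
    n_tum = cfg.cohort_n - n_norm
    samples = [f"T{i:04d}" for i in range(n_tum)] + [f"N{i:04d}" for i in range(n_norm)]
    cond = pd.Series(["tumor"] * n_tum + ["normal"] * n_norm, index=samples)
    base = truth["baseline"].to_numpy()[:, None]
    fc = truth["log2fc"].to_numpy()[:, None]
    is_tumor = (cond == "tumor").to_numpy()[None, :]
    vals = base + fc * is_tumor + rng.normal(0.0, cfg.cohort_sd,
                                             (cfg.n_genes, cfg.cohort_n))
    vals = np.clip(vals, 0.0, None)
    n_drop = round(cfg.n_genes * cfg.dropout_frac)
    drop_genes = rng.choice(cfg.n_genes, size=n_drop, replace=False)
    for gi in drop_genes:
        drop_samples = rng.random(n_tum) < 0.15
        vals[gi, :n_tum][drop_samples] = 0.0
    expr = pd.DataFrame(vals, index=truth.index, columns=samples)
    return expr, cond


def choose_drivers(cfg: SimConfig, truth: pd.DataFrame,
                   dropout_safe: pd.DataFrame | None = None) -> pd.Series:
    """Planted driver genes with their hazard coefficients.

    Drivers are drawn from the planted DEGs with a two-thirds/one-third
    down/up split, mirroring the direction mix of elongation-mark changes
    typically seen across a driver-gene signature (most drivers lose the
    gene-body marks in tumor cells, a minority gains them).
    """
    rng = _rng_for(cfg, 6)
    pools = {k: list(truth.index[truth["klass"] == k]) for k in ("down", "up")}
    if dropout_safe is not None:
        ok = (dropout_safe > 0).mean(axis=1) > 0.95
        pools = {k: [g for g in v if ok.get(g, False)] for k, v in pools.items()}
    n_down = min(int(np.ceil(cfg.n_drivers * 2 / 3)), len(pools["down"]))
    n_up = cfg.n_drivers - n_down
    if n_up > len(pools["up"]):
        n_up = len(pools["up"])
        n_down = cfg.n_drivers - n_up
    if n_down > len(pools["down"]) or n_down + n_up < cfg.n_drivers:
        raise ValueError("not enough planted DEGs to host the drivers")
    drivers = np.concatenate([
        rng.choice(np.asarray(pools["down"]), size=n_down, replace=False),
        rng.choice(np.asarray(pools["up"]), size=n_up, replace=False),
    ])
    coefs = np.asarray(cfg.driver_coefs, dtype=float)[: cfg.n_drivers]
    if len(coefs) < cfg.n_drivers:
        raise ValueError("fewer driver coefficients than drivers")
    return pd.Series(coefs, index=drivers)


def gen_cohort(
    cfg: SimConfig,
    cohort_expr: pd.DataFrame,
    drivers: pd.Series,
    condition: pd.Series,
) -> pd.DataFrame:
    """Survival table for the tumor cohort samples.

    Times are exponential with hazard ``lambda0 * exp(eta)`` where ``eta``
    is the centred planted linear predictor; censoring times are uniform on
    [0, tau] with tau bisected so the censored fraction matches the config.
    """
    if not np.all(np.isfinite(drivers.to_numpy())):
        raise ValueError("planted coefficients must be finite")
    rng = _rng_for(cfg, 7)
    tumor = condition.index[condition == "tumor"]
    X = cohort_expr.loc[drivers.index, tumor].to_numpy()
    eta = drivers.to_numpy() @ X
    eta = eta - eta.mean()
    lam0 = np.log(2.0) / cfg.median_survival_years
    t_event = rng.exponential(1.0 / (lam0 * np.exp(eta)))
    if cfg.censoring == 0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    else:
        u = rng.random(len(t_event))

        def censored_frac(tau: float) -> float:
            return float(np.mean(t_event > tau * u))

        lo_t, hi_t = 1e-6, float(t_event.max()) * 100
        for _ in range(200):
            mid = 0.5 * (lo_t + hi_t)
            if censored_frac(mid) > cfg.censoring:
                lo_t = mid
            else:
                hi_t = mid
        tau = 0.5 * (lo_t + hi_t)
        c = tau * u
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": event}, index=tumor)


# ---------------------------------------------------------------------------
# One-call simulation + on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    reads: dict[str, dict[tuple[str, str], ReadSet]]
    expression: ExpressionMatrix
    cohort_expr: pd.DataFrame
    cohort_condition: pd.Series
    drivers: pd.Series
    survival: pd.DataFrame


def simulate(cfg: SimConfig) -> SimResult:
    """Generate every pipeline input under the master seed."""
    genes = gen_gene_models(cfg)
    truth = plant_truth(cfg)
    reads = gen_hm_reads(cfg, genes, truth)
    expression = gen_expression(cfg, truth)
    cohort_expr, cond = gen_cohort_expression(cfg, truth)
    drivers = choose_drivers(cfg, truth, dropout_safe=cohort_expr[
        cond.index[cond == "tumor"]])
    survival = gen_cohort(cfg, cohort_expr, drivers, cond)
    return SimResult(cfg, genes, truth, reads, expression, cohort_expr, cond,
                     drivers, survival)


def write_simulation(sim: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write the simulated inputs in the pipeline's on-disk layout.

    Layout: ``genes.gtf``, ``reads/<mark>__<sample>.bed``,
    ``expr/cellline_expr.tsv`` + ``expr/labels.tsv``, ``cohort/expr.tsv``,
    ``cohort/clinical.tsv``, ``truth.json``. Returns a manifest of paths.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "expr").mkdir(exist_ok=True)
    (outdir / "cohort").mkdir(exist_ok=True)
    manifest = {}
    write_gtf(sim.genes, outdir / "genes.gtf")
    manifest["genes"] = "genes.gtf"
    for condition, readsets in sim.reads.items():
        for (mark, sample), rs in readsets.items():
            rel = f"reads/{mark}__{sample}.bed"
            write_intervals(rs, outdir / rel)
            manifest[f"reads:{mark}:{sample}"] = rel
    write_matrix(sim.expression.values, outdir / "expr" / "cellline_expr.tsv")
    sim.expression.condition.rename("condition").rename_axis("sample").to_csv(
        outdir / "expr" / "labels.tsv", sep="\t")
    write_matrix(sim.cohort_expr, outdir / "cohort" / "expr.tsv")
    sim.cohort_condition.rename("condition").rename_axis("sample").to_csv(
        outdir / "cohort" / "labels.tsv", sep="\t")
    write_survival(sim.survival, outdir / "cohort" / "clinical.tsv")
    manifest.update({
        "cellline_expr": "expr/cellline_expr.tsv", "cellline_labels": "expr/labels.tsv",
        "cohort_expr": "cohort/expr.tsv", "cohort_labels": "cohort/labels.tsv",
        "clinical": "cohort/clinical.tsv",
    })
    truth_payload = {
        "seed": sim.config.seed,
        "causal_marks": list(sim.config.causal_marks),
        "classes": sim.truth["klass"].to_dict(),
        "log2fc": {g: float(v) for g, v in sim.truth["log2fc"].items()},
        "drivers": {g: float(c) for g, c in sim.drivers.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    manifest["truth"] = "truth.json"
    return manifest
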