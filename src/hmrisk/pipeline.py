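"""End-to-end orchestration: binned signals -> DEGs -> (optional mark
importance) -> entropy selection -> risk model.

A :class:`PipelineConfig` names the inputs (gene models, per-mark/sample read
BEDs, cell-line expression, cohort expression + clinical table) and the
stage parameters. :func:`run_pipeline` executes the stages in order, writes
each stage's output table into the run directory, and closes the run with a
manifest recording every input, output and a hash of the parameters, so an
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, entropy, importance, io_core, quantify, survival

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "run"
    genes: str = "genes.gtf"
    reads_dir: str = "reads"            # <mark>__<sample>.bed; sample encodes condition
    cellline_expr: str = "expr/cellline_expr.tsv"
    cellline_labels: str = "expr/labels.tsv"
    cohort_expr: str = "cohort/expr.tsv"
    cohort_labels: str = "cohort/labels.tsv"
    clinical: str = "cohort/clinical.tsv"

    fc_threshold: float = 1.0
    p_threshold: float = 0.01
    deg_mode: str = "welch"
    pseudocount: float = 1.0
    entropy_threshold: float = entropy.DEFAULT_ENTROPY_THRESHOLD
    entropy_marks: tuple[str, ...] = ("H3K36me3", "H3K79me2")
    expressed_frac: float = 0.9
    p_cut: float = 0.05
    multivariate_p: float | None = 0.05
    roc_horizons: tuple[float, ...] = (3.0, 5.0)
    seed: int = 0

    run_importance: bool = False
    importance_n_trees: int = 100
    importance_cv_mode: str = "oob"
    importance_subset_size: int = 5
    importance_marks: tuple[str, ...] | None = None  # None = all marks

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate_values()
        return cfg

    def validate_values(self) -> None:
        if not (0 <= self.expressed_frac <= 1):
            raise ValueError("expressed_frac must be in [0, 1]")
        if self.entropy_threshold <= 0:
            raise ValueError("entropy_threshold must be > 0")
        if self.p_threshold <= 0 or self.p_cut <= 0:
            raise ValueError("p thresholds must be > 0")

    def validate_paths(self) -> list[str]:
        """Missing input paths (empty when the config is runnable)."""
        base = Path(self.input_dir)
        missing = []
        for rel in (self.genes, self.reads_dir, self.cellline_expr,
                    self.cellline_labels, self.cohort_expr, self.cohort_labels,
                    self.clinical):
            if not (base / rel).exists():
                missing.append(str(base / rel))
        return missing

    def param_hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in ("input_dir", "out_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_condition_labels(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    cfg.validate_values()
    missing = cfg.validate_paths()
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    base = Path(cfg.input_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "param_hash": cfg.param_hash(),
        "inputs": [], "stages": {}, "outputs": [],
    }
    run_log: list[dict] = []

    def record(stage: str, outputs: list[str], t0: float) -> None:
        manifest["stages"][stage] = outputs
        manifest["outputs"].extend(outputs)
        run_log.append({"stage": stage, "seconds": round(_time.monotonic() - t0, 3)})

    def fail(stage: str, exc: Exception):
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        raise StageError(stage, exc) from exc

    # --- quantify ---------------------------------------------------------
    t0 = _time.monotonic()
    try:
        genes = io_core.read_gene_models(base / cfg.genes, seed=cfg.seed)
        readsets = {}
        for bed in sorted((base / cfg.reads_dir).glob("*.bed")):
            mark, _, sample = bed.stem.partition("__")
            readsets[(mark, sample)] = io_core.read_intervals(bed, mark, sample)
            manifest["inputs"].append(str(bed))
        if not readsets:
            raise FileNotFoundError(f"no read BEDs in {base / cfg.reads_dir}")
        tensor = quantify.quantify_bin_signals(readsets, genes)
        tumor_samples = [s for s in tensor.samples if s.startswith("tumor")]
        normal_samples = [s for s in tensor.samples if s.startswith("normal")]
        t_tensor = subset_samples(tensor, tumor_samples)
        n_tensor = subset_samples(tensor, normal_samples)
        changes = quantify.signal_change(t_tensor, n_tensor, cfg.pseudocount)
        mean_signal = pd.DataFrame(
            tensor.mean_over_samples().mean(axis=2),
            index=tensor.marks, columns=tensor.genes,
        ).T
        mean_signal.rename_axis("gene").to_csv(out / "mean_signal.tsv", sep="\t",
                                               float_format="%.6g")
        record("quantify", ["mean_signal.tsv"], t0)
    except StageError:
        raise
    except Exception as exc:
        fail("quantify", exc)

    # --- deg --------------------------------------------------------------
    t0 = _time.monotonic()
    try:
        expr_vals = io_core.read_matrix(base / cfg.cellline_expr)
        labels = _read_condition_labels(base / cfg.cellline_labels)
        expr = quantify.ExpressionMatrix(expr_vals, labels, unit="RPKM")
        degs = diffexpr.call_degs(expr, cfg.fc_threshold, cfg.p_threshold,
                                  cfg.pseudocount, mode=cfg.deg_mode)
        degs.rename_axis("gene").to_csv(out / "degs.tsv", sep="\t",
                                        float_format="%.6g")
        record("deg", ["degs.tsv"], t0)
    except Exception as exc:
        fail("deg", exc)

    # --- importance (optional) -------------------------------------------
    if cfg.run_importance:
        t0 = _time.monotonic()
        try:
            cv = importance.CVConfig(mode=cfg.importance_cv_mode)
            marks = (list(cfg.importance_marks) if cfg.importance_marks
                     else list(changes.marks))
            sweep = importance.sweep_combinations(
                changes, degs, marks=marks, cv=cv,
                n_trees=cfg.importance_n_trees, seed=cfg.seed)
            sweep.to_csv(out / "sweep.tsv", sep="\t", index=False,
                         float_format="%.6g")
            full_auc = sweep.loc[sweep["size"] == sweep["size"].max(), "auc"].max()
            freqs = importance.mark_frequencies(
                sweep, min(cfg.importance_subset_size, len(marks)), full_auc)
            freqs.rename("frequency_pct").rename_axis("mark").to_csv(
                out / "mark_frequencies.tsv", sep="\t", float_format="%.6g")
            record("importance", ["sweep.tsv", "mark_frequencies.tsv"], t0)
        except Exception as exc:
            fail("importance", exc)

    # --- entropy ----------------------------------------------------------
    t0 = _time.monotonic()
    try:
        tables = {m: entropy.gene_hm_entropy(tensor, m) for m in cfg.entropy_marks}
        diff = entropy.select_differential(tables, cfg.entropy_threshold)
        diff.rename_axis("gene").to_csv(out / "diffgenes.tsv", sep="\t")
        record("entropy", ["diffgenes.tsv"], t0)
    except Exception as exc:
        fail("entropy", exc)

    # --- survive ----------------------------------------------------------
    t0 = _time.monotonic()
    try:
        cohort = io_core.read_matrix(base / cfg.cohort_expr)
        cohort_labels = _read_condition_labels(base / cfg.cohort_labels)
        surv = io_core.read_survival(base / cfg.clinical)
        tumor_cohort = cohort_labels.index[cohort_labels == "tumor"].tolist()
        candidates = survival.build_candidates(
            diff.index.tolist(), degs, cohort, tumor_cohort, cfg.expressed_frac)
        seeds, uni = survival.univariate_screen(candidates, cohort, surv, cfg.p_cut)
        uni.to_csv(out / "univariate.tsv", sep="\t", float_format="%.6g")
        if len(seeds) >= 2:
            selected, lasso_info = survival.lasso_select(seeds, cohort, surv,
                                                         seed=cfg.seed)
        else:
            # an L1 path over a single covariate cannot select anything;
            # pass the lone screened gene straight to the joint fit
            selected, lasso_info = list(seeds), {"alpha": None, "cv": None}
        model, fit = survival.multivariate_fit(
            selected, cohort, surv, drop_insignificant=cfg.multivariate_p)
        fit.rename_axis("gene").to_csv(out / "model.tsv", sep="\t",
                                       float_format="%.6g")
        scores = survival.risk_score(model, cohort[tumor_cohort])
        scores.rename_axis("sample").to_csv(out / "risk_scores.tsv", sep="\t",
                                            float_format="%.6g")
        km = survival.km_curves(scores, surv)
        km_long = pd.concat(
            [curve.assign(group=grp).rename_axis("time").reset_index()
             for grp, curve in km["curves"].items()], ignore_index=True)
        km_long.to_csv(out / "km_curves.tsv", sep="\t", index=False,
                       float_format="%.6g")
        aucs = survival.time_dependent_roc(scores, surv, cfg.roc_horizons)
        summary = {
            "n_candidates": len(candidates),
            "n_seed_genes": len(seeds),
            "n_lasso_genes": len(selected),
            "model_genes": model.genes,
            "lasso_alpha": lasso_info["alpha"],
            "logrank_p": km["logrank_p"],
            "logrank_reliable": km["reliable"],
            "td_auc": {str(k): v for k, v in aucs.items()},
        }
        with open(out / "survival_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        record("survive", ["univariate.tsv", "model.tsv", "risk_scores.tsv",
                           "km_curves.tsv", "survival_summary.json"], t0)
    except StageError:
        raise
    except Exception as exc:
        fail("survive", exc)

    manifest["run_log"] = run_log
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def subset_samples(tensor: quantify.BinSignalTensor,
                   samples: list[str]) -> quantify.BinSignalTensor:
    """A tensor restricted to the given samples (order preserved)."""
    idx = [tensor.samples.index(s) for s in samples]
    if not idx:
        raise ValueError("empty sample subset")
    return quantify.BinSignalTensor(
        tensor.values[:, idx], list(tensor.marks), list(samples),
        list(tensor.genes), tensor.total_reads[:, idx],
        clipped_genes=list(tensor.clipped_genes),
    )
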