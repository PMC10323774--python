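"""Differential expression calls between tumor and normal cell lines.

Genes are classed up/down when |log2 fold change| exceeds a threshold and a
test statistic's two-sided p-value clears a cutoff. Two statistics are
available:

``welch``
    The Welch two-sample t statistic ``(mean_t - mean_n) / sqrt(s2_t/N_t +
    s2_n/N_n)`` with Satterthwaite degrees of freedom — the conventional
    choice and the default-documented intent.

``as_printed``
    A ratio-based variant that places the (pseudocounted) fold-change ratio,
    rather than the mean difference, over the same standard error, mapped
    through the standard normal tail. Kept because some published workflows
    define their score exactly this way.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)


def call_degs(
    expr: ExpressionMatrix,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    pseudocount: float = 1.0,
    mode: str = "welch",
    var_floor: float = 1e-8,
) -> pd.DataFrame:
    """Classify genes as up/down/ns between tumor and normal samples.

    Returns a table indexed by gene with columns ``mean_tumor``,
    ``mean_normal``, ``log2fc``, ``statistic``, ``p`` and ``klass``.
    ``pseudocount`` enters the fold-change ratio only, never the variance
    terms. When a condition has a single replicate its variance is 0 with a
    warning; zero pooled variance is floored at ``var_floor`` so the
    statistic stays finite.
    """
    if mode not in ("welch", "as_printed"):
        raise ValueError(f"unknown mode {mode!r}")
    tumor_samples = expr.samples_of("tumor")
    normal_samples = expr.samples_of("normal")
    if not tumor_samples or not normal_samples:
        raise ValueError("need at least one tumor and one normal sample")
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        logger.warning("a condition has < 2 replicates; its variance is 0")

    t_vals = expr.values[tumor_samples].to_numpy(dtype=float)
    n_vals = expr.values[normal_samples].to_numpy(dtype=float)
    n_t, n_n = t_vals.shape[1], n_vals.shape[1]
    mean_t, mean_n = t_vals.mean(axis=1), n_vals.mean(axis=1)
    var_t = t_vals.var(axis=1, ddof=1) if n_t > 1 else np.zeros(len(mean_t))
    var_n = n_vals.var(axis=1, ddof=1) if n_n > 1 else np.zeros(len(mean_n))

    log2fc = np.log2((mean_t + pseudocount) / (mean_n + pseudocount))
    se2 = np.maximum(var_t / n_t + var_n / n_n, var_floor)
    se = np.sqrt(se2)

    if mode == "welch":
        stat = (mean_t - mean_n) / se
        # Satterthwaite df; floored components keep the df finite
        vt = np.maximum(var_t, var_floor) / n_t
        vn = np.maximum(var_n, var_floor) / n_n
        df = (vt + vn) ** 2 / (
            vt**2 / max(n_t - 1, 1) + vn**2 / max(n_n - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        ratio = (mean_t + pseudocount) / (mean_n + pseudocount)
        stat = ratio / se
        p = 2.0 * stats.norm.sf(np.abs(stat))

    klass = np.where(
        (log2fc > fc_threshold) & (p < p_threshold), "up",
        np.where((log2fc < -fc_threshold) & (p < p_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2fc": log2fc,
            "statistic": stat,
            "p": p,
            "klass": klass,
        },
        index=expr.values.index,
    )


def deg_genes(degs: pd.DataFrame, classes: tuple[str, ...] = ("up", "down")) -> list[str]:
    """Gene ids whose class is in ``classes`` (default: all DEGs)."""
    return degs.index[degs["klass"].isin(classes)].tolist()
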