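"""Shannon-entropy selection of genes with sample-specific mark levels.

For each gene the mark signal is summed over the 100 bins to a gene-level
signal per sample, standardised against the per-sample extrema, converted to
a distribution over samples, and scored by Shannon entropy
``E_j = -sum_m P_m log2 P_m``. A gene whose signal is concentrated in few
samples (low entropy) has a "differential" mark level; entropy is maximal
(log2 M) when the signal is uniform across the M samples.

The standardisation ``SH = (H - H_min) / H_max`` divides by the per-sample
maximum rather than the max-min range; the classical min-max form is
available via ``standardization="minmax"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantify import BinSignalTensor

logger = logging.getLogger(__name__)

DEFAULT_ENTROPY_THRESHOLD = 1.549


def gene_hm_entropy(
    tensor: BinSignalTensor,
    mark: str,
    standardization: str = "as_printed",
    extrema: str = "per_sample",
) -> pd.DataFrame:
    """Per-gene Shannon entropy of one mark's signal across samples.

    Returns a table indexed by gene with one ``SH_<sample>`` column per
    sample, the across-sample distribution's ``entropy``, and a
    ``degenerate`` flag for genes whose standardised signal is zero in every
    sample (these are assigned the maximal entropy log2(M)).

    ``extrema`` controls where H_min/H_max come from: ``per_sample``
    (extrema over genes within each sample, the default) or ``per_gene``.
    """
    if standardization not in ("as_printed", "minmax"):
        raise ValueError(f"unknown standardization {standardization!r}")
    if mark not in tensor.marks:
        raise KeyError(f"mark {mark!r} not in tensor")
    sig = tensor.sel(mark)  # (samples, genes, bins)
    n_samples = sig.shape[0]
    if n_samples < 2:
        raise ValueError("entropy needs >= 2 samples carrying the mark")
    if n_samples == 2:
        logger.warning(
            "only 2 samples: entropy is capped at 1 bit, so any threshold "
            "above 1 selects every gene"
        )
    h = sig.sum(axis=2)  # gene-level signal, (samples, genes)

    if extrema == "per_sample":
        h_min = h.min(axis=1, keepdims=True)
        h_max = h.max(axis=1, keepdims=True)
    elif extrema == "per_gene":
        h_min = h.min(axis=0, keepdims=True)
        h_max = h.max(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown extrema mode {extrema!r}")
    if np.any(h_max <= 0):
        which = np.where(h_max.ravel() <= 0)[0]
        labels = ([tensor.samples[i] for i in which] if extrema == "per_sample"
                  else [tensor.genes[i] for i in which])
        raise ValueError(f"maximum signal is zero for {labels}")

    if standardization == "as_printed":
        sh = (h - h_min) / h_max
    else:
        span = np.where(h_max - h_min > 0, h_max - h_min, 1.0)
        sh = (h - h_min) / span

    tot = sh.sum(axis=0)  # per gene
    degenerate = tot <= 0
    safe_tot = np.where(degenerate, 1.0, tot)
    p = sh / safe_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=0)
    entropy[degenerate] = np.log2(n_samples)
    if degenerate.any():
        logger.warning("%d genes have zero standardised signal in all samples; "
                       "assigned maximal entropy", int(degenerate.sum()))

    out = pd.DataFrame(
        sh.T, index=tensor.genes,
        columns=[f"SH_{s}" for s in tensor.samples],
    )
    out["entropy"] = entropy
    out["degenerate"] = degenerate
    return out


def select_differential(
    tables: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_ENTROPY_THRESHOLD,
) -> pd.DataFrame:
    """Union of genes below the entropy threshold for any mark.

    ``tables`` maps mark name to the output of :func:`gene_hm_entropy`; all
    tables must share the same gene universe. Returns a table indexed by the
    selected genes with one boolean column per mark recording which mark(s)
    triggered selection and a ``marks`` column joining their names.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not tables:
        raise ValueError("no entropy tables given")
    marks = sorted(tables)
    universe = tables[marks[0]].index
    for m in marks[1:]:
        if not tables[m].index.equals(universe):
            raise ValueError("entropy tables do not share a gene universe")
    flags = pd.DataFrame(
        {m: tables[m]["entropy"] < threshold for m in marks}, index=universe
    )
    selected = flags[flags.any(axis=1)].copy()
    selected["marks"] = selected[marks].apply(
        lambda row: ",".join(m for m in marks if row[m]), axis=1
    )
    return selected
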