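"""Shared fixtures: one small simulated dataset reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from hmrisk import diffexpr, quantify
from hmrisk.pipeline import subset_samples
from hmrisk.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """60-gene simulation with the default mark panel and planted drivers."""
    return simulate(SimConfig(n_genes=60, seed=7))


@pytest.fixture(scope="session")
def tensor_small(sim_small):
    readsets = {**sim_small.reads["tumor"], **sim_small.reads["normal"]}
    return quantify.quantify_bin_signals(readsets, sim_small.genes)


@pytest.fixture(scope="session")
def changes_small(tensor_small):
    tumor = subset_samples(
        tensor_small, [s for s in tensor_small.samples if s.startswith("tumor")])
    normal = subset_samples(
        tensor_small, [s for s in tensor_small.samples if s.startswith("normal")])
    return quantify.signal_change(tumor, normal)


@pytest.fixture(scope="session")
def degs_small(sim_small):
    return diffexpr.call_degs(sim_small.expression)


def make_tensor(values, marks=None, samples=None, genes=None):
    """BinSignalTensor from a raw (marks, samples, genes, bins) array."""
    values = np.asarray(values, dtype=float)
    m, s, g, _ = values.shape
    return quantify.BinSignalTensor(
        values,
        marks=marks or [f"M{i}" for i in range(m)],
        samples=samples or [f"s{i}" for i in range(s)],
        genes=genes or [f"g{i}" for i in range(g)],
        total_reads=np.full((m, s), 1000, dtype=int),
    )


def gene_signal_tensor(per_sample_gene, marks=None, samples=None, genes=None):
    """Tensor whose bin-1 signal carries the given (samples x genes) values."""
    arr = np.asarray(per_sample_gene, dtype=float)
    values = np.zeros((1, arr.shape[0], arr.shape[1], quantify.N_BINS))
    values[0, :, :, 0] = arr
    return make_tensor(values, marks=marks, samples=samples, genes=genes)
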