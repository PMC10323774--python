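"""Expression quantification, TSS binning and tumor/normal signal change."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmrisk import quantify
from hmrisk.io_core import GeneModel, ReadSet
from hmrisk.quantify import BIN_WIDTH, FLANK, N_BINS

from conftest import make_tensor


def _gene(gene_id="g1", chrom="chr1", strand="+", exons=((10_000, 11_000),)):
    tss = exons[0][0] if strand == "+" else exons[-1][1]
    return GeneModel(gene_id, chrom, strand, tss, tuple(exons))


# ---------------------------------------------------------------------------
# make_bins
# ---------------------------------------------------------------------------

def test_make_bins_plus_strand_arithmetic():
    windows, clipped = quantify.make_bins(_gene(exons=((10_000, 12_000),)))
    assert not clipped
    assert windows.shape == (N_BINS, 2)
    assert tuple(windows[0]) == (5_000, 5_100)
    assert tuple(windows[-1]) == (14_900, 15_000)
    assert np.all(windows[:, 1] - windows[:, 0] == BIN_WIDTH)


def test_make_bins_minus_strand_reverses_order():
    g = _gene(strand="-", exons=((8_000, 10_000),))  # tss = 10000
    windows, _ = quantify.make_bins(g)
    assert tuple(windows[0]) == (14_900, 15_000)
    assert tuple(windows[-1]) == (5_000, 5_100)
    plus = quantify.make_bins(_gene(exons=((10_000, 12_000),)))[0]
    np.testing.assert_array_equal(windows, plus[::-1])


def test_make_bins_contract_any_gene():
    for tss in (5_000, 77_300, 1_000_000):
        g = _gene(exons=((tss, tss + 500),))
        windows, _ = quantify.make_bins(g)
        assert len(windows) == N_BINS
        assert np.all(windows[:, 1] - windows[:, 0] == BIN_WIDTH)
        assert windows.min() == tss - FLANK and windows.max() == tss + FLANK


def test_make_bins_clips_near_chromosome_start():
    windows, clipped = quantify.make_bins(_gene(exons=((3_000, 3_500),)))
    assert clipped
    assert windows.min() == 0


# ---------------------------------------------------------------------------
# compute_expression
# ---------------------------------------------------------------------------

def test_expression_formula_plug_in():
    # n_j reads with midpoints in a 1 kb exon, library of N reads
    gene = _gene(exons=((10_000, 11_000),))
    hits = [("chr1", 10_000 + 10 * i, 10_100 + 10 * i) for i in range(10)]
    elsewhere = [("chr1", 500_000, 500_100)] * 90
    rs = ReadSet("RNA", "s1", hits + elsewhere)
    expr = quantify.compute_expression(rs, [gene])
    assert expr["g1"] == pytest.approx(10 * 1e9 / (100 * 1000))


def test_expression_zero_hits_and_errors():
    gene = _gene()
    rs = ReadSet("RNA", "s1", [("chr2", 0, 100)])  # other chromosome only
    assert quantify.compute_expression(rs, [gene])["g1"] == 0.0
    with pytest.raises(ValueError, match="zero total reads"):
        quantify.compute_expression(ReadSet("RNA", "s1", []), [gene])


def test_expression_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    genes = []
    pos = 20_000
    for i in range(5):
        n_ex = rng.integers(1, 4)
        exons, p = [], pos
        for _ in range(n_ex):
            length = int(rng.integers(200, 2_000))
            exons.append((p, p + length))
            p += length + int(rng.integers(100, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        genes.append(GeneModel(f"g{i}", "chr1", strand, tss, tuple(exons)))
        pos = p + 5_000
    starts = rng.integers(15_000, pos, size=400)
    reads = [("chr1", int(s), int(s) + 100) for s in starts]
    rs = ReadSet("RNA", "s1", reads)

    expr = quantify.compute_expression(rs, genes)
    for g in genes:  # independent per-gene loop
        n = sum(
            1 for c, s, e in reads
            if c == g.chrom and any(a <= (s + e) / 2 < b for a, b in g.exons)
        )
        expected = n * 1e9 / (len(reads) * g.exon_length_bp)
        assert expr[g.gene_id] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# quantify_bin_signals
# ---------------------------------------------------------------------------

def test_bin_signal_formula_plug_in():
    gene = _gene(exons=((10_000, 12_000),))
    # 5 reads with midpoints in window [5000, 5100) = bin 1; 995 far away
    close = [("chr1", 5_000, 5_100)] * 5
    far = [("chr1", 800_000, 800_100)] * 995
    rs = ReadSet("H3K4me3", "s1", close + far)
    tensor = quantify.quantify_bin_signals({("H3K4me3", "s1"): rs}, [gene])
    assert tensor.values[0, 0, 0, 0] == pytest.approx(5 * 1e9 / (1000 * 100))
    assert tensor.values[0, 0, 0, 1] == 0.0  # no read overlaps bin 2


def test_bin_signal_matches_double_loop_oracle():
    rng = np.random.default_rng(3)
    genes = [
        _gene("gA", exons=((30_000, 33_000),)),
        _gene("gB", strand="-", exons=((58_000, 60_000),)),
        _gene("gC", exons=((90_000, 91_000),)),
    ]
    starts = rng.integers(20_000, 100_000, size=200)
    reads = [("chr1", int(s), int(s) + 100) for s in starts]
    rs = ReadSet("M", "s1", reads)
    tensor = quantify.quantify_bin_signals({("M", "s1"): rs}, genes)

    for gi, g in enumerate(genes):
        windows, _ = quantify.make_bins(g)
        for bi, (lo, hi) in enumerate(windows):
            n = sum(1 for c, s, e in reads if c == "chr1" and lo <= (s + e) / 2 < hi)
            expected = n * 1e9 / (200 * 100)
            assert tensor.values[0, 0, gi, bi] == pytest.approx(expected), (gi, bi)


def test_duplicating_reads_leaves_signal_unchanged():
    gene = _gene(exons=((10_000, 12_000),))
    rng = np.random.default_rng(9)
    reads = [("chr1", int(s), int(s) + 100)
             for s in rng.integers(5_000, 15_000, size=150)]
    rs = ReadSet("M", "s1", reads)
    doubled = ReadSet("M", "s1", reads + reads)
    t1 = quantify.quantify_bin_signals({("M", "s1"): rs}, [gene])
    t2 = quantify.quantify_bin_signals({("M", "s1"): doubled}, [gene])
    np.testing.assert_allclose(t1.values, t2.values)


def test_bin_counts_bounded_by_window_reads(tensor_small, sim_small):
    """Sum of per-bin counts cannot exceed reads whose midpoint is in the window."""
    readsets = {**sim_small.reads["tumor"], **sim_small.reads["normal"]}
    mark, sample = "H3K4me3", "tumor_rep1"
    rs = readsets[(mark, sample)]
    mi = tensor_small.marks.index(mark)
    si = tensor_small.samples.index(sample)
    mids = rs.midpoints_by_chrom()
    for gi, g in enumerate(sim_small.genes[:10]):
        h = tensor_small.values[mi, si, gi]
        n_binned = h.sum() * rs.total_reads * 100 / 1e9
        chrom_mids = mids[g.chrom]
        in_window = ((chrom_mids >= g.tss - FLANK) & (chrom_mids < g.tss + FLANK)).sum()
        assert n_binned <= in_window + 1e-6


def test_zero_total_reads_rejected():
    gene = _gene()
    with pytest.raises(ValueError, match="zero total reads"):
        quantify.quantify_bin_signals({("M", "s1"): ReadSet("M", "s1", [])}, [gene])


# ---------------------------------------------------------------------------
# signal_change / compare_profiles
# ---------------------------------------------------------------------------

def test_signal_change_closed_forms():
    vals_t = np.zeros((1, 1, 1, N_BINS))
    vals_n = np.zeros((1, 1, 1, N_BINS))
    vals_t[0, 0, 0, 0] = 4.0  # mean_t = 4*eps with eps=1, mean_n = 0
    vals_t[0, 0, 0, 1] = 7.0
    vals_n[0, 0, 0, 1] = 7.0
    change = quantify.signal_change(make_tensor(vals_t), make_tensor(vals_n),
                                    pseudocount=1.0)
    assert change.values[0, 0, 0] == pytest.approx(np.log2(5.0))
    assert change.values[0, 0, 1] == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_signal_change_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a = make_tensor(rng.gamma(2.0, 1.0, size=(2, 2, 3, N_BINS)))
    b = make_tensor(rng.gamma(2.0, 1.0, size=(2, 2, 3, N_BINS)))
    fwd = quantify.signal_change(a, b, 0.5).values
    rev = quantify.signal_change(b, a, 0.5).values
    np.testing.assert_allclose(fwd, -rev, atol=1e-12)


def test_compare_profiles_finds_planted_region():
    base = np.ones((1, 1, 2, N_BINS))
    boosted = base.copy()
    boosted[0, 0, 0, 39:60] = 20.0  # bins 40-60 strongly raised in gene g0
    tumor = make_tensor(boosted)
    normal = make_tensor(base)
    report = quantify.compare_profiles(tumor, normal, ["g0", "g1"], ["M0"],
                                       delta=0.5)
    g0 = report[report["gene"] == "g0"]
    regions = sorted(set(g0.loc[g0["flagged"], "region"]))
    assert regions == ["40-60"]
    assert not report[report["gene"] == "g1"]["flagged"].any()

    identical = quantify.compare_profiles(tumor, tumor, ["g0"], ["M0"], delta=0.5)
    assert not identical["flagged"].any()
    infinite = quantify.compare_profiles(tumor, normal, ["g0"], ["M0"],
                                         delta=np.inf)
    assert not infinite["flagged"].any()


def test_compare_profiles_unknown_keys():
    t = make_tensor(np.ones((1, 1, 1, N_BINS)))
    with pytest.raises(KeyError):
        quantify.compare_profiles(t, t, ["nope"], ["M0"])
    with pytest.raises(ValueError):
        quantify.compare_profiles(t, t, [], ["M0"])
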