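"""Hi-C expected model, peak calling and the shifted background."""

import numpy as np
import pandas as pd
import pytest

from rd3d.genome import Genome
from rd3d.hic import (
    HiCMatrix,
    SignificantInteractionSet,
    call_significant_interactions,
    expected_by_distance,
    expected_inter,
    shift_interactions,
)


def dense_intra(counts_by_sep, n=50, bin_size=10_000):
    """Matrix whose every pair at separation d carries counts_by_sep(d)."""
    ii, jj = np.triu_indices(n)
    counts = np.array([counts_by_sep(j - i) for i, j in zip(ii, jj)])
    nz = counts > 0
    return HiCMatrix("chr1", "chr1", bin_size, ii[nz], jj[nz], counts[nz], n, n)


def test_expected_reproduces_exact_decay_table():
    m = dense_intra(lambda d: 100 // (1 + d), n=40)
    model = expected_by_distance(m)
    for d in range(40):
        assert model.expected_by_sep[d] == pytest.approx(100 // (1 + d))


def test_expected_constant_counts():
    m = dense_intra(lambda d: 7, n=30)
    model = expected_by_distance(m)
    assert np.allclose(model.expected_by_sep, 7.0)


def test_expected_rejects_inter_and_empty():
    inter = HiCMatrix("chr1", "chr2", 10_000, [0], [0], [1], 10, 10)
    with pytest.raises(ValueError):
        expected_by_distance(inter)
    assert expected_inter(inter).global_expected == pytest.approx(1 / 100)


def test_caller_flags_single_hot_pair():
    def counts(d):
        return 50 if d == 10 else 2

    # one separation stratum is globally hot; spike a single pair instead
    m = dense_intra(lambda d: 2, n=60)
    hot = (m.bin_a == 5) & (m.bin_b == 25)
    counts_arr = m.count.copy()
    counts_arr[hot] = 20
    m = HiCMatrix("chr1", "chr1", 10_000, m.bin_a, m.bin_b, counts_arr, 60, 60)
    model = expected_by_distance(m)
    peaks = call_significant_interactions([m], [model], fdr=0.05)
    assert (5, 25) in peaks.pair_set("chr1", "chr1")
    assert len(peaks) == 1


def test_caller_empty_when_nothing_exceeds_expected():
    m = dense_intra(lambda d: 3, n=40)
    model = expected_by_distance(m)
    peaks = call_significant_interactions([m], [model], fdr=0.05)
    assert len(peaks) == 0


def test_peak_set_validates_fdr_and_dedups():
    table = pd.DataFrame(
        {
            "chrom_a": ["chr1", "chr1"],
            "bin_a": [7, 3],
            "chrom_b": ["chr1", "chr1"],
            "bin_b": [3, 7],
            "p": [1e-9, 1e-9],
            "q": [1e-6, 1e-6],
        }
    )
    peaks = SignificantInteractionSet(table, fdr=0.05, bin_size=10_000)
    assert len(peaks) == 1  # order-normalised duplicate removed
    assert peaks.pair_set("chr1", "chr1") == {(3, 7)}
    with pytest.raises(ValueError):
        SignificantInteractionSet(table.assign(q=0.5), fdr=0.05, bin_size=10_000)


def uniform_compartments(length=10_000_000, label="A"):
    return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [length], "name": [label]})


def ab_compartments(block, length):
    rows = []
    for i, start in enumerate(range(0, length, block)):
        rows.append(("chr1", start, min(start + block, length), "AB"[i % 2]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def test_shift_preserves_separation(peaks_factory):
    genome = Genome({"chr1": 10_000_000})
    peaks = peaks_factory([(100, 150)])
    shifted = shift_interactions(peaks, 2_000_000, genome, uniform_compartments())
    assert shifted.pair_set("chr1", "chr1") == {(300, 350)}


def test_shift_drops_out_of_range_pairs(peaks_factory):
    genome = Genome({"chr1": 3_000_000})  # 300 bins; shift of 200 bins
    peaks = peaks_factory([(100, 150)])
    shifted = shift_interactions(peaks, 2_000_000, genome, uniform_compartments(3_000_000))
    assert len(shifted) == 0


def test_shift_falls_back_to_minus_s_on_label_mismatch(peaks_factory):
    genome = Genome({"chr1": 10_000_000})
    # original anchors (A, A) at bins 200, 240; +2 Mb lands in the B block
    # [2.5 Mb, 5 Mb); -2 Mb stays in A
    comp = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [0, 2_500_000, 5_000_000],
            "end": [2_500_000, 5_000_000, 10_000_000],
            "name": ["A", "B", "A"],
        }
    )
    peaks = peaks_factory([(200, 240)])
    shifted = shift_interactions(peaks, 2_000_000, genome, comp)
    assert shifted.pair_set("chr1", "chr1") == {(0, 40)}


def test_shift_never_grows_and_warns_without_compartments(peaks_factory):
    genome = Genome({"chr1": 10_000_000})
    peaks = peaks_factory([(10, 60), (500, 700), (900, 990)])
    with pytest.warns(UserWarning):
        shifted = shift_interactions(peaks, 2_000_000, genome, None)
    assert len(shifted) <= len(peaks)
    for a, b in shifted.pair_set("chr1", "chr1"):
        assert b - a in {50, 200, 90}


def test_inter_shift_moves_each_axis(peaks_factory):
    genome = Genome({"chr1": 10_000_000, "chr2": 10_000_000})
    peaks = peaks_factory([("chr1", 100, "chr2", 100)])
    shifted = shift_interactions(peaks, 2_000_000, genome, uniform_compartments())
    (pair,) = shifted.table[["bin_a", "bin_b"]].itertuples(index=False)
    assert abs(pair.bin_a - 100) == 200 and abs(pair.bin_b - 100) == 200


def test_balancing_weights_fold_into_expected():
    m = dense_intra(lambda d: 10, n=20)
    w = np.ones(20)
    w[5] = 2.0  # bin 5 carries double weight
    m.weights = {"chr1": w}
    model = expected_by_distance(m)
    exp = model.expected_for(m)
    base = exp[(m.bin_a == 0) & (m.bin_b == 10)][0]
    boosted = exp[(m.bin_a == 5) & (m.bin_b == 15)][0]
    # same separation, but one anchor has twice the (mean-normalised) weight
    assert boosted / base == pytest.approx(2.0, rel=0.11)


def test_expected_log_pooling_covers_all_separations():
    m = dense_intra(lambda d: 100 // (1 + d), n=80)
    model = expected_by_distance(m, pool="log", n_strata=10)
    assert len(model.expected_by_sep) == 80
    assert np.all(np.isfinite(model.expected_by_sep))
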