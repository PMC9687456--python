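"""Window counting, Fisher exact windows and peak merging."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meripkit.peaks import (LibraryTotals, call_peaks, call_significant_windows,
                            count_windows, fisher_one_sided,
                            fisher_one_sided_many, merge_adjacent)


def hypergeom_tail_exact(a, b, c, d):
    """Independent oracle: P(X >= a) by exact big-integer enumeration."""
    M, K, N = a + b + c + d, a + b, a + c
    num = sum(comb(K, k) * comb(M - K, N - k)
              for k in range(a, min(K, N) + 1))
    return float(Fraction(num, comb(M, N)))


# ----------------------------------------------------------------- fisher


def test_fisher_minimal_observation_gives_one():
    assert fisher_one_sided(0, 100, 5, 95) == pytest.approx(1.0)


def test_fisher_equal_proportions_not_significant():
    assert fisher_one_sided(10, 90, 10, 90) > 0.5


def test_fisher_matches_enumeration_oracle():
    assert fisher_one_sided(10, 990, 1, 999) == pytest.approx(
        hypergeom_tail_exact(10, 990, 1, 999), abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(200):
        m1, m2 = rng.integers(1, 60, 2)
        n1 = rng.integers(0, m1 + m2 + 1)
        a = rng.integers(max(0, n1 - m2), min(m1, n1) + 1)
        b, c = m1 - a, n1 - a
        d = m2 - c
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            hypergeom_tail_exact(a, b, c, d), abs=1e-10)


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        fisher_one_sided(-1, 5, 2, 3)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(5, 60), st.integers(5, 60), st.integers(1, 30))
def test_fisher_monotone_in_observed_count(n_ip, n_in, col):
    """With margins fixed, a larger window IP count never raises p."""
    col = min(col, n_ip + n_in)
    lo, hi = max(0, col - n_in), min(n_ip, col)
    ps = [fisher_one_sided(a, n_ip - a, col - a, n_in - (col - a))
          for a in range(lo, hi + 1)]
    assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


def test_vectorized_fisher_agrees_with_scalar():
    totals = LibraryTotals(ip_total=1000, input_total=800)
    a = np.array([0, 5, 40, 100])
    c = np.array([3, 5, 5, 100])
    vec = fisher_one_sided_many(a, c, totals)
    for i in range(len(a)):
        scalar = fisher_one_sided(int(a[i]), 1000 - int(a[i]),
                                  int(c[i]), 800 - int(c[i]))
        assert vec[i] == pytest.approx(scalar, abs=1e-12)


# ---------------------------------------------------------------- windows


def _reads(rows):
    return pd.DataFrame(rows, columns=["seqname", "start", "end", "strand"])


def test_one_read_hits_every_overlapped_window():
    df = _reads([("chr1", 0, 100, "+")])
    w = count_windows(df, {"chr1": 200}, w=20)
    assert list(w["window_start"]) == [0, 20, 40, 60, 80]
    assert (w["count"] == 1).all()


def test_no_reads_empty_stream():
    w = count_windows(_reads([]), {"chr1": 200})
    assert len(w) == 0


def test_out_of_bounds_read_rejected(caplog):
    df = _reads([("chr1", 150, 250, "+"), ("chr1", 0, 50, "+")])
    with caplog.at_level("WARNING"):
        w = count_windows(df, {"chr1": 200})
    assert w["count"].sum() == 3  # only the in-bounds read's windows


def test_window_counts_match_quadratic_overlap_oracle(small_sim, small_annotation):
    reads = small_sim.library("coarse", "IP").head(1000)
    sizes = small_annotation.chrom_sizes
    w = 20
    got = count_windows(reads, sizes, w=w)
    lookup = {(r.seqname, r.strand, r.window_start): r.count
              for r in got.itertuples(index=False)}
    rng = np.random.default_rng(5)
    for _ in range(300):
        seqname = rng.choice(list(sizes))
        ws = int(rng.integers(0, sizes[seqname] // w)) * w
        for strand in "+-":
            expected = int(((reads["seqname"] == seqname)
                            & (reads["strand"] == strand)
                            & (reads["start"] < ws + w)
                            & (reads["end"] > ws)).sum())
            assert lookup.get((seqname, strand, ws), 0) == expected


def test_stranded_counting_separates_strands():
    df = _reads([("chr1", 0, 40, "+"), ("chr1", 0, 40, "-")])
    w = count_windows(df, {"chr1": 100}, w=20, stranded=True)
    assert len(w) == 4  # two windows per strand
    w2 = count_windows(df, {"chr1": 100}, w=20, stranded=False)
    assert len(w2) == 2 and (w2["count"] == 2).all()


# -------------------------------------------------------- significance


def _win(seqname, strand, start, count):
    return {"seqname": seqname, "strand": strand, "window_start": start,
            "count": count}


def test_zero_ip_window_never_significant():
    totals = LibraryTotals(1000, 1000)
    ipw = pd.DataFrame(columns=["seqname", "strand", "window_start", "count"])
    inw = pd.DataFrame([_win("chr1", "+", 0, 50)])
    out = call_significant_windows(ipw, inw, totals, min_cov=10)
    assert not out["significant"].any()


def test_planted_eightfold_window_is_significant():
    # 8-fold enriched window at ~30 reads coverage in equal-size libraries
    totals = LibraryTotals(100_000, 100_000)
    ipw = pd.DataFrame([_win("chr1", "+", 0, 27)])
    inw = pd.DataFrame([_win("chr1", "+", 0, 3)])
    out = call_significant_windows(ipw, inw, totals)
    assert out.loc[0, "significant"]
    assert out.loc[0, "p_value"] < 1e-4


def test_low_coverage_window_not_tested():
    totals = LibraryTotals(1000, 1000)
    ipw = pd.DataFrame([_win("chr1", "+", 0, 5)])
    inw = pd.DataFrame(columns=["seqname", "strand", "window_start", "count"])
    out = call_significant_windows(ipw, inw, totals, min_cov=10)
    assert not out["tested"].any() and not out["significant"].any()


# ---------------------------------------------------------------- merging


def _flagged(starts, sig, seqname="chr1", strand="+"):
    return pd.DataFrame({
        "seqname": seqname, "strand": strand, "window_start": starts,
        "ip_count": 10, "input_count": 1, "p_value": 0.01,
        "significant": sig})


def test_adjacent_significant_windows_merge():
    w = _flagged([100, 120], [True, True])
    peaks = merge_adjacent(w, w=20)
    assert len(peaks) == 1
    assert (peaks.loc[0, "start"], peaks.loc[0, "end"]) == (100, 140)
    assert peaks.loc[0, "ip_count"] == 20


def test_gap_splits_peaks_unless_allowed():
    w = _flagged([100, 120, 140], [True, False, True])
    assert len(merge_adjacent(w, w=20, max_gap=0)) == 2
    assert len(merge_adjacent(w, w=20, max_gap=1)) == 1


def test_merge_matches_run_length_oracle():
    rng = np.random.default_rng(6)
    starts = np.arange(0, 20 * 200, 20)
    sig = rng.random(200) < 0.3
    w = _flagged(starts, sig)
    peaks = merge_adjacent(w, w=20)
    # oracle: explicit run-length scan over the boolean vector
    runs = []
    i = 0
    while i < 200:
        if sig[i]:
            j = i
            while j + 1 < 200 and sig[j + 1]:
                j += 1
            runs.append((i * 20, (j + 1) * 20, j - i + 1))
            i = j + 1
        else:
            i += 1
    assert len(peaks) == len(runs)
    for k, (s, e, n) in enumerate(runs):
        assert (peaks.loc[k, "start"], peaks.loc[k, "end"],
                peaks.loc[k, "n_windows"]) == (s, e, n)
    # conservation: summed counts equal significant windows' totals
    assert peaks["ip_count"].sum() == int(sig.sum()) * 10


def test_merge_min_windows_drops_singletons():
    w = _flagged([0, 100, 120], [True, True, True])
    peaks = merge_adjacent(w, w=20, min_windows=2)
    assert len(peaks) == 1 and peaks.loc[0, "start"] == 100


def test_call_peaks_end_to_end_on_planted_data(small_sim, small_annotation):
    ip = small_sim.library("coarse", "IP")
    inp = small_sim.library("coarse", "Input")
    windows, peaks = call_peaks(ip, inp, small_annotation.chrom_sizes)
    tp = small_sim.truth.peaks_for("coarse")
    hits = 0
    for r in tp.itertuples(index=False):
        m = ((peaks["seqname"] == r.seqname) & (peaks["strand"] == r.strand)
             & (peaks["start"] < r.end) & (peaks["end"] > r.start))
        hits += int(m.any())
    assert hits / len(tp) >= 0.9
    assert (peaks["p_value"] > 0).all() and (peaks["p_value"] <= 1).all()
    assert (peaks["end"] - peaks["start"] >= 20).all()
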