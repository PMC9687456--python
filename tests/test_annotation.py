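"""Feature classification, region distributions, metagene profiles, GTF IO."""

import numpy as np
import pandas as pd
import pytest

from meripkit.annotation import (AnnotationError, CDS, GenomeAnnotation,
                                 INTERGENIC, REGION_PRIORITY, THREE_UTR,
                                 metagene_matrix, region_distribution)
from meripkit.simulate import SimulationConfig, simulate_dataset, simulate_genome


def _iv(seqname, start, end, strand="+"):
    return pd.DataFrame({"seqname": [seqname], "start": [start], "end": [end],
                         "strand": [strand]})


def test_interval_inside_cds_labelled_cds(small_annotation):
    g = next(g for g in small_annotation.genes.values() if g.coding)
    s, e, _ = next(iv for iv in g.intervals if iv[2] == CDS)
    mid = (s + e) // 2
    lab = small_annotation.classify_intervals(
        _iv(g.seqname, mid - 5, mid + 5, g.strand))[0]
    assert lab == CDS


def test_interval_outside_genes_is_intergenic(small_annotation):
    lab = small_annotation.classify_intervals(_iv("chr1", 0, 50, "+"))[0]
    assert lab == INTERGENIC


def test_unknown_seqname_raises(small_annotation):
    with pytest.raises(AnnotationError):
        small_annotation.classify_intervals(_iv("chrX", 0, 50, "+"))


def _per_base_oracle(ann, seqname, start, end, strand):
    """Per-base majority with priority tie-break, from the gene models directly."""
    prio = {lab: i for i, lab in enumerate(REGION_PRIORITY)}
    base_label = [prio[INTERGENIC]] * (end - start)
    for g in ann.genes.values():
        if g.seqname != seqname or g.strand != strand:
            continue
        for s, e, lab in g.intervals:
            for p in range(max(s, start), min(e, end)):
                base_label[p - start] = min(base_label[p - start], prio[lab])
    counts = np.bincount(base_label, minlength=len(REGION_PRIORITY))
    return REGION_PRIORITY[int(np.argmax(counts))]


def test_classification_matches_per_base_oracle(small_annotation):
    rng = np.random.default_rng(8)
    sizes = small_annotation.chrom_sizes
    rows = []
    for _ in range(500):
        seqname = str(rng.choice(list(sizes)))
        start = int(rng.integers(0, sizes[seqname] - 200))
        rows.append({"seqname": seqname, "start": start,
                     "end": start + int(rng.integers(20, 200)),
                     "strand": str(rng.choice(["+", "-"]))})
    df = pd.DataFrame(rows)
    got = small_annotation.classify_intervals(df)
    for i, r in enumerate(df.itertuples(index=False)):
        assert got[i] == _per_base_oracle(small_annotation, r.seqname, r.start,
                                          r.end, r.strand), (i, r)


def test_classification_invariant_to_order(small_annotation):
    rng = np.random.default_rng(9)
    sizes = small_annotation.chrom_sizes
    df = pd.DataFrame({
        "seqname": rng.choice(list(sizes), 50),
        "start": rng.integers(0, 10_000, 50),
        "strand": rng.choice(["+", "-"], 50)})
    df["end"] = df["start"] + 100
    fwd = small_annotation.classify_intervals(df)
    rev = small_annotation.classify_intervals(df.iloc[::-1].reset_index(drop=True))
    assert fwd == rev[::-1]


# -------------------------------------------------------------- distribution


def test_region_distribution_all_cds(small_annotation):
    g = next(g for g in small_annotation.genes.values() if g.coding)
    s, e, _ = next(iv for iv in g.intervals if iv[2] == CDS)
    df = pd.DataFrame({"seqname": [g.seqname] * 3,
                       "start": [s, s + 1, s + 2],
                       "end": [s + 10, s + 11, s + 12],
                       "strand": [g.strand] * 3})
    dist = region_distribution(df, small_annotation)
    assert dist.loc[CDS, "fraction"] == 1.0
    assert dist["count"].sum() == 3


def test_region_distribution_empty_warns(small_annotation):
    with pytest.warns(UserWarning):
        dist = region_distribution(pd.DataFrame(columns=["seqname", "start",
                                                         "end", "strand"]),
                                   small_annotation)
    assert (dist["fraction"] == 0).all()


def test_stop_codon_bias_puts_peaks_in_three_utr():
    cfg = SimulationConfig(n_genes=40, stop_codon_bias=1.0, noncoding_fraction=0.0,
                           depth_per_library=0, seed=12)
    with pytest.warns(UserWarning):
        genome, ann, sim = simulate_dataset(cfg)
    dist = region_distribution(sim.truth.true_peaks, ann)
    assert dist["fraction"].idxmax() == THREE_UTR


# ------------------------------------------------------------------ metagene


def _single_gene_annotation(strand):
    from meripkit.annotation import Gene, FIVE_UTR, THREE_UTR

    if strand == "+":
        ivs = [(1000, 1200, FIVE_UTR), (1200, 1800, CDS), (1800, 2000, THREE_UTR)]
    else:
        ivs = [(1000, 1200, THREE_UTR), (1200, 1800, CDS), (1800, 2000, FIVE_UTR)]
    g = Gene(gene_id="g1", seqname="chr1", strand=strand, start=1000, end=2000,
             coding=True, intervals=ivs)
    return GenomeAnnotation({"g1": g}, {"chr1": 3000})


def test_metagene_single_read_on_plus_tss_hits_center_bin():
    ann = _single_gene_annotation("+")
    reads = pd.DataFrame({"seqname": ["chr1"], "start": [1000], "end": [1001],
                          "strand": ["+"]})
    mat = metagene_matrix(reads, ann, anchor="TSS", flank=500, bins=50)
    assert mat.loc["g1"].sum() == 1
    assert mat.loc["g1", "bin_25"] == 1


def test_metagene_minus_strand_mirrors_plus():
    reads_plus = pd.DataFrame({"seqname": ["chr1"], "start": [1100],
                               "end": [1101], "strand": ["+"]})
    mat_plus = metagene_matrix(reads_plus, _single_gene_annotation("+"),
                               anchor="TSS", flank=500, bins=50)
    # equivalent minus-strand case: TSS at 1999, read 100 bp downstream (=1899)
    reads_minus = pd.DataFrame({"seqname": ["chr1"], "start": [1899],
                                "end": [1900], "strand": ["-"]})
    mat_minus = metagene_matrix(reads_minus, _single_gene_annotation("-"),
                                anchor="TSS", flank=500, bins=50)
    assert list(mat_plus.loc["g1"]) == list(mat_minus.loc["g1"])


def test_metagene_uniform_coverage_is_flat(small_annotation):
    rng = np.random.default_rng(14)
    g = next(g for g in small_annotation.genes.values()
             if g.strand == "+" and g.coding)
    n = 20_000
    starts = rng.integers(g.start - 600, g.end + 600, n)
    reads = pd.DataFrame({"seqname": g.seqname, "start": starts,
                          "end": starts + 100, "strand": "+"})
    mat = metagene_matrix(reads, small_annotation, anchor="stop_codon",
                          flank=400, bins=20)
    row = mat.loc[g.gene_id].to_numpy(dtype=float)
    assert row.std() / row.mean() < 0.1


def test_metagene_conservation(small_sim, small_annotation):
    reads = small_sim.library("coarse", "Input").head(2000)
    mat = metagene_matrix(reads, small_annotation, anchor="TSS", flank=200,
                          bins=10)
    # total equals the brute-force count of read-bin incidences
    total = 0
    for gid in mat.index:
        g = small_annotation.genes[gid]
        a = g.tss
        for b in range(10):
            if g.strand == "+":
                lo = a - 200 + b * 40
                hi = lo + 40
            else:
                hi = a + 1 + 200 - b * 40
                lo = hi - 40
            total += int(((reads["seqname"] == g.seqname)
                          & (reads["strand"] == g.strand)
                          & (reads["start"] < hi) & (reads["end"] > lo)).sum())
    assert int(mat.to_numpy().sum()) == total


def test_metagene_rejects_bad_arguments(small_annotation):
    reads = pd.DataFrame(columns=["seqname", "start", "end", "strand"])
    with pytest.raises(ValueError):
        metagene_matrix(reads, small_annotation, flank=0)
    with pytest.raises(ValueError):
        metagene_matrix(reads, small_annotation, anchor="middle")


# ------------------------------------------------------------------ GTF I/O


def test_gtf_round_trip(tmp_path):
    genome, ann = simulate_genome(SimulationConfig(n_genes=12, exons_per_gene=3,
                                                   seed=15))
    path = tmp_path / "a.gtf"
    ann.to_gtf(path)
    back = GenomeAnnotation.from_gtf(path, ann.chrom_sizes)
    assert set(back.genes) == set(ann.genes)
    for gid, g in ann.genes.items():
        b = back.genes[gid]
        assert (g.start, g.end, g.strand, g.coding) == (b.start, b.end, b.strand,
                                                        b.coding)
        assert g.intervals == b.intervals


def test_corrupted_gtf_raises(tmp_path):
    bad = tmp_path / "bad.gtf"
    bad.write_text("chr1\tx\tgene\tnot_a_number\t10\t.\t+\t.\tgene_id g;\n")
    with pytest.raises(AnnotationError):
        GenomeAnnotation.from_gtf(bad, {"chr1": 100})


def test_gene_assignment_maximal_overlap(small_annotation):
    g = sorted(small_annotation.genes.values(), key=lambda g: g.gene_id)[0]
    df = _iv(g.seqname, g.start + 10, g.start + 60, g.strand)
    assert small_annotation.assign_genes(df) == [g.gene_id]
    far = _iv(g.seqname, 0, 5, g.strand)
    assert small_annotation.assign_genes(far) == [None]
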