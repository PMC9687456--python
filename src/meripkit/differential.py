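"""Two-condition differential m6A peak analysis.

Peaks called independently in two conditions (named coarse and fine) are
matched by genomic overlap: the union of both peak sets is merged into
maximal intervals, and each merged interval is flagged by which condition(s)
contributed a peak.  Intervals present in only one condition are
condition-specific; matched intervals are tested for a methylation shift with
a two-sided Fisher exact test on the IP counts against the IP library totals
(``[[coarse_ip, N_c - coarse_ip], [fine_ip, N_f - fine_ip]]``), Input counts
entering only the normalized methylation ratio.  An alternative four-way
IP-vs-Input table is available via ``mode="four_way"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .peaks import PSEUDOCOUNT

CLASSES = ("up", "down", "ns", "coarse_specific", "fine_specific")


def match_peaks(coarse_peaks: pd.DataFrame, fine_peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge two peak sets into union intervals flagged by origin.

    Overlapping (>= 1 bp, same strand) peaks from the two conditions collapse
    into one union interval with ``in_coarse``/``in_fine`` flags; an interval
    seen in exactly one condition is that condition's specific peak.
    """
    frames = []
    for df, label in ((coarse_peaks, "coarse"), (fine_peaks, "fine")):
        if len(df):
            frames.append(df[["seqname", "strand", "start", "end"]]
                          .assign(origin=label))
    if not frames:
        return pd.DataFrame(columns=["seqname", "strand", "start", "end",
                                     "in_coarse", "in_fine"])
    both = pd.concat(frames, ignore_index=True).sort_values(
        ["seqname", "strand", "start", "end"]).reset_index(drop=True)
    out = []
    for (seqname, strand), rows in both.groupby(["seqname", "strand"], sort=True):
        cur = None
        for r in rows.itertuples(index=False):
            if cur is None or r.start >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {"seqname": seqname, "strand": strand, "start": r.start,
                       "end": r.end, "in_coarse": False, "in_fine": False}
            else:
                cur["end"] = max(cur["end"], r.end)
            cur[f"in_{r.origin}"] = True
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out, columns=["seqname", "strand", "start", "end",
                                      "in_coarse", "in_fine"])


def count_in_intervals(reads: pd.DataFrame, intervals: pd.DataFrame,
                       stranded: bool = True) -> np.ndarray:
    """Reads overlapping each interval by >= 1 bp (sorted-array bisection)."""
    idx: dict = {}
    strands = reads["strand"].to_numpy() if stranded else np.full(len(reads), ".")
    for key, rows in reads.assign(_s=strands).groupby(["seqname", "_s"], sort=False):
        idx[key] = (np.sort(rows["start"].to_numpy()), np.sort(rows["end"].to_numpy()))
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, r in enumerate(intervals.itertuples(index=False)):
        key = (r.seqname, r.strand if stranded else ".")
        if key not in idx:
            continue
        starts, ends = idx[key]
        out[i] = (np.searchsorted(starts, r.end, side="left")
                  - np.searchsorted(ends, r.start, side="right"))
    return out


def test_differential(coarse_ip: np.ndarray, fine_ip: np.ndarray,
                      coarse_ip_total: int, fine_ip_total: int,
                      coarse_input: np.ndarray | None = None,
                      fine_input: np.ndarray | None = None,
                      mode: str = "ip_totals") -> np.ndarray:
    """Two-sided Fisher exact p-values for a methylation shift per interval."""
    if coarse_ip_total <= 0 or fine_ip_total <= 0:
        raise ValueError("library totals must be positive")
    p = np.ones(len(coarse_ip))
    for i in range(len(coarse_ip)):
        if mode == "four_way":
            if coarse_input is None or fine_input is None:
                raise ValueError("four_way mode requires Input counts")
            table = [[int(coarse_ip[i]), int(coarse_input[i])],
                     [int(fine_ip[i]), int(fine_input[i])]]
        else:
            table = [[int(coarse_ip[i]), coarse_ip_total - int(coarse_ip[i])],
                     [int(fine_ip[i]), fine_ip_total - int(fine_ip[i])]]
        p[i] = fisher_exact(table, alternative="two-sided")[1]
    return p


def differential_peaks(coarse_peaks: pd.DataFrame, fine_peaks: pd.DataFrame,
                       reads: pd.DataFrame, alpha: float = 0.05,
                       stranded: bool = True, mode: str = "ip_totals") -> pd.DataFrame:
    """Match, count, test and classify peaks across the two conditions.

    ``reads`` is the molecule table with condition/library columns; counts in
    every union interval are taken per (condition, library).  Classes: ``up``
    (more methylated in coarse, p < alpha), ``down``, ``ns``, or
    ``coarse_specific``/``fine_specific`` for unmatched peaks.  The
    methylation ratio is log2 of the reads-per-million-normalized,
    pseudocounted (IP/Input) ratio of coarse over fine.
    """
    matched = match_peaks(coarse_peaks, fine_peaks)
    if len(matched) == 0:
        return matched.assign(p_value=[], log2_methylation_ratio=[], peak_class=[])
    counts, totals = {}, {}
    for cond in ("coarse", "fine"):
        for lib in ("IP", "Input"):
            sel = reads[(reads["condition"] == cond) & (reads["library"] == lib)]
            counts[(cond, lib)] = count_in_intervals(sel, matched, stranded=stranded)
            totals[(cond, lib)] = len(sel)
    p = test_differential(counts[("coarse", "IP")], counts[("fine", "IP")],
                          totals[("coarse", "IP")], totals[("fine", "IP")],
                          counts[("coarse", "Input")], counts[("fine", "Input")],
                          mode=mode)

    def rpm(cond, lib):
        return (counts[(cond, lib)] + PSEUDOCOUNT) / max(totals[(cond, lib)], 1) * 1e6

    ratio = np.log2((rpm("coarse", "IP") / rpm("coarse", "Input"))
                    / (rpm("fine", "IP") / rpm("fine", "Input")))
    cls = np.where(matched["in_coarse"] & ~matched["in_fine"], "coarse_specific",
                   np.where(matched["in_fine"] & ~matched["in_coarse"], "fine_specific",
                            np.where((p < alpha) & (ratio > 0), "up",
                                     np.where((p < alpha) & (ratio < 0), "down", "ns"))))
    out = matched.copy()
    out["coarse_ip"] = counts[("coarse", "IP")]
    out["coarse_input"] = counts[("coarse", "Input")]
    out["fine_ip"] = counts[("fine", "IP")]
    out["fine_input"] = counts[("fine", "Input")]
    out["p_value"] = p
    out["log2_methylation_ratio"] = ratio
    out["peak_class"] = cls
    return out


def summarize_differential(records: pd.DataFrame) -> dict:
    """Class totals at peak and gene level.

    Gene-level collapse assigns each gene the class of its most significant
    peak (smallest p; ties resolved in favour of ``up``).  Records must carry
    a ``gene`` column (peaks with no gene are counted at peak level only).
    """
    peak_counts = {c: int((records["peak_class"] == c).sum()) for c in CLASSES}
    gene_counts = dict.fromkeys(CLASSES, 0)
    pref = {c: i for i, c in enumerate(("up", "down", "coarse_specific",
                                        "fine_specific", "ns"))}
    with_gene = records.dropna(subset=["gene"]) if "gene" in records else records.iloc[0:0]
    for _gene, rows in with_gene.groupby("gene", sort=True):
        best = min(rows.itertuples(index=False),
                   key=lambda r: (r.p_value, pref[r.peak_class]))
        gene_counts[best.peak_class] += 1
    n_diff_genes = sum(gene_counts[c] for c in ("up", "down"))
    return {"peaks": peak_counts, "genes": gene_counts,
            "differential_genes": n_diff_genes}
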