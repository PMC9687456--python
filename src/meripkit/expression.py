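"""Expression quantification (RPKM), fold-change DE calls, mapping summaries,
methylation-expression overlaps, and gene-set over-representation.

Gene expression is quantified from the Input libraries (the non-enriched
RNA-seq role): RPKM = C * 1e9 / (N * L) with C the gene's read count, N the
library size and L the exon-model length in bp.  A gene is differentially
expressed when its pseudocounted coarse/fine RPKM ratio is strictly > 2 (up)
or < 0.5 (down); boundary values are not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .differential import count_in_intervals

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5
RPKM_PSEUDOCOUNT = 0.5


def rpkm(count, library_size, exon_length_bp):
    """Reads per kilobase of exon model per million mapped reads."""
    count = np.asarray(count, dtype=float)
    if np.any(np.asarray(library_size) <= 0) or np.any(np.asarray(exon_length_bp) <= 0):
        raise ValueError("library size and exon length must be positive")
    return count * 1e9 / (np.asarray(library_size, dtype=float)
                          * np.asarray(exon_length_bp, dtype=float))


def call_de(records: pd.DataFrame, up_threshold: float = UP_THRESHOLD,
            down_threshold: float = DOWN_THRESHOLD) -> pd.DataFrame:
    """Classify fold changes: strictly > up_threshold is up, < down is down."""
    fc = records["fold_change"].to_numpy()
    cls = np.where(fc > up_threshold, "up",
                   np.where(fc < down_threshold, "down", "ns"))
    out = records.copy()
    out["de_class"] = cls
    return out


def quantify_expression(reads: pd.DataFrame, annotation: GenomeAnnotation,
                        stranded: bool = True) -> pd.DataFrame:
    """Per-gene counts, RPKM and coarse/fine fold change from Input libraries.

    Returns one row per gene: exon_length, count/RPKM per condition, the
    pseudocounted fold change (coarse over fine) and the DE class.
    """
    gids = sorted(annotation.genes)
    gene_iv = pd.DataFrame({
        "seqname": [annotation.genes[g].seqname for g in gids],
        "strand": [annotation.genes[g].strand for g in gids],
        "start": [annotation.genes[g].start for g in gids],
        "end": [annotation.genes[g].end for g in gids]})
    lens = np.array([annotation.genes[g].exon_length for g in gids])
    data = {"gene": gids, "exon_length": lens}
    rpkms = {}
    for cond in ("coarse", "fine"):
        lib = reads[(reads["condition"] == cond) & (reads["library"] == "Input")]
        counts = count_in_intervals(lib, gene_iv, stranded=stranded)
        data[f"count_{cond}"] = counts
        data[f"library_size_{cond}"] = len(lib)
        rpkms[cond] = rpkm(counts, max(len(lib), 1), lens)
        data[f"rpkm_{cond}"] = rpkms[cond]
    fold = (rpkms["coarse"] + RPKM_PSEUDOCOUNT) / (rpkms["fine"] + RPKM_PSEUDOCOUNT)
    df = pd.DataFrame(data)
    df["fold_change"] = fold
    return call_de(df)


@dataclass(frozen=True)
class AlignmentSummary:
    """Mapping-rate bookkeeping with two-decimal percentages.

    ``unique`` and ``non_unique`` percentages use total mapped reads as the
    denominator; the mapped percentage uses total reads.
    """

    total_reads: int
    total_mapped: int
    unique_mapped: int

    def __post_init__(self):
        if not 0 <= self.unique_mapped <= self.total_mapped <= self.total_reads:
            raise ValueError("inconsistent alignment counts")

    @property
    def non_unique_mapped(self) -> int:
        return self.total_mapped - self.unique_mapped

    @property
    def mapped_pct(self) -> float:
        return round(100 * self.total_mapped / self.total_reads, 2)

    @property
    def unique_pct(self) -> float:
        return round(100 * self.unique_mapped / self.total_mapped, 2)

    @property
    def non_unique_pct(self) -> float:
        return round(100 * self.non_unique_mapped / self.total_mapped, 2)

    def as_dict(self) -> dict:
        return {"total_reads": self.total_reads, "total_mapped": self.total_mapped,
                "unique_mapped": self.unique_mapped,
                "non_unique_mapped": self.non_unique_mapped,
                "mapped_pct": self.mapped_pct, "unique_pct": self.unique_pct,
                "non_unique_pct": self.non_unique_pct}


def alignment_summary(flags: pd.DataFrame | None = None, *, total_reads: int | None = None,
                      total_mapped: int | None = None,
                      unique_mapped: int | None = None) -> AlignmentSummary:
    """Build an :class:`AlignmentSummary` from per-read flags or raw counts.

    ``flags`` needs boolean columns ``mapped`` and ``unique``; alternatively
    pass the three counts directly.
    """
    if flags is not None:
        total_reads = len(flags)
        total_mapped = int(flags["mapped"].sum())
        unique_mapped = int((flags["mapped"] & flags["unique"]).sum())
    if total_reads is None or total_mapped is None or unique_mapped is None:
        raise ValueError("provide either flags or all three counts")
    return AlignmentSummary(total_reads, total_mapped, unique_mapped)


def overlap_analysis(sets: dict[str, set]) -> dict:
    """All pairwise and triple intersection cardinalities of named gene sets."""
    names = sorted(sets)
    report = {"sizes": {n: len(sets[n]) for n in names}, "pairwise": {},
              "triple": {}}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report["pairwise"][f"{a}&{b}"] = len(sets[a] & sets[b])
            for c in names[i + 1:]:
                if c > b:
                    report["triple"][f"{a}&{b}&{c}"] = len(sets[a] & sets[b] & sets[c])
    return report


def gene_set_enrichment(study: set, population: set,
                        category_map: dict[str, list[str]]) -> pd.DataFrame:
    """Per-category hypergeometric over-representation with BH adjustment.

    ``category_map`` maps gene -> list of category names.  The p-value per
    category is the upper tail P(X >= observed overlap) for drawing
    ``len(study)`` genes from the population.
    """
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    cat_genes: dict[str, set] = {}
    for gene, cats in category_map.items():
        if gene not in population:
            continue
        for c in cats:
            cat_genes.setdefault(c, set()).add(gene)
    rows = []
    M, n_study = len(population), len(study)
    for cat in sorted(cat_genes):
        K = len(cat_genes[cat])
        k = len(cat_genes[cat] & study)
        p = float(hypergeom.sf(k - 1, M, K, n_study))
        rows.append({"category": cat, "category_size": K, "overlap": k,
                     "expected": K * n_study / M, "p_value": p})
    df = pd.DataFrame(rows, columns=["category", "category_size", "overlap",
                                     "expected", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_value", "category"]).reset_index(drop=True)
    return df
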