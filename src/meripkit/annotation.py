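"""Gene models, genomic feature classification, and metagene coverage profiles.

A :class:`GenomeAnnotation` holds single-transcript gene models whose exonic
sequence is partitioned into 5'UTR / CDS / 3'UTR for protein-coding genes or
NP_exon (non-protein-coding exon) for non-coding genes; introns and intergenic
space complete the label set used to classify reads and peaks.

Coordinates are 0-based half-open internally.  GTF is read and written as
1-based closed per the standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

FIVE_UTR = "five_prime_utr"
CDS = "CDS"
THREE_UTR = "three_prime_utr"
NP_EXON = "NP_exon"
INTRON = "intron"
INTERGENIC = "intergenic"

#: Tie-break priority for classification, highest first.
REGION_PRIORITY = (CDS, THREE_UTR, FIVE_UTR, NP_EXON, INTRON, INTERGENIC)
_PRIO = {lab: i for i, lab in enumerate(REGION_PRIORITY)}


class AnnotationError(ValueError):
    """Raised on malformed annotations or unknown sequence names."""


@dataclass
class Gene:
    """Single-transcript gene model with labelled sub-intervals.

    ``intervals`` are genomic, sorted, non-overlapping ``(start, end, label)``
    triples whose union equals ``[start, end)``.
    """

    gene_id: str
    seqname: str
    strand: str
    start: int
    end: int
    coding: bool
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e, lab in self.intervals if lab != INTRON)

    @property
    def tss(self) -> int:
        """Genomic position of the transcript 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def stop_codon_pos(self) -> int | None:
        """Genomic position of the CDS 3' boundary (None for non-coding)."""
        cds = [(s, e) for s, e, lab in self.intervals if lab == CDS]
        if not cds:
            return None
        return max(e for _, e in cds) - 1 if self.strand == "+" else min(s for s, _ in cds)


class GenomeAnnotation:
    """Container of :class:`Gene` models with fast region classification."""

    def __init__(self, genes: dict[str, Gene], chrom_sizes: dict[str, int],
                 metadata: dict | None = None):
        self.genes = dict(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self.metadata = metadata or {}
        self._cum: dict[tuple[str, str], np.ndarray] = {}
        for g in self.genes.values():
            if g.seqname not in self.chrom_sizes:
                raise AnnotationError(f"gene {g.gene_id} on unknown sequence {g.seqname}")
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.seqname]):
                raise AnnotationError(f"gene {g.gene_id} outside sequence bounds")

    # ---------------------------------------------------------------- labels

    def _cumulative(self, seqname: str, strand: str) -> np.ndarray:
        """Per-base label cumulative-count matrix, shape (6, L + 1).

        ``strand`` is '+', '-' or '.' (both strands pooled).  Bases covered by
        more than one label take the higher-priority label.
        """
        key = (seqname, strand)
        if key in self._cum:
            return self._cum[key]
        if seqname not in self.chrom_sizes:
            raise AnnotationError(f"unknown sequence name: {seqname}")
        size = self.chrom_sizes[seqname]
        lab = np.full(size, _PRIO[INTERGENIC], dtype=np.uint8)
        order = list(reversed(REGION_PRIORITY[:-1]))  # low priority first
        for want in order:
            for g in self.genes.values():
                if g.seqname != seqname or (strand != "." and g.strand != strand):
                    continue
                for s, e, l in g.intervals:
                    if l == want:
                        lab[s:e] = _PRIO[l]
        cum = np.zeros((len(REGION_PRIORITY), size + 1), dtype=np.int64)
        for i in range(len(REGION_PRIORITY)):
            cum[i, 1:] = np.cumsum(lab == i)
        self._cum[key] = cum
        return cum

    def classify_intervals(self, intervals: pd.DataFrame, stranded: bool = True) -> list[str]:
        """Label each interval by maximal per-base overlap.

        Ties are broken by the fixed priority CDS > 3'UTR > 5'UTR > NP_exon >
        intron > intergenic.  ``intervals`` needs columns seqname/start/end and
        strand when ``stranded``.
        """
        labels = [INTERGENIC] * len(intervals)
        idx = np.arange(len(intervals))
        strands = intervals["strand"].to_numpy() if stranded else np.full(len(intervals), ".")
        for (seqname, strand), rows in pd.DataFrame({
                "seqname": intervals["seqname"].to_numpy(),
                "strand": strands, "i": idx,
                "start": intervals["start"].to_numpy(),
                "end": intervals["end"].to_numpy()}).groupby(["seqname", "strand"], sort=False):
            cum = self._cumulative(seqname, strand)
            size = self.chrom_sizes[seqname]
            s = np.clip(rows["start"].to_numpy(), 0, size)
            e = np.clip(rows["end"].to_numpy(), 0, size)
            ov = cum[:, e] - cum[:, s]  # (6, n); rows already priority-ordered
            best = np.argmax(ov, axis=0)
            for i, b in zip(rows["i"], best):
                labels[i] = REGION_PRIORITY[b]
        return labels

    def classify_interval(self, seqname: str, start: int, end: int,
                          strand: str | None = None) -> str:
        """Classify one interval; ``strand=None`` pools both strands."""
        df = pd.DataFrame({"seqname": [seqname], "start": [start], "end": [end],
                           "strand": [strand or "."]})
        return self.classify_intervals(df, stranded=strand is not None)[0]

    def assign_genes(self, intervals: pd.DataFrame, stranded: bool = True) -> list[str | None]:
        """Assign each interval to the gene of maximal overlap (tie: alphabetical id)."""
        by_chrom: dict[str, list[Gene]] = {}
        for g in sorted(self.genes.values(), key=lambda g: g.gene_id):
            by_chrom.setdefault(g.seqname, []).append(g)
        out: list[str | None] = []
        for row in intervals.itertuples(index=False):
            best, best_ov = None, 0
            for g in by_chrom.get(row.seqname, []):
                if stranded and g.strand != row.strand:
                    continue
                ov = min(row.end, g.end) - max(row.start, g.start)
                if ov > best_ov:
                    best, best_ov = g.gene_id, ov
            out.append(best)
        return out

    # ------------------------------------------------------------------- io

    def to_gtf(self, path: str | Path) -> None:
        """Write the annotation as GTF (1-based closed coordinates)."""
        feature_of = {FIVE_UTR: "five_prime_utr", CDS: "CDS",
                      THREE_UTR: "three_prime_utr", NP_EXON: "exon"}
        with open(path, "w") as fh:
            for g in sorted(self.genes.values(), key=lambda g: (g.seqname, g.start)):
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                bt = "protein_coding" if g.coding else "non_coding"
                fh.write(f"{g.seqname}\tmeripkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs} gene_biotype \"{bt}\";\n")
                fh.write(f"{g.seqname}\tmeripkit\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
                for s, e, lab in g.intervals:
                    if lab == INTRON:
                        continue
                    fh.write(f"{g.seqname}\tmeripkit\texon\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t.\t{attrs}\n")
                    if feature_of[lab] != "exon":
                        fh.write(f"{g.seqname}\tmeripkit\t{feature_of[lab]}\t{s + 1}\t{e}\t.\t"
                                 f"{g.strand}\t.\t{attrs}\n")

    @classmethod
    def from_gtf(cls, path: str | Path, chrom_sizes: dict[str, int]) -> "GenomeAnnotation":
        """Load gene models from GTF using gffutils (coordinates converted to 0-based)."""
        try:
            db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                    disable_infer_genes=True, disable_infer_transcripts=True)
        except Exception as exc:  # noqa: BLE001 - surface parser context
            raise AnnotationError(f"cannot parse GTF {path}: {exc}") from exc
        genes: dict[str, Gene] = {}
        for f in db.features_of_type("gene"):
            gid = f.attributes["gene_id"][0]
            genes[gid] = Gene(gene_id=gid, seqname=f.seqid, strand=f.strand,
                              start=f.start - 1, end=f.end, coding=False, intervals=[])
        labelled: dict[str, dict[tuple[int, int], str]] = {g: {} for g in genes}
        for ftype, lab in (("exon", None), ("CDS", CDS),
                           ("five_prime_utr", FIVE_UTR), ("three_prime_utr", THREE_UTR)):
            for f in db.features_of_type(ftype):
                gid = f.attributes["gene_id"][0]
                iv = (f.start - 1, f.end)
                if lab is None:
                    labelled[gid].setdefault(iv, NP_EXON)
                else:
                    labelled[gid][iv] = lab
                    if lab == CDS:
                        genes[gid].coding = True
        for gid, g in genes.items():
            ivs = sorted((s, e, lab) for (s, e), lab in labelled[gid].items())
            # re-label bare exons of coding genes is not needed: our writer
            # emits UTR/CDS features alongside every coding exon
            full = []
            prev = g.start
            for s, e, lab in ivs:
                if s > prev:
                    full.append((prev, s, INTRON))
                full.append((s, e, lab))
                prev = e
            if prev < g.end:
                full.append((prev, g.end, INTRON))
            g.intervals = full
        return cls(genes, chrom_sizes)


def region_distribution(intervals: pd.DataFrame, annotation: GenomeAnnotation,
                        stranded: bool = True) -> pd.DataFrame:
    """Tally feature-class labels over a set of intervals.

    Returns a frame indexed by label with ``count`` and ``fraction`` columns;
    fractions sum to 1 (all zero for an empty input, with a warning).
    """
    counts = dict.fromkeys(REGION_PRIORITY, 0)
    if len(intervals) == 0:
        import warnings

        warnings.warn("empty interval set: all-zero region distribution", stacklevel=2)
        frac = [0.0] * len(REGION_PRIORITY)
    else:
        for lab in annotation.classify_intervals(intervals, stranded=stranded):
            counts[lab] += 1
        total = len(intervals)
        frac = [counts[lab] / total for lab in REGION_PRIORITY]
    return pd.DataFrame({"count": [counts[lab] for lab in REGION_PRIORITY],
                         "fraction": frac}, index=list(REGION_PRIORITY))


def metagene_matrix(reads: pd.DataFrame, annotation: GenomeAnnotation,
                    anchor: str = "TSS", flank: int = 500, bins: int = 50,
                    stranded: bool = True) -> pd.DataFrame:
    """Per-gene binned read coverage around an anchor (TSS or stop_codon).

    Rows are genes (coding genes only for ``stop_codon``), columns are bins
    ordered 5'→3' along the transcript; minus-strand profiles are flipped so
    the axis is transcript-oriented.  Bins beyond the sequence edge are zero.
    """
    if flank <= 0 or bins <= 0:
        raise ValueError("flank and bins must be positive")
    if anchor not in ("TSS", "stop_codon"):
        raise ValueError("anchor must be 'TSS' or 'stop_codon'")
    edges = np.linspace(-flank, flank, bins + 1).astype(int)
    pos_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    strands = reads["strand"].to_numpy() if stranded else np.full(len(reads), ".")
    for (seqname, strand), rows in reads.assign(_strand=strands).groupby(
            ["seqname", "_strand"], sort=False):
        pos_index[(seqname, strand)] = (np.sort(rows["start"].to_numpy()),
                                        np.sort(rows["end"].to_numpy()))
    out = {}
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        a = g.tss if anchor == "TSS" else g.stop_codon_pos
        if a is None:
            continue
        if g.strand == "+":
            bs = a + edges
            lo, hi = bs[:-1], bs[1:]
        else:
            # transcript offset t maps to genomic a - t, so [e_i, e_{i+1})
            # becomes [a - e_{i+1} + 1, a - e_i + 1)
            bs = a + 1 - edges
            lo, hi = bs[1:], bs[:-1]
        key = (g.seqname, g.strand if stranded else ".")
        if key not in pos_index:
            out[gid] = np.zeros(bins, dtype=int)
            continue
        starts, ends = pos_index[key]
        size = annotation.chrom_sizes[g.seqname]
        lo_c, hi_c = np.clip(lo, 0, size), np.clip(hi, 0, size)
        cov = (np.searchsorted(starts, hi_c, side="left")
               - np.searchsorted(ends, lo_c, side="right"))
        cov[hi_c <= lo_c] = 0
        out[gid] = np.maximum(cov, 0)
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=[f"bin_{i}" for i in range(bins)])
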