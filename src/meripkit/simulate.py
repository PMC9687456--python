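"""Synthetic MeRIP-seq data with known ground truth.

Emulates two conditions (coarse/fine) x two stranded libraries each (IP and
Input).  Input coverage is proportional to gene expression; IP coverage is
multiplied by a configurable enrichment inside planted m6A peaks, which sit
near stop codons with configurable bias and carry a planted motif (GGACT, the
DNA spelling of the canonical m6A GGACU/RRACH motif).  Molecules carry UMIs
and can be expanded into PCR-duplicate FASTQ reads with substitution errors,
so the whole downstream pipeline — deduplication, peak calling, differential
methylation, motif and expression analysis — can be exercised against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .annotation import (CDS, FIVE_UTR, INTRON, NP_EXON, THREE_UTR, Gene,
                         GenomeAnnotation)
from .io import Read

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONDITIONS = ("coarse", "fine")
LIBRARIES = ("IP", "Input")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study conditions: 100 genes of 1.5–3 kb,
    half carrying a true m6A peak at 8-fold IP enrichment, 200k expected
    molecules per library, 8-bp UMIs with one expected PCR duplicate per
    molecule, and a fifth of genes differentially expressed at 4-fold.
    """

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1500, 3000)
    exons_per_gene: int = 1
    noncoding_fraction: float = 0.1
    peak_fraction: float = 0.5
    peak_width: int = 100
    peak_enrichment: float = 8.0
    motif: str = "GGACT"
    stop_codon_bias: float = 0.8
    specific_peak_fraction: float = 0.2
    depth_per_library: int = 200_000
    read_length: int = 100
    umi_length: int = 8
    pcr_duplication_rate: float = 1.0
    seq_error_rate: float = 0.001
    de_fraction: float = 0.2
    de_fold: float = 4.0
    intergenic_gap: int = 500
    n_chromosomes: int = 2
    intron_length: int = 200
    stranded: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.peak_enrichment < 1:
            raise ConfigError("peak_enrichment must be >= 1")
        for name in ("noncoding_fraction", "peak_fraction", "stop_codon_bias",
                     "specific_peak_fraction", "seq_error_rate", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes < 1 or self.depth_per_library < 0:
            raise ConfigError("n_genes must be >= 1 and depth non-negative")
        lo, hi = self.gene_length_range
        min_len = 300 + (self.exons_per_gene - 1) * self.intron_length
        if lo > hi or lo < min_len:
            raise ConfigError(
                f"gene_length_range {self.gene_length_range} too short for the "
                f"exon structure (needs >= {min_len} bp)")
        if self.read_length >= lo:
            raise ConfigError("read_length must be shorter than the shortest gene")


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``true_peaks`` has one row per planted peak (gene, genomic interval,
    strand, and which condition carries it: both/coarse/fine); ``true_de``
    maps gene id -> coarse/fine expression fold change; ``true_molecules``
    counts unique pre-PCR molecules per (condition, library).
    """

    true_peaks: pd.DataFrame
    true_de: dict[str, float]
    true_molecules: dict[tuple[str, str], int]

    def peaks_for(self, condition: str) -> pd.DataFrame:
        m = self.true_peaks["condition"].isin(["both", condition])
        return self.true_peaks[m].reset_index(drop=True)


@dataclass
class ReadSimulation:
    """Simulated molecule placements plus lazy FASTQ expansion."""

    reads: pd.DataFrame  # one row per unique molecule
    truth: GroundTruth
    config: SimulationConfig
    genome: dict[str, str]

    def library(self, condition: str, library: str) -> pd.DataFrame:
        m = (self.reads["condition"] == condition) & (self.reads["library"] == library)
        return self.reads[m].reset_index(drop=True)

    def fastq_reads(self, condition: str, library: str) -> list[Read]:
        """Expand one library's molecules into UMI-prefixed PCR-duplicate reads."""
        return list(_pcr_expand(self.library(condition, library), self.genome,
                                self.config, condition, library))


# ------------------------------------------------------------------ genome


def _gene_structure(length: int, cfg: SimulationConfig, coding: bool):
    """Transcript-coordinate labelled segments: [(t_start, t_end, label), ...]."""
    if not coding:
        return [(0, length, NP_EXON)]
    utr5 = max(50, int(round(0.15 * length)))
    utr3 = max(100, int(round(0.25 * length)))
    return [(0, utr5, FIVE_UTR), (utr5, length - utr3, CDS),
            (length - utr3, length, THREE_UTR)]


def _exon_layout(tx_len: int, cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Transcript split into exons of near-equal length."""
    n = cfg.exons_per_gene
    bounds = np.linspace(0, tx_len, n + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n)]


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Build a random genome and gene annotation, planting true peaks.

    True m6A peaks (interval, carrying condition) are chosen here so the
    planted motif can be written into the genome sequence at each peak
    center; the placements are stored in ``annotation.metadata['true_peaks']``
    for :func:`simulate_reads` to consume.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tx_lens = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1,
                           cfg.n_genes)
    n_nc = int(round(cfg.noncoding_fraction * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    noncoding = set(order[:n_nc].tolist())
    strands = rng.choice(np.array(["+", "-"]), cfg.n_genes)

    genes: dict[str, Gene] = {}
    chrom_of, offset_of = [], []
    cursors = [cfg.intergenic_gap] * cfg.n_chromosomes
    tx_maps = []  # per gene: list of (t_start, t_end, g_start) exon blocks
    for i in range(cfg.n_genes):
        chrom = i % cfg.n_chromosomes
        tx_len = int(tx_lens[i])
        exons = _exon_layout(tx_len, cfg)
        genomic_len = tx_len + (len(exons) - 1) * cfg.intron_length
        g_start = cursors[chrom]
        cursors[chrom] = g_start + genomic_len + cfg.intergenic_gap
        chrom_of.append(chrom)
        offset_of.append(g_start)
        # transcript -> genome block map (strand-aware)
        blocks = []
        for j, (ts, te) in enumerate(exons):
            if strands[i] == "+":
                gs = g_start + ts + j * cfg.intron_length
            else:
                # transcript runs right-to-left on the genome
                gs_end = g_start + genomic_len - (ts + j * cfg.intron_length)
                gs = gs_end - (te - ts)
            blocks.append((ts, te, gs))
        tx_maps.append(blocks)

        gid = f"g{i:04d}"
        seqname = f"chr{chrom + 1}"
        coding = i not in noncoding
        segs = _gene_structure(tx_len, cfg, coding)
        ivs = []
        for ts, te, gs in blocks:
            for ss, se, lab in segs:
                lo, hi = max(ss, ts), min(se, te)
                if lo < hi:
                    if strands[i] == "+":
                        ivs.append((gs + (lo - ts), gs + (hi - ts), lab))
                    else:
                        ivs.append((gs + (te - hi), gs + (te - lo), lab))
        ivs.sort()
        filled, prev = [], g_start
        for s, e, lab in ivs:
            if s > prev:
                filled.append((prev, s, INTRON))
            filled.append((s, e, lab))
            prev = e
        if prev < g_start + genomic_len:
            filled.append((prev, g_start + genomic_len, INTRON))
        genes[gid] = Gene(gene_id=gid, seqname=seqname, strand=str(strands[i]),
                          start=g_start, end=g_start + genomic_len,
                          coding=coding, intervals=filled)

    chrom_sizes = {f"chr{c + 1}": cursors[c] for c in range(cfg.n_chromosomes)}
    seqs = {name: rng.integers(0, 4, size).astype(np.uint8)
            for name, size in chrom_sizes.items()}

    # ---- plant peaks
    n_pk = int(round(cfg.peak_fraction * cfg.n_genes))
    peak_genes = np.sort(rng.choice(cfg.n_genes, n_pk, replace=False))
    n_spec = int(round(cfg.specific_peak_fraction * n_pk))
    spec_idx = rng.choice(n_pk, n_spec, replace=False)
    cond_of = np.full(n_pk, "both", dtype=object)
    cond_of[spec_idx[: n_spec // 2]] = "coarse"
    cond_of[spec_idx[n_spec // 2:]] = "fine"

    rows = []
    w = cfg.peak_width
    for k, gi in enumerate(peak_genes):
        gid = f"g{gi:04d}"
        g = genes[gid]
        tx_len = int(tx_lens[gi])
        segs = _gene_structure(tx_len, cfg, g.coding)
        stop_t = next((e for s, e, lab in segs if lab == CDS), None)
        if stop_t is not None and rng.random() < cfg.stop_codon_bias:
            center_t = stop_t + int(rng.integers(-20, 21))
        else:
            center_t = int(rng.integers(w // 2, tx_len - w // 2))
        # keep the peak inside one exon so it is genomically contiguous
        blocks = tx_maps[gi]
        center_t = int(np.clip(center_t, 0, tx_len - 1))
        ts, te, gs = blocks[0]
        for b in blocks:
            if b[0] <= center_t < b[1]:
                ts, te, gs = b
                break
        center_t = int(np.clip(center_t, ts + w // 2, te - w // 2 - 1))
        p_lo_t, p_hi_t = center_t - w // 2, center_t + (w - w // 2)
        if g.strand == "+":
            p_lo = gs + (p_lo_t - ts)
            p_hi = gs + (p_hi_t - ts)
            m_lo = gs + (center_t - ts) - len(cfg.motif) // 2
            motif = cfg.motif
        else:
            p_lo = gs + (te - p_hi_t)
            p_hi = gs + (te - p_lo_t)
            m_hi = gs + (te - center_t) + len(cfg.motif) // 2
            m_lo = m_hi - len(cfg.motif)
            motif = reverse_complement(cfg.motif)
        enc = np.frombuffer(motif.encode().translate(
            bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))), dtype=np.uint8)
        seqs[g.seqname][m_lo:m_lo + len(motif)] = enc
        rows.append({"gene": gid, "seqname": g.seqname, "start": int(p_lo),
                     "end": int(p_hi), "strand": g.strand,
                     "condition": str(cond_of[k])})

    genome = {name: arr.tobytes().translate(
        bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")).decode()
        for name, arr in seqs.items()}
    true_peaks = pd.DataFrame(rows, columns=["gene", "seqname", "start", "end",
                                             "strand", "condition"])
    ann = GenomeAnnotation(genes, chrom_sizes,
                           metadata={"true_peaks": true_peaks})
    return genome, ann


# ------------------------------------------------------------------- reads


def _allowed_starts(gene: Gene, read_len: int) -> list[tuple[int, int]]:
    """Genomic [lo, hi) ranges of valid read start positions (read fits an exon)."""
    out = []
    for s, e, lab in gene.intervals:
        if lab != INTRON and e - s >= read_len:
            out.append((s, e - read_len + 1))
    return out


def simulate_reads(genome: dict[str, str], annotation: GenomeAnnotation,
                   config: SimulationConfig) -> ReadSimulation:
    """Draw molecule placements for all four libraries.

    Per-gene molecule counts are Poisson with mean proportional to exon length
    x expression (depth_per_library sets the expected library total); within a
    gene, start positions that put the read over a true peak carry
    ``peak_enrichment``-fold weight in IP libraries, so the expected IP/Input
    rate ratio inside a true peak equals the configured enrichment.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    gids = sorted(annotation.genes)
    n = len(gids)
    true_peaks = annotation.metadata.get("true_peaks",
                                        pd.DataFrame(columns=["gene", "seqname",
                                                              "start", "end",
                                                              "strand", "condition"]))
    if cfg.depth_per_library == 0:
        import warnings

        warnings.warn("zero depth: empty libraries", stacklevel=2)

    # expression truth
    base = rng.lognormal(0.0, 0.5, n)
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, n_de, replace=False)
    fold = np.ones(n)
    fold[de_idx[: n_de // 2]] = cfg.de_fold
    fold[de_idx[n_de // 2:]] = 1.0 / cfg.de_fold
    true_de = {gids[i]: float(fold[i]) for i in range(n)}

    lens = np.array([annotation.genes[g].exon_length for g in gids], dtype=float)
    peak_of = {r.gene: r for r in true_peaks.itertuples(index=False)}

    frames = []
    true_molecules = {}
    for cond in CONDITIONS:
        expr = base * (fold if cond == "coarse" else 1.0)
        weight = lens * expr
        weight = weight / weight.sum()
        for lib in LIBRARIES:
            recs = {"seqname": [], "start": [], "strand": [], "gene": []}
            for i, gid in enumerate(gids):
                g = annotation.genes[gid]
                ranges = _allowed_starts(g, cfg.read_length)
                if not ranges:
                    continue
                sizes = np.array([hi - lo for lo, hi in ranges])
                total_starts = sizes.sum()
                pk = peak_of.get(gid)
                pk_active = (pk is not None and lib == "IP"
                             and pk.condition in ("both", cond)
                             and cfg.peak_enrichment > 1)
                mean = cfg.depth_per_library * weight[i]
                if pk_active:
                    # starts whose read overlaps the peak interval
                    seg = []
                    for lo, hi in ranges:
                        a = max(lo, pk.start - cfg.read_length + 1)
                        b = min(hi, pk.end)
                        if a < b:
                            seg.append((a, b))
                    n_pk = sum(b - a for a, b in seg)
                    n_out = total_starts - n_pk
                    E = cfg.peak_enrichment
                    boost = (n_out + E * n_pk) / total_starts
                    n_mol = rng.poisson(mean * boost)
                    p_in = E * n_pk / (n_out + E * n_pk)
                    k_in = rng.binomial(n_mol, p_in)
                    starts_in = _uniform_starts(rng, seg, k_in)
                    out_seg = _subtract(ranges, seg)
                    starts_out = _uniform_starts(rng, out_seg, n_mol - k_in)
                    starts = np.concatenate([starts_in, starts_out])
                else:
                    n_mol = rng.poisson(mean)
                    starts = _uniform_starts(rng, ranges, n_mol)
                if len(starts) == 0:
                    continue
                recs["seqname"].append(np.full(len(starts), g.seqname, dtype=object))
                recs["start"].append(starts)
                if cfg.stranded:
                    recs["strand"].append(np.full(len(starts), g.strand, dtype=object))
                else:
                    recs["strand"].append(rng.choice(np.array(["+", "-"]), len(starts)))
                recs["gene"].append(np.full(len(starts), gid, dtype=object))
            if recs["start"]:
                df = pd.DataFrame({k: np.concatenate(v) for k, v in recs.items()})
            else:
                df = pd.DataFrame(columns=["seqname", "start", "strand", "gene"])
            df["start"] = df.get("start", pd.Series(dtype=int)).astype(int)
            df["end"] = df["start"] + cfg.read_length
            df["condition"] = cond
            df["library"] = lib
            codes = rng.integers(0, 4, (len(df), cfg.umi_length)).astype(np.uint8)
            if len(df):
                df["umi"] = np.ascontiguousarray(_BASES[codes]).view(
                    f"S{cfg.umi_length}").ravel().astype("U")
            else:
                df["umi"] = pd.Series(dtype=str)
            true_molecules[(cond, lib)] = len(df)
            frames.append(df)

    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["seqname", "start", "end", "strand", "gene", "condition",
                 "library", "umi"])
    reads = reads[["seqname", "start", "end", "strand", "gene", "condition",
                   "library", "umi"]]
    truth = GroundTruth(true_peaks=true_peaks, true_de=true_de,
                        true_molecules=true_molecules)
    return ReadSimulation(reads=reads, truth=truth, config=cfg, genome=genome)


def _uniform_starts(rng, ranges: list[tuple[int, int]], k: int) -> np.ndarray:
    if k == 0 or not ranges:
        return np.zeros(0, dtype=int)
    sizes = np.array([hi - lo for lo, hi in ranges])
    offs = rng.integers(0, sizes.sum(), k)
    bounds = np.cumsum(sizes)
    which = np.searchsorted(bounds, offs, side="right")
    lo = np.array([r[0] for r in ranges])
    prev = np.concatenate([[0], bounds[:-1]])
    return lo[which] + (offs - prev[which])


def _subtract(ranges, holes):
    """Set difference of [lo, hi) range lists (both sorted, holes within ranges)."""
    out = []
    for lo, hi in ranges:
        cur = lo
        for a, b in holes:
            if b <= lo or a >= hi:
                continue
            if a > cur:
                out.append((cur, a))
            cur = max(cur, b)
        if cur < hi:
            out.append((cur, hi))
    return out


def _pcr_expand(molecules: pd.DataFrame, genome: dict[str, str],
                cfg: SimulationConfig, condition: str, library: str) -> Iterator[Read]:
    """PCR-duplicate a molecule table into UMI-prefixed FASTQ reads.

    Copies per molecule are 1 + Poisson(pcr_duplication_rate); each copy gets
    independent substitution errors at seq_error_rate over the insert (the
    UMI prefix is copied exactly, so duplicates always share their UMI).
    """
    tag = f"{condition}_{library}"
    rng = np.random.default_rng([cfg.seed, 2, CONDITIONS.index(condition),
                                 LIBRARIES.index(library)])
    copies = 1 + rng.poisson(cfg.pcr_duplication_rate, len(molecules))
    for i, row in enumerate(molecules.itertuples(index=False)):
        insert = genome[row.seqname][row.start:row.end]
        if row.strand == "-":
            insert = reverse_complement(insert)
        for c in range(copies[i]):
            seq = insert
            n_err = rng.binomial(len(seq), cfg.seq_error_rate)
            if n_err:
                pos = rng.choice(len(seq), n_err, replace=False)
                arr = list(seq)
                for p in pos:
                    arr[p] = "ACGT"[(("ACGT".index(arr[p])) + int(rng.integers(1, 4))) % 4]
                seq = "".join(arr)
            yield Read(name=f"{tag}:m{i}:c{c}_{row.umi}", sequence=row.umi + seq)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: genome + annotation + reads in one call."""
    genome, ann = simulate_genome(config)
    sim = simulate_reads(genome, ann, config)
    return genome, ann, sim
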