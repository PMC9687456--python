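# Methods

## The experiment being modelled

MeRIP-seq compares an anti-m6A immunoprecipitated sequencing library (IP)
with a non-enriched library (Input) of the same fragmented, polyA-selected
RNA. Methylated regions show an excess of IP coverage relative to Input;
because the Input library is ordinary RNA-seq, it doubles as the expression
measurement. meripkit models a two-condition design (called *coarse* and
*fine*, after coarse- and fine-wool sheep skin pools) with one IP and one
Input library per condition, stranded, with UMI-tagged molecules amplified
into PCR-duplicate families.

## UMI consensus deduplication

Reads carry a fixed-length UMI as the first bases of the sequence (echoed in
the read name after `_`). Deduplication proceeds in three steps:

1. **Cluster** by exact UMI string (reads missing a UMI, or with one of the
   wrong length, are rejected and counted).
2. **Sub-cluster** greedily: the most abundant member sequence (ties broken
   lexicographically) seeds a sub-cluster that absorbs every remaining read
   whose global-alignment identity to the seed is strictly greater than 0.95;
   the process repeats on the remainder. Identity is matched columns over
   alignment columns under end-to-end alignment with match +1, mismatch −1,
   gap −2. The strict inequality means a pair at exactly 95% identity is
   split. Greedy seeding was chosen over all-vs-all transitive closure for
   determinism and linear passes; for same-fragment PCR duplicates the two
   give the same partition in practice.
3. **Consensus** by column-wise majority over a star alignment to the seed:
   each member is pairwise-aligned to the seed and its bases projected onto
   seed columns (insertions relative to the seed are dropped — full MSA is
   unnecessary for near-identical duplicates and this simplification is
   deliberate). Ties are broken by highest summed base quality, then
   alphabetically; a majority gap deletes the column. Consensus quality is
   the maximum member quality per column.

With error-free duplicates the number of consensus reads equals the number
of distinct molecules exactly (distinct molecules sharing a UMI are kept
apart because their inserts differ). With 1% per-base substitution errors,
families occasionally split: when no member sequence repeats, the seed is an
arbitrary erroneous copy, and two ~3-error copies can sit below 95% mutual
identity. The consensus of any family of ≥ 5 members still recovers the
template essentially always (majority over ≥ 5 votes at 1% per-base error);
the package's accuracy checks therefore condition on sub-clusters of ≥ 5
members.

## Peak calling

The genome is tiled with non-overlapping windows (default w = 20 bp,
anchored at coordinate 0). A read increments every window it overlaps by
≥ 1 bp; counting is strand-aware by default (the libraries are stranded),
with an unstranded mode available. Each window with combined coverage
≥ `min_cov` (default 10; the test is vacuous on smaller counts) is scored
with the one-sided Fisher exact test on

```
[[ a, N_IP − a ],
 [ c, N_In − c ]]
```

where a and c are the window's IP and Input counts and N are the library
totals — i.e. the hypergeometric tail P(X ≥ a) with margins fixed. Windows
with p < α (default 0.05, uncorrected; Benjamini–Hochberg available behind
a flag) are significant, and maximal runs of significant windows separated
by at most `max_gap` (default 0) non-significant windows merge into peaks.
Peak counts are summed over member windows, the peak p-value is the minimum
member p (no peak-level p is defined by the windowed test itself), and
enrichment is the pseudocounted rate ratio (a + 0.5)/N_IP over
(c + 0.5)/N_In.

`call_peaks` additionally drops runs of fewer than `min_windows = 2`
significant windows. With ~10⁴ uncorrected tests at α = 0.05, isolated
single-window hits are expected false positives, whereas a genuine peak
driven by 100–200 nt fragments always spans several windows; requiring two
adjacent independent rejections suppresses that background (on the default
synthetic conditions it lowers the false-discovery proportion from ~0.3 to
~0.12 without costing sensitivity). `merge_adjacent` itself keeps
`min_windows = 1` so the raw run-length semantics remain available.

## Differential methylation

Peaks called per condition are merged into union intervals flagged by
origin; intervals contributed by a single condition are that condition's
specific peaks. Matched intervals are tested two-sided on
`[[coarse_IP, N_c − coarse_IP], [fine_IP, N_f − fine_IP]]` (IP counts
against IP library totals); Input counts enter only the effect measure, the
log2 ratio of reads-per-million-normalized, 0.5-pseudocounted (IP/Input)
between conditions. Class `up`/`down` requires p < α and the matching ratio
sign. An alternative four-way IP-vs-Input table is available
(`mode="four_way"`).

A known property of the IP-totals test: a strong expression change shifts a
gene's share of the IP library even at constant methylation, so
expression-driven peaks can reach significance while their Input-normalized
ratio stays near zero (the sign of the small ratio then decides up/down).
This mirrors what a library-proportion Fisher test on pooled libraries can
and cannot distinguish without replicates; the downstream
methylation-expression overlap analysis is the intended consumer of these
calls.

Gene-level summaries collapse each gene to its most significant peak
(smallest p; ties prefer `up`).

## Annotation and metagene profiles

Gene models are single-transcript, with exonic sequence partitioned into
5'UTR / CDS / 3'UTR for coding genes or NP_exon for non-coding genes;
introns and intergenic space complete the label set. Coordinates are
0-based half-open internally; GTF is 1-based closed on ingest (gffutils)
and export, BED is 0-based. Classification assigns an interval the label of
maximal per-base overlap with fixed tie priority CDS > 3'UTR > 5'UTR >
NP_exon > intron > intergenic (the priority is a package choice; nothing in
the windowed statistics depends on it). Peaks are assigned to the gene of
maximal overlap, ties alphabetical. Metagene matrices bin strand-oriented
read coverage around the TSS or stop codon; rows near a sequence edge are
zero-padded.

## Motif enrichment

Peak sequences are extracted strand-oriented (minus-strand peaks
reverse-complemented). Each k-mer (default k = 5, the RRACH length; 4–8
supported) is scored by per-sequence presence/absence — the "ratio of
targets" convention — in a 2×2 table against a background set, with the
same one-sided Fisher machinery as peak calling and BH adjustment across
all tested k-mers (4^k simultaneous tests, unlike the window scan). The
default background is a seeded dinucleotide-preserving shuffle
(Altschul–Erikson style Euler-path resampling) of the targets. RRACH
matching uses {A,G}{A,G}AC{A,C,T} on the oriented sequence only.

## Expression integration

RPKM = C·10⁹/(N·L) with C the gene's Input read count, N the Input library
size and L the exon-model length. Gene counts use the Input libraries only
(their RNA-seq role). Fold change is (RPKM_coarse + 0.5)/(RPKM_fine + 0.5);
DE classes use strict inequalities (fold > 2 up, < 0.5 down, boundaries not
significant). Mapping summaries reproduce the published percentage
convention: mapped% over total reads, unique% and non-unique% over total
mapped reads, each rounded to two decimals — the denominator choice is
inferred from reproducing all sixteen printed cells of the source table.
Overlap analysis reports pairwise and triple intersection cardinalities of
named gene sets; gene-set over-representation is the upper hypergeometric
tail with BH adjustment, replacing live GO/KEGG lookups with user-supplied
category maps.

## qPCR

ΔCt = Ct_target − Ct_reference per sample; the calibrator is the mean ΔCt
of the reference group (fine, the reference phenotype — configurable), so
RQ = 2^−ΔΔCt is ~1 in the reference group and the fold change in the
comparison group. Group differences use Welch's t on replicate ΔCt values
(the standard choice for this design; no amplification-efficiency
correction is attempted). At least two replicates per group are required.

## Synthetic data generator

The generator defines the study conditions. Defaults: 100 genes of
1.5–3 kb on 2 chromosomes (10% non-coding), single-exon by default
(multi-exon supported), 50 true peaks (fraction 0.5) of 100 bp at 8-fold IP
enrichment, 80% placed within ±20 nt of the stop codon, 20% of peaks
condition-specific (half coarse-only, half fine-only), GGACT planted at each
peak center in genome space on the gene strand, 200,000 expected molecules
per library, 100-bp reads, 8-bp UMIs, one expected PCR duplicate per
molecule, 0.1% per-base substitution error on duplicates (never on the
UMI), 20% of genes differentially expressed at 4-fold (half up, half down),
lognormal(0, 0.5) baseline expression. Per-gene molecule counts are Poisson
with mean proportional to exon length × expression; within a gene, start
positions whose read would overlap a true peak carry enrichment-fold weight
in IP libraries, so the expected IP/Input rate ratio inside a peak equals
the configured enrichment exactly. Fixed seed gives byte-identical outputs.

What it does **not** emulate: transcript isoforms, indels, quality-score
variation, GC or positional coverage bias, local background structure
(Input is uniform within a gene), and biological replicate dispersion
(matching the pooled single-library design). Passing tests therefore
demonstrate the correctness and calibration of the statistics under the
stated model, not robustness to those real-data artefacts.

## Problem sizes used in checks

The automated checks run at desk scale, chosen so the full suite completes
in minutes: peak recovery uses the default conditions over 10 seeds; the
null type-I check uses 120 genes (≥ 10,000 covered windows); Fisher
exactness compares against big-integer enumeration on thousands of random
tables with margins ≤ 200; UMI checks use 5,000 molecules (error-free
recovery) and 2,000 molecules × ~7 copies (1% errors). The 5,000-molecule
scale for *exact* recovery is deliberate: at hundreds of thousands of
molecules an 8-bp UMI space (65,536) makes a same-UMI-same-locus collision
likely by birthday arithmetic, which is a property of UMI length, not of
the algorithm.

## Numerical choices

- Pseudocount 0.5 in all rate ratios (enrichment, methylation ratio, RPKM
  fold change) to avoid division by zero.
- One-sided window test (only IP-excess windows are peaks); two-sided
  differential test (both directions are reported).
- Window p-values come from the exact hypergeometric tail (scipy), verified
  against independent exact enumeration to ≤ 1e-10 on small margins.
- Sorting and tie-breaks (sub-cluster seeds, k-mer ranking by (p, kmer),
  gene assignment by id) are fixed so every pipeline output is
  deterministic under a fixed seed.
- Degenerate inputs: empty read sets yield empty (warned) outputs; windows
  below `min_cov` are reported untested with p = 1; boundary fold changes
  and identity values fall on the non-significant / split side of their
  strict thresholds.

## Known limitations

Peak boundaries are window-quantized (no sub-window refinement); the
windowed caller is not a GLM/Poisson model and does not use local
background; differential calls are replicate-free; motif analysis is plain
k-mer counting (no PWM optimization); headline peak and gene counts from
full-depth sheep data are not reproducible at this scale and are not
targets of the checks.
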