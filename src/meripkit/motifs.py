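"""k-mer motif enrichment in peak sequences.

Peaks are scored for k-mers (default k = 5, the length of the canonical m6A
motif RRACH) by per-sequence presence/absence: each k-mer's target and
background hit counts form a 2x2 table tested with the one-sided Fisher
exact test, Benjamini-Hochberg adjusted across all tested k-mers.  The
default background is a seeded dinucleotide-preserving shuffle of the target
sequences; a user-supplied background set can be used instead.

RRACH matching uses the degenerate alphabet R = A/G, H = A/C/T (DNA
spelling; GGACT is the canonical instance GGACU).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .peaks import fisher_one_sided_many, LibraryTotals
from .simulate import reverse_complement

RRACH_POSITIONS = ({"A", "G"}, {"A", "G"}, {"A"}, {"C"}, {"A", "C", "T"})


def extract_peak_sequences(peaks: pd.DataFrame, genome: dict[str, str],
                           flank: int = 0) -> list[str]:
    """Strand-oriented peak sequences (minus-strand peaks reverse-complemented).

    Peaks extending past the sequence bounds are rejected (logged via a
    ValueError-free skip); ``flank`` widens each peak symmetrically.
    """
    import logging

    out, rejected = [], 0
    for r in peaks.itertuples(index=False):
        if r.seqname not in genome:
            rejected += 1
            continue
        seq = genome[r.seqname]
        lo, hi = r.start - flank, r.end + flank
        if lo < 0 or hi > len(seq) or lo >= hi:
            rejected += 1
            continue
        s = seq[lo:hi]
        out.append(reverse_complement(s) if getattr(r, "strand", "+") == "-" else s)
    if rejected:
        logging.getLogger(__name__).warning(
            "extract_peak_sequences: rejected %d out-of-bounds peaks", rejected)
    return out


def matches_rrach(kmer: str) -> bool:
    """True if a 5-mer fits the degenerate RRACH pattern."""
    return len(kmer) == 5 and all(b in allowed
                                  for b, allowed in zip(kmer, RRACH_POSITIONS))


def rrach_match_fraction(sequences: list[str]) -> float:
    """Fraction of oriented sequences containing >= 1 RRACH match."""
    if not sequences:
        return 0.0
    hits = 0
    for s in sequences:
        if any(matches_rrach(s[i:i + 5]) for i in range(len(s) - 4)):
            hits += 1
    return hits / len(sequences)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator,
                         max_tries: int = 200) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Randomizes the successor lists of the transition multigraph and walks an
    Eulerian path from the original start base, retrying until the walk
    consumes every edge (guaranteed to exist; random orderings occasionally
    strand early).  Falls back to a plain shuffle if no walk is found.
    """
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        succ: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            succ.setdefault(a, []).append(b)
        for lst in succ.values():
            rng.shuffle(lst)
        walk = [seq[0]]
        cur = seq[0]
        while succ.get(cur):
            cur = succ[cur].pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def kmer_enrichment(targets: list[str], background: list[str] | None = None,
                    k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Rank k-mers by one-sided enrichment of per-sequence presence.

    When ``background`` is None, each target is dinucleotide-shuffled with a
    generator seeded by ``seed``.  Only k-mers present in >= 1 target are
    tested.  Results are sorted by (p, kmer) with 1-based ranks; ``q_value``
    is Benjamini-Hochberg adjusted over the tested k-mers.
    """
    if not targets:
        raise ValueError("kmer_enrichment requires a non-empty target set")
    if min(len(s) for s in targets) < k:
        raise ValueError("k exceeds the shortest target sequence")
    if background is None:
        rng = np.random.default_rng(seed)
        background = [dinucleotide_shuffle(s, rng) for s in targets]
    if not background:
        raise ValueError("kmer_enrichment requires a non-empty background set")

    def presence(seqs):
        pres: dict[str, int] = {}
        for s in seqs:
            seen = {s[i:i + k] for i in range(len(s) - k + 1)}
            for m in seen:
                pres[m] = pres.get(m, 0) + 1
        return pres

    t_pres, b_pres = presence(targets), presence(background)
    kmers = sorted(t_pres)
    t_with = np.array([t_pres[m] for m in kmers])
    b_with = np.array([b_pres.get(m, 0) for m in kmers])
    n_t, n_b = len(targets), len(background)
    # table [[t_with, t_without], [b_with, b_without]] scored one-sided
    p = fisher_one_sided_many(t_with, b_with,
                              LibraryTotals(ip_total=n_t, input_total=n_b))
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "kmer": kmers, "target_hits": t_with,
        "target_fraction": t_with / n_t,
        "background_fraction": b_with / n_b,
        "p_value": p, "q_value": q,
    }).sort_values(["p_value", "kmer"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
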