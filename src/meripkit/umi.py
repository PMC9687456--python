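"""UMI consensus deduplication.

Reads are partitioned by their UMI; each UMI cluster is greedily split into
sub-clusters of reads sharing > 95% global-alignment identity with the
sub-cluster seed, and each sub-cluster is collapsed to a single consensus
read by column-wise majority over a star alignment to the seed.  This removes
PCR amplification and sequencing errors while keeping genuinely distinct
molecules that happen to share a UMI apart (their inserts differ).

Alignment scoring is match +1, mismatch -1, gap -2 (end-to-end); identity is
matched columns over total alignment columns.  The 95% threshold is strict:
a pair at exactly 0.95 is split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .io import Read

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.95


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_ALIGNER = _make_aligner()


@dataclass
class UmiCluster:
    """All reads sharing one exact UMI string."""

    umi: str
    members: list[Read]


@dataclass
class SubCluster:
    """Reads of one cluster within the identity threshold of a seed read."""

    seed: Read
    members: list[Read]
    consensus: Read | None = None


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matched columns in an optimal global alignment of two sequences."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_by_umi(reads: list[Read], umi_length: int | None = None) -> list[UmiCluster]:
    """Partition reads by exact UMI string.

    Reads without a UMI (or with one of the wrong length, when ``umi_length``
    is given) are rejected and counted in the log.
    """
    clusters: dict[str, list[Read]] = {}
    rejected = 0
    for r in reads:
        if not r.umi or (umi_length is not None and len(r.umi) != umi_length):
            rejected += 1
            continue
        clusters.setdefault(r.umi, []).append(r)
    if rejected:
        logger.warning("cluster_by_umi: rejected %d reads without a valid UMI", rejected)
    return [UmiCluster(umi=u, members=m) for u, m in clusters.items()]


def subcluster(cluster: UmiCluster,
               identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> list[SubCluster]:
    """Greedy split of a UMI cluster at strict identity > threshold to a seed.

    The seed of each round is the most abundant member sequence (ties:
    lexicographically smallest), which makes the partition deterministic.
    """
    if not cluster.members:
        raise ValueError("subcluster requires a non-empty cluster")
    remaining = list(cluster.members)
    out: list[SubCluster] = []
    while remaining:
        tally: dict[str, int] = {}
        for r in remaining:
            tally[r.sequence] = tally.get(r.sequence, 0) + 1
        seed_seq = min(tally, key=lambda s: (-tally[s], s))
        seed = next(r for r in remaining if r.sequence == seed_seq)
        taken, rest = [], []
        for r in remaining:
            if r.sequence == seed_seq or pairwise_identity(seed_seq, r.sequence) > identity_threshold:
                taken.append(r)
            else:
                rest.append(r)
        out.append(SubCluster(seed=seed, members=taken))
        remaining = rest
    return out


def consensus(sub: SubCluster) -> Read:
    """Column-wise majority consensus over a star alignment to the seed.

    Each member is pairwise-aligned to the seed and its bases projected onto
    seed columns (insertions relative to the seed are dropped).  Ties are
    broken by highest summed base quality, then alphabetically; a majority
    gap deletes the column.  Consensus quality is the max member quality per
    kept column.
    """
    if not sub.members:
        raise ValueError("consensus requires a non-empty sub-cluster")
    seed_seq = sub.seed.sequence
    if all(r.sequence == seed_seq for r in sub.members):
        r = sub.seed
        return Read(name=r.name, sequence=r.sequence, quality=r.quality, umi=r.umi)
    n_cols = len(seed_seq)
    votes: list[dict[str, int]] = [dict() for _ in range(n_cols)]
    sumq: list[dict[str, int]] = [dict() for _ in range(n_cols)]
    maxq = [0] * n_cols
    for r in sub.members:
        q = r.quality or "I" * len(r.sequence)
        if r.sequence == seed_seq:
            covered = {c: c for c in range(n_cols)}
        else:
            aln = _ALIGNER.align(seed_seq, r.sequence)[0]
            covered = {}
            for (ss, se), (ms, _me) in zip(*aln.aligned):
                for k in range(se - ss):
                    covered[ss + k] = ms + k
        for c in range(n_cols):
            if c in covered:
                b = r.sequence[covered[c]]
                phred = ord(q[covered[c]]) - 33
            else:
                b, phred = "-", 0
            votes[c][b] = votes[c].get(b, 0) + 1
            sumq[c][b] = sumq[c].get(b, 0) + phred
            maxq[c] = max(maxq[c], phred)
    seq, qual = [], []
    for c in range(n_cols):
        best = min(votes[c], key=lambda b: (-votes[c][b], -sumq[c][b], b))
        if best == "-":
            continue
        seq.append(best)
        qual.append(chr(33 + maxq[c]))
    return Read(name=sub.seed.name, sequence="".join(seq), quality="".join(qual),
                umi=sub.seed.umi)


def deduplicate(reads: list[Read], identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                umi_length: int | None = None) -> list[Read]:
    """Full consensus deduplication: cluster by UMI, sub-cluster, collapse.

    Output order is deterministic (sorted by UMI, then seed sequence); the
    output length equals the total number of sub-clusters, i.e. the inferred
    number of unique molecules.
    """
    out: list[Read] = []
    for cluster in sorted(cluster_by_umi(reads, umi_length=umi_length),
                          key=lambda c: c.umi):
        for sub in subcluster(cluster, identity_threshold):
            out.append(consensus(sub))
    return out
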