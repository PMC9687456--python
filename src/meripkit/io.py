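"""File formats and light-weight read records.

FASTA/FASTQ go through Bio.SeqIO; BED and TSV tables through pandas.  The
aligned-read table used throughout the package is a plain DataFrame with
columns ``seqname, start, end, strand`` plus optional ``library, condition,
gene, umi`` (0-based half-open coordinates, BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["seqname", "start", "end", "name", "score", "strand"]


@dataclass
class Read:
    """A sequencing read; quality is a phred+33 string (may be empty)."""

    name: str
    sequence: str
    quality: str = ""
    umi: str | None = None

    def __post_init__(self):
        if self.quality and len(self.quality) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch for {self.name}")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(name=rec.id, sequence=str(rec.seq), quality=qual))
    return reads


def write_fastq(reads, path: str | Path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
            qual = r.quality or "I" * len(r.sequence)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec
    SeqIO.write(records(), str(path), "fastq")


def strip_umi_prefix(read: Read, umi_length: int) -> Read:
    """Split off the UMI carried as the first ``umi_length`` bases."""
    if len(read.sequence) <= umi_length:
        raise ValueError(f"read {read.name} shorter than UMI length {umi_length}")
    return Read(name=read.name, sequence=read.sequence[umi_length:],
                quality=read.quality[umi_length:] if read.quality else "",
                umi=read.sequence[:umi_length])


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6(+) file into the aligned-read/peak table layout."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    df.columns = BED6_COLUMNS[:ncol] + [f"extra_{i}" for i in range(max(0, ncol - 6))]
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_columns: list[str] | None = None) -> None:
    """Write intervals as BED6 plus optional extra columns."""
    out = pd.DataFrame({
        "seqname": df["seqname"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["name"] if "name" in df else [f"iv_{i}" for i in range(len(df))],
        "score": df["score"] if "score" in df else 0,
        "strand": df["strand"] if "strand" in df else ".",
    })
    for c in extra_columns or []:
        out[c] = df[c].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
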