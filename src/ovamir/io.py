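"""Plain-text format helpers shared across stages.

FASTA/FASTQ parsing is delegated to Biopython; BED and the various TSV
tables are simple enough to read and write directly with pandas.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet out; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}, preserving file order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class FastqRead:
    name: str
    seq: str
    qual: str  # Phred+33 string, same length as seq


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream Phred+33 FASTQ records; raises on truncated records."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"truncated FASTQ record at index {idx} in {path}")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield FastqRead(header[1:].rstrip("\n"), seq.upper(), qual)
            idx += 1


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED (0-based half-open) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    return df.astype({"start": int, "end": int})


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str | Path) -> pd.DataFrame:
    """Two-column gene<TAB>term map."""
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_digest(path: str | Path) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
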