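"""Plain-text I/O: FASTA with sidecar quality files, TSV tables.

Every stage of the pipeline reads and writes ordinary files (FASTA / TSV)
so any stage can be swapped for an external tool's output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass
class Read:
    """A sequenced fragment with a technology label and optional qualities."""

    id: str
    seq: str
    technology: str = "unknown"  # "sanger" | "flx454" | "unknown"
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)


def write_fasta(records: Iterable[tuple[str, str]] | dict, path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    if isinstance(records, dict):
        records = records.items()
    recs = [SeqRecord(Seq(seq), id=name,
                      description=(descriptions or {}).get(name, ""))
            for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_reads(reads: Sequence[Read], fasta_path: str | Path,
                qual_path: str | Path | None = None) -> None:
    """FASTA plus an optional sidecar .qual file of per-base integers."""
    write_fasta([(r.id, r.seq) for r in reads], fasta_path,
                descriptions={r.id: f"technology={r.technology}"
                              for r in reads})
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                qual = r.qual if r.qual is not None else [40] * len(r.seq)
                fh.write(f">{r.id}\n")
                fh.write(" ".join(str(q) for q in qual) + "\n")


def read_reads(fasta_path: str | Path,
               qual_path: str | Path | None = None) -> list[Read]:
    quals: dict[str, list[int]] = {}
    if qual_path is not None and Path(qual_path).exists():
        for rec in SeqIO.parse(str(qual_path), "qual"):
            quals[rec.id] = list(rec.letter_annotations["phred_quality"])
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tech = "unknown"
        for token in rec.description.split():
            if token.startswith("technology="):
                tech = token.split("=", 1)[1]
        reads.append(Read(rec.id, str(rec.seq), tech, quals.get(rec.id)))
    return reads


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
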