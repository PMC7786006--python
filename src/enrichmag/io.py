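"""File I/O: FASTA/FASTQ via Biopython, tables via pandas.

All tabular outputs are tab-separated; coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Read reads from FASTQ or FASTA (by extension) as (id, seq) pairs."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, qual: int = 30) -> None:
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [qual] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_bin_table(path: str | Path) -> dict[str, list[str]]:
    """Read a bin membership TSV (columns: bin_id, scaffold_id)."""
    df = read_tsv(path)
    return {b: sorted(g["scaffold_id"]) for b, g in df.groupby("bin_id")}


def write_bin_table(bins: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(b, s) for b in sorted(bins) for s in sorted(bins[b])]
    write_tsv(pd.DataFrame(rows, columns=["bin_id", "scaffold_id"]), path)
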