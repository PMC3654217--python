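"""Readers and writers for the package's external file formats.

Sequences travel as FASTA (Biopython), alignment hits as the standard
12-column tabular format (qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore), and everything else as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a headerless 12-column tabular alignment hit file."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
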