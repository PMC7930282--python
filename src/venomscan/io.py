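"""Thin readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Bio.SeqIO; tabular files through pandas. All writers are
deterministic: fixed column order, ``\\t`` separators, ``%.6g`` floats, no
index column, so re-running a stage on identical inputs is byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLOAT_FORMAT = "%.6g"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def fasta_bytes(records: Iterable[tuple[str, str]]) -> bytes:
    """Serialize records to FASTA in memory (used for determinism checks)."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    buf = _io.StringIO()
    SeqIO.write(recs, buf, "fasta")
    return buf.getvalue().encode()


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_table(
    df: pd.DataFrame, path: str | Path, sep: str = "\t", columns: Sequence[str] | None = None
) -> None:
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_peptide_list(path: str | Path) -> list[str]:
    """One observed peptide per row; a ``peptide`` header column is accepted."""
    df = pd.read_csv(path, sep="\t")
    if "peptide" in df.columns:
        col = df["peptide"]
    else:  # headerless single column
        df = pd.read_csv(path, sep="\t", header=None)
        col = df[0]
    return [str(p).strip().upper() for p in col if str(p).strip()]
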