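"""FASTA reading/writing with the conventions the toolkit relies on.

Record IDs are truncated at the first whitespace and must be unique;
sequences round-trip losslessly and are wrapped at 60 columns on write.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "DuplicateIdError"]

WRAP = 60


class DuplicateIdError(ValueError):
    pass


def read_fasta(path: str | Path, alignment: bool = False) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping.

    With ``alignment=True`` all rows must be equal length.  An empty file
    yields an empty mapping with a warning; duplicate IDs (after whitespace
    truncation) raise listing the offenders.
    """
    records: dict[str, str] = {}
    dups: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            dups.append(rec.id)
        records[rec.id] = str(rec.seq)
    if dups:
        raise DuplicateIdError(f"duplicate record IDs in {path}: {sorted(set(dups))}")
    if not records:
        warnings.warn(f"no FASTA records in {path}")
    if alignment:
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of {path} are not aligned: lengths {sorted(lengths)}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
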