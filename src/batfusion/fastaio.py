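"""FASTA ingestion and emission for peptide records.

Reading goes through Bio.SeqIO; sequences are validated against the
20-letter standard amino-acid alphabet on ingest.  Writing emits a fixed
canonical layout (``>id description``, sequence wrapped at 60 columns, LF
endings) so that read → write round-trips are byte-identical for files the
package itself produced.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO

from .propensity import STANDARD_AMINO_ACIDS

__all__ = ["FastaRecord", "FastaError", "read_fasta", "write_fasta"]

_WRAP = 60


class FastaError(ValueError):
    """Raised for malformed FASTA input or non-standard residues."""


class FastaRecord(NamedTuple):
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a FASTA file into validated peptide records, preserving order.

    An empty file yields an empty list.  A file whose first non-blank line
    is not a header, or a record containing a non-standard residue, raises
    :class:`FastaError` naming the offending line or position.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
    else:
        return []

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).strip().upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in STANDARD_AMINO_ACIDS:
                raise FastaError(
                    f"{path}: record {rec.id!r}: non-standard residue {ch!r} "
                    f"at position {pos}"
                )
        # SeqIO's description includes the id; keep only the trailing part
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(FastaRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    """Write records in the package's canonical FASTA layout."""
    lines = []
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        lines.append(header)
        for start in range(0, len(rec.sequence), _WRAP):
            lines.append(rec.sequence[start : start + _WRAP])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
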