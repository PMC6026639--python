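"""FASTA reading/writing for peptide sequences and panels.

Thin wrappers over Biopython's SeqIO that enforce this package's alphabet
contract: uppercase standard residues (lowercase input is uppercased),
no gap or stop characters, unique ids, and at least one record.
Writing is canonical (60-column wrapping) so that write-read round-trips
are byte-stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import PeptideSequence, SequenceError


class FastaError(ValueError):
    """Structurally invalid FASTA input for this package."""


def read_fasta(path: str | Path, allow_nonstandard: bool = False) -> list[PeptideSequence]:
    """Read an ordered list of peptide sequences from FASTA.

    ``allow_nonstandard`` tolerates ``X`` records (used by panels); gap
    (``-``) and stop (``*``) characters are always rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[PeptideSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        for bad in "*-.":
            if bad in residues:
                raise FastaError(
                    f"{path}: sequence {rec.id!r} contains illegal character {bad!r}"
                )
        try:
            if allow_nonstandard and "X" in residues:
                from .simulate import _nonstandard_member

                out.append(_nonstandard_member(rec.id, residues))
            else:
                out.append(
                    PeptideSequence(rec.id, residues, rec.description.partition(" ")[2])
                )
        except SequenceError as exc:
            raise FastaError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[PeptideSequence], path: str | Path) -> None:
    """Write sequences in canonical 60-column FASTA, preserving order."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
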