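"""FASTA input/output and the in-memory protein record.

Sequences are held as plain uppercase amino-acid strings.  The accession is
the first whitespace-delimited token of the header; a UniProt-style
``db|ACC|name`` token is reduced to the bare accession, because downstream
outputs (hit reports, cluster summaries, annotation tables) key everything
by bare accessions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

# 20 standard residues plus the IUPAC ambiguity/rare codes B, Z, X and the
# translated selenocysteine/pyrrolysine U, O.  "*" is accepted only as a
# trailing stop and stripped on input.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO")


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


def _clean_accession(token: str) -> str:
    # "sp|O75179|ANR17_HUMAN" -> "O75179"; anything else passes through.
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with identifier, description and residues."""

    accession: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaError("empty accession")
        residues = self.residues.upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if not residues:
            raise FastaError(f"{self.accession}: empty sequence")
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise FastaError(
                f"{self.accession}: illegal residue(s) {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into an ordered list of records.

    Order follows the file.  Duplicate accessions and illegal residues are
    rejected; illegal residues are reported with the line number on which
    the offending sequence block starts.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise FastaError(f"empty FASTA file: {path}")

    # Track the line number of each header so residue errors are locatable.
    header_lines: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            token = line[1:].split(None, 1)[0] if line[1:].strip() else ""
            header_lines.setdefault(_clean_accession(token), lineno)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except ValueError as exc:
        raise FastaError(f"{path}: {exc}") from None
    for rec in parsed:
        accession = _clean_accession(rec.id)
        description = rec.description[len(rec.id):].strip()
        try:
            record = SequenceRecord(accession, str(rec.seq), description)
        except FastaError as exc:
            lineno = header_lines.get(accession, 0)
            raise FastaError(f"{path}:{lineno}: {exc}") from None
        if accession in seen:
            raise FastaError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(record)
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> Path:
    """Write records as plain FASTA, wrapping sequence lines at `width`."""
    records = list(records)
    if not records:
        raise FastaError("refusing to write an empty FASTA file")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.accession
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")
    return path
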