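"""Obtain the hit list: run blastp or parse a precomputed tabular file.

The pipeline consumes one hit per database subject.  BLAST may report
several HSPs for a subject; only the best-scoring HSP is kept, because the
report displays a single identity-to-query per protein.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

from .seqio import SequenceRecord, read_fasta, write_fasta


class BlastNotFoundError(RuntimeError):
    """blastp / makeblastdb not on PATH; precomputed hit files still work."""


class BlastError(RuntimeError):
    """A search or hit-file parse failed."""


@dataclass(frozen=True)
class SearchParams:
    """blastp invocation parameters.

    Defaults: e-value 1e-5, BLOSUM62, low-complexity filter off; at most
    20000 subjects reported.
    """

    evalue_threshold: float = 1e-5
    matrix: str = "BLOSUM62"
    low_complexity_filter: bool = False
    max_hits: int = 20000

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass(frozen=True)
class BlastHit:
    """One query-vs-subject result (best HSP), 1-based inclusive coordinates."""

    query_id: str
    subject_id: str
    pident_query: float
    align_length: int
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int
    rank: int = 0


_N_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def _parse_row(line: str, lineno: int, path: str) -> BlastHit:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != _N_COLUMNS:
        raise BlastError(
            f"{path}:{lineno}: expected {_N_COLUMNS} tab-separated columns, "
            f"got {len(fields)}"
        )
    try:
        return BlastHit(
            query_id=fields[0],
            subject_id=fields[1],
            pident_query=float(fields[2]),
            align_length=int(fields[3]),
            evalue=float(fields[10]),
            bitscore=float(fields[11]),
            qstart=int(fields[6]),
            qend=int(fields[7]),
            sstart=int(fields[8]),
            send=int(fields[9]),
        )
    except ValueError as exc:
        raise BlastError(f"{path}:{lineno}: non-numeric field ({exc})") from None


def parse_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into ranked hits.

    HSPs are collapsed to one hit per subject, keeping the highest
    bitscore (ties: lowest e-value, then smallest sstart).  Hits are then
    ordered by bitscore descending (stable in first-appearance order) and
    ranked 1..n.  An empty file (after comments) means "no hits".
    """
    path = Path(path)
    raw: list[BlastHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            raw.append(_parse_row(line, lineno, str(path)))

    best: dict[str, BlastHit] = {}
    order: dict[str, int] = {}
    for i, hit in enumerate(raw):
        key = hit.subject_id
        if key not in best:
            best[key], order[key] = hit, i
            continue
        cur = best[key]
        if (-hit.bitscore, hit.evalue, hit.sstart) < (-cur.bitscore, cur.evalue, cur.sstart):
            best[key] = hit

    ranked = sorted(best.values(),
                    key=lambda h: (-h.bitscore, order[h.subject_id]))
    return [replace(h, rank=i) for i, h in enumerate(ranked, start=1)]


def run_search(query: SequenceRecord, db_path: str | Path,
               params: SearchParams | None = None) -> list[BlastHit]:
    """blastp the query against a FASTA database, formatted on the fly.

    Raises :class:`BlastNotFoundError` when the BLAST+ executables are not
    discoverable, so callers can fall back to precomputed hit files.
    """
    params = params or SearchParams()
    for exe in ("blastp", "makeblastdb"):
        if shutil.which(exe) is None:
            raise BlastNotFoundError(
                f"{exe} not found on PATH; supply a precomputed tabular hit file"
            )
    db_path = Path(db_path)
    with tempfile.TemporaryDirectory(prefix="hitcluster_blast_") as tmp:
        tmpdir = Path(tmp)
        # rewrite the db with normalized (bare) accessions so blastp's
        # sseqid column matches the accessions used everywhere else
        db = tmpdir / "db.fasta"
        write_fasta(read_fasta(db_path), db)
        _run([
            "makeblastdb", "-in", str(db), "-dbtype", "prot",
        ])
        query_fa = tmpdir / "query.fasta"
        write_fasta([query], query_fa)
        out = tmpdir / "hits.tsv"
        _run([
            "blastp",
            "-query", str(query_fa),
            "-db", str(db),
            "-out", str(out),
            "-outfmt", "6",
            "-evalue", str(params.evalue_threshold),
            "-matrix", params.matrix,
            "-seg", "yes" if params.low_complexity_filter else "no",
            "-max_target_seqs", str(params.max_hits),
        ])
        return parse_blast_tabular(out)


def _run(cmd: list[str]) -> None:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise BlastError(
            f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )


def resolve_hit_sequences(
    hits: Sequence[BlastHit],
    db: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
) -> dict[str, SequenceRecord]:
    """Map each hit's subject accession to its sequence record.

    Total by contract: every subject must resolve, otherwise all missing
    accessions are reported at once.
    """
    if not isinstance(db, Mapping):
        db = {rec.accession: rec for rec in db}
    missing = [h.subject_id for h in hits if h.subject_id not in db]
    if missing:
        raise BlastError(
            "hit subject(s) absent from the database: " + ", ".join(missing)
        )
    return {h.subject_id: db[h.subject_id] for h in hits}
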