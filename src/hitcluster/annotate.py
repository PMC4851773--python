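"""Per-protein annotations and per-cluster summaries.

Annotations (protein name, organism, taxonomic lineage, domain
architecture, PDB entries) live in a flat TSV so the whole pipeline runs
offline; an opt-in helper can build that table from UniProt.  A cluster
summary reports the joint taxonomy (the deepest lineage prefix shared by
all annotated members), the distinct domain architectures with member
counts, the union of PDB entries and the member length range.
"""

from __future__ import annotations

import csv
import logging
import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cluster import Cluster
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["accession", "protein_name", "organism", "lineage",
                 "domains", "pdb", "length"]


class AnnotationError(ValueError):
    """Malformed annotation table."""


@dataclass(frozen=True)
class ProteinAnnotation:
    accession: str
    protein_name: str = ""
    organism: str = ""
    lineage: tuple[str, ...] = ()       # root -> leaf taxon names
    domains: tuple[str, ...] = ()       # ordered: the architecture
    pdb_ids: frozenset[str] = frozenset()
    annotated_length: int | None = None


@dataclass
class ClusterAnnotation:
    joint_taxonomy: list[str]
    architectures: list[tuple[tuple[str, ...], int]]  # (domains, member count)
    pdb_ids: set[str]
    length_min: int
    length_max: int
    n_members_annotated: int


def read_annotation_table(path: str | Path) -> dict[str, ProteinAnnotation]:
    """Read the per-protein annotation TSV.

    Columns: accession, protein_name, organism, lineage (";"-separated
    root->leaf), domains (";"-separated, order = architecture), pdb
    (","-separated), length.  Any cell but accession may be empty.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != TABLE_COLUMNS:
            raise AnnotationError(
                f"{path}: expected header {TABLE_COLUMNS}, got {reader.fieldnames}"
            )
        table: dict[str, ProteinAnnotation] = {}
        for lineno, row in enumerate(reader, start=2):
            acc = (row["accession"] or "").strip()
            if not acc:
                raise AnnotationError(f"{path}:{lineno}: empty accession")
            if acc in table:
                raise AnnotationError(f"{path}:{lineno}: duplicate accession {acc!r}")
            length_cell = (row["length"] or "").strip()
            try:
                length = int(length_cell) if length_cell else None
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer length {length_cell!r}"
                ) from None
            table[acc] = ProteinAnnotation(
                accession=acc,
                protein_name=(row["protein_name"] or "").strip(),
                organism=(row["organism"] or "").strip(),
                lineage=_split(row["lineage"], ";"),
                domains=_split(row["domains"], ";"),
                pdb_ids=frozenset(_split(row["pdb"], ",")),
                annotated_length=length,
            )
    return table


def write_annotation_table(annotations: Iterable[ProteinAnnotation],
                           path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for ann in annotations:
            writer.writerow([
                ann.accession, ann.protein_name, ann.organism,
                ";".join(ann.lineage), ";".join(ann.domains),
                ",".join(sorted(ann.pdb_ids)),
                "" if ann.annotated_length is None else ann.annotated_length,
            ])
    return path


def _split(cell: str | None, sep: str) -> tuple[str, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    return tuple(part.strip() for part in cell.split(sep) if part.strip())


def joint_taxonomy(lineages: Iterable[Sequence[str]]) -> list[str]:
    """Longest common prefix of the non-empty lineages (root -> leaf)."""
    nonempty = [list(l) for l in lineages if l]
    if not nonempty:
        return []
    prefix = nonempty[0]
    for lineage in nonempty[1:]:
        n = 0
        for a, b in zip(prefix, lineage):
            if a != b:
                break
            n += 1
        prefix = prefix[:n]
        if not prefix:
            break
    return prefix


def annotate_cluster(cluster: Cluster,
                     table: Mapping[str, ProteinAnnotation],
                     sequences: Mapping[str, SequenceRecord]) -> ClusterAnnotation:
    """Summarize one cluster from the annotation table and the sequences.

    Lengths always come from the actual sequences; members missing from
    the table contribute lengths only.  Architectures are distinct ordered
    domain lists counted over annotated members, ordered by count
    descending, ties by first appearance in member order.
    """
    lengths = [sequences[m.accession].length for m in cluster.members]
    annotated = [table[m.accession] for m in cluster.members
                 if m.accession in table]

    arch_counts: Counter[tuple[str, ...]] = Counter()
    first_seen: dict[tuple[str, ...], int] = {}
    for i, ann in enumerate(annotated):
        if ann.domains:
            arch_counts[ann.domains] += 1
            first_seen.setdefault(ann.domains, i)
    architectures = sorted(arch_counts.items(),
                           key=lambda kv: (-kv[1], first_seen[kv[0]]))

    for ann in annotated:
        if ann.annotated_length is not None and \
                ann.annotated_length != sequences[ann.accession].length:
            logger.warning(
                "%s: annotated length %d differs from sequence length %d",
                ann.accession, ann.annotated_length,
                sequences[ann.accession].length)

    return ClusterAnnotation(
        joint_taxonomy=joint_taxonomy(ann.lineage for ann in annotated),
        architectures=architectures,
        pdb_ids=set().union(*(ann.pdb_ids for ann in annotated)) if annotated else set(),
        length_min=min(lengths),
        length_max=max(lengths),
        n_members_annotated=len(annotated),
    )


def annotate_clusters(clusters: Sequence[Cluster],
                      table: Mapping[str, ProteinAnnotation],
                      sequences: Mapping[str, SequenceRecord],
                      ) -> dict[int, ClusterAnnotation]:
    return {c.cluster_index: annotate_cluster(c, table, sequences)
            for c in clusters}


def fetch_uniprot_annotations(accessions: Iterable[str],
                              timeout: float = 30.0) -> list[ProteinAnnotation]:
    """Build annotation rows from the UniProt REST API (opt-in, network).

    Unknown accessions are skipped with a warning.  Never called by the
    core pipeline.
    """
    import json
    import urllib.error
    import urllib.request

    out: list[ProteinAnnotation] = []
    seen: set[str] = set()
    for acc in accessions:
        if acc in seen:
            continue
        seen.add(acc)
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.json"
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                entry = json.load(resp)
        except (urllib.error.URLError, OSError) as exc:
            logger.warning("skipping %s: %s", acc, exc)
            continue
        lineage = tuple(t.get("scientificName", "")
                        for t in entry.get("organism", {}).get("lineage", [])
                        ) or tuple(entry.get("organism", {}).get("lineage", []))
        domains = tuple(
            f.get("description", "")
            for f in entry.get("features", [])
            if f.get("type") in {"Domain", "Zinc finger", "Repeat"}
        )
        pdb = frozenset(
            x["id"] for x in entry.get("uniProtKBCrossReferences", [])
            if x.get("database") == "PDB"
        )
        seq = entry.get("sequence", {})
        out.append(ProteinAnnotation(
            accession=acc,
            protein_name=entry.get("proteinDescription", {})
                .get("recommendedName", {}).get("fullName", {}).get("value", ""),
            organism=entry.get("organism", {}).get("scientificName", ""),
            lineage=tuple(x for x in lineage if x),
            domains=domains,
            pdb_ids=pdb,
            annotated_length=seq.get("length"),
        ))
    return out
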