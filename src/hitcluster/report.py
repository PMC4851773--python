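"""The two output views: the color-coded hit report and the cluster summaries.

The hit report is one TSV row per BLAST hit, in rank order, carrying the
cluster index and a cluster color so related hits are visually grouped;
rescued members keep their "2:" label.  The cluster report is a versioned
JSON array (plus a TSV digest) with everything needed to reconstruct the
partition: representative, members with both identities, joint taxonomy,
architectures, PDB entries and the length range.  Both files are
byte-stable given identical inputs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .annotate import ClusterAnnotation
from .blast import BlastHit
from .cluster import Cluster
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

# Fixed palette: distinct colors for the first twenty clusters, then grey.
PALETTE: tuple[str, ...] = (
    "red", "blue", "green", "orange", "purple",
    "cyan", "magenta", "yellow", "teal", "pink",
    "brown", "olive", "navy", "maroon", "lime",
    "coral", "gold", "indigo", "turquoise", "salmon",
)
FALLBACK_COLOR = "grey"

HIT_REPORT_COLUMNS = ["rank", "accession", "label", "pident_query", "evalue",
                      "bitscore", "length", "cluster", "color"]


@dataclass(frozen=True)
class ReportRow:
    rank: int
    accession: str
    display_label: str
    pident_query: float
    evalue: float
    bitscore: float
    seq_length: int
    cluster_index: int
    color_name: str


def assign_colors(clusters: Sequence[Cluster]) -> dict[int, str]:
    """Distinct palette colors for cluster indices 1..20, grey beyond."""
    return {
        c.cluster_index: PALETTE[c.cluster_index - 1]
        if c.cluster_index <= len(PALETTE) else FALLBACK_COLOR
        for c in clusters
    }


def build_report_rows(hits: Sequence[BlastHit],
                      clusters: Sequence[Cluster],
                      sequences: Mapping[str, SequenceRecord]) -> list[ReportRow]:
    colors = assign_colors(clusters)
    member_of: dict[str, tuple[int, str]] = {}
    for clu in clusters:
        for m in clu.members:
            member_of[m.accession] = (clu.cluster_index, m.display_label)
    rows = []
    for hit in sorted(hits, key=lambda h: h.rank):
        idx, label = member_of[hit.subject_id]
        rows.append(ReportRow(
            rank=hit.rank,
            accession=hit.subject_id,
            display_label=label,
            pident_query=hit.pident_query,
            evalue=hit.evalue,
            bitscore=hit.bitscore,
            seq_length=sequences[hit.subject_id].length,
            cluster_index=idx,
            color_name=colors[idx],
        ))
    return rows


def _pct(x: float | None) -> str | None:
    return None if x is None else f"{x:.2f}"


def write_hit_report(rows: Sequence[ReportRow], path: str | Path) -> Path:
    """Write the rank-ordered, cluster-colored hit table as TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HIT_REPORT_COLUMNS)
        for row in rows:
            writer.writerow([
                row.rank, row.accession, row.display_label,
                _pct(row.pident_query), f"{row.evalue:.2g}",
                f"{row.bitscore:g}", row.seq_length,
                row.cluster_index, row.color_name,
            ])
    if not rows:
        logger.info("no hits: wrote header-only report to %s", path)
    return path


def cluster_report_doc(clusters: Sequence[Cluster],
                       annotations: Mapping[int, ClusterAnnotation] | None,
                       ) -> dict:
    """The cluster report as a plain JSON-ready document."""
    colors = assign_colors(clusters)
    items = []
    for clu in clusters:
        ann = (annotations or {}).get(clu.cluster_index)
        items.append({
            "index": clu.cluster_index,
            "color": colors[clu.cluster_index],
            "representative": clu.representative,
            "members": [
                {
                    "accession": m.accession,
                    "label": m.display_label,
                    "pass": m.pass_no,
                    "identity_to_rep": _pct(m.identity_to_rep),
                    "identity_to_query": _pct(m.identity_to_query),
                }
                for m in clu.members
            ],
            "joint_taxonomy": list(ann.joint_taxonomy) if ann else [],
            "architectures": [
                {"domains": list(domains), "count": count}
                for domains, count in (ann.architectures if ann else [])
            ],
            "pdb_ids": sorted(ann.pdb_ids) if ann else [],
            "length_min": ann.length_min if ann else None,
            "length_max": ann.length_max if ann else None,
            "n_members_annotated": ann.n_members_annotated if ann else 0,
        })
    return {"schema_version": REPORT_SCHEMA_VERSION, "clusters": items}


def write_cluster_report(clusters: Sequence[Cluster],
                         annotations: Mapping[int, ClusterAnnotation] | None,
                         json_path: str | Path,
                         tsv_path: str | Path | None = None) -> Path:
    """Write clusters.json (sorted keys, stable floats) and a TSV digest."""
    json_path = Path(json_path)
    doc = cluster_report_doc(clusters, annotations)
    json_path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
    if tsv_path is not None:
        _write_cluster_tsv(doc, Path(tsv_path))
    return json_path


def _write_cluster_tsv(doc: dict, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster", "color", "representative", "n_members",
                         "members", "joint_taxonomy", "architectures",
                         "pdb_ids", "length_range"])
        for c in doc["clusters"]:
            writer.writerow([
                c["index"], c["color"], c["representative"],
                len(c["members"]),
                ",".join(m["label"] for m in c["members"]),
                ";".join(c["joint_taxonomy"]),
                " | ".join("{} (x{})".format(";".join(a["domains"]), a["count"])
                           for a in c["architectures"]),
                ",".join(c["pdb_ids"]),
                "" if c["length_min"] is None
                else f"{c['length_min']}-{c['length_max']}",
            ])


def partition_from_report(doc: dict) -> dict[str, int]:
    """Reconstruct the accession -> cluster-index partition from the JSON doc."""
    return {m["accession"]: c["index"]
            for c in doc["clusters"] for m in c["members"]}
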