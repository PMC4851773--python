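"""Two-pass greedy clustering of hit sequences, and session re-clustering.

Pass 1 sorts the sequences by length, repeatedly takes the longest
remaining one as a cluster representative and absorbs every remaining
sequence that (1) is less than ``length_diff_limit`` residues shorter
(default 32, strict) and (2) reaches the effective identity threshold —
the larger of the user cutoff (default 53 %) and the length-dependent
twilight-zone curve — against the representative.

Pass 2 rescues singletons (typically fragments and splice variants): each
single-member cluster is compared against the representatives of all
multi-member clusters and moved into the best-matching one if it reaches
the identity threshold, with no length condition.  Rescued members carry
pass number 2 and a "2:" display prefix.

Because the search itself dominates the runtime, the frozen search result
(:class:`SessionState`) can be re-clustered at a new cutoff without
touching the database again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

from .align import (PairIdentity, ThresholdPolicy, effective_threshold,
                    global_identity, meets_threshold)
from .blast import BlastHit, SearchParams
from .seqio import SequenceRecord

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClusteringParams:
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    length_diff_limit: int = 32  # strict: a difference of exactly 32 fails

    def __post_init__(self) -> None:
        if self.length_diff_limit < 0:
            raise ValueError("length_diff_limit must be >= 0")


@dataclass
class ClusterMember:
    accession: str
    pass_no: int  # 1 = length-constrained pass, 2 = singleton rescue
    identity_to_rep: float
    identity_to_query: float | None = None
    is_representative: bool = False

    @property
    def display_label(self) -> str:
        return f"2:{self.accession}" if self.pass_no == 2 else self.accession


@dataclass
class Cluster:
    cluster_index: int
    representative: str
    members: list[ClusterMember]

    @property
    def accessions(self) -> list[str]:
        return [m.accession for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def _pass1_order(sequences: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # longest first; ties broken by ascending accession for determinism
    return sorted(sequences, key=lambda s: (-s.length, s.accession))


def cluster_pass1(sequences: Sequence[SequenceRecord],
                  params: ClusteringParams | None = None) -> list[Cluster]:
    """Greedy length-constrained clustering pass."""
    params = params or ClusteringParams()
    if not sequences:
        raise ValueError("cluster_pass1 requires at least one sequence")
    accessions = [s.accession for s in sequences]
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate accessions in clustering input")

    remaining = _pass1_order(sequences)
    clusters: list[Cluster] = []
    while remaining:
        rep = remaining.pop(0)
        members = [ClusterMember(rep.accession, 1, 100.0, is_representative=True)]
        kept: list[SequenceRecord] = []
        for seq in remaining:
            if rep.length - seq.length >= params.length_diff_limit:
                kept.append(seq)
                continue
            pair = global_identity(rep, seq)
            if meets_threshold(pair, params.policy):
                members.append(ClusterMember(seq.accession, 1, pair.identity_pct))
            else:
                kept.append(seq)
        remaining = kept
        clusters.append(Cluster(len(clusters) + 1, rep.accession, members))
    return clusters


def cluster_pass2(clusters: Sequence[Cluster],
                  sequences: Mapping[str, SequenceRecord],
                  params: ClusteringParams | None = None) -> list[Cluster]:
    """Rescue singletons into existing multi-member clusters.

    A singleton joins the multi-member cluster whose representative it
    matches best (ties: lower cluster index), provided the identity
    reaches the threshold; length differences are ignored.  Multi-member
    clusters never dissolve or merge, and a rescued singleton cannot
    itself receive members (single sweep).  When every pass-1 cluster is
    a singleton there is nothing "existing" to join and the pass is a
    no-op.
    """
    params = params or ClusteringParams()
    multi = [c for c in clusters if len(c) >= 2]
    out: list[Cluster] = [Cluster(c.cluster_index, c.representative, list(c.members))
                          for c in clusters]
    if not multi:
        return out
    multi_idx = {c.cluster_index for c in multi}

    rescued: list[int] = []
    for pos, clu in enumerate(out):
        if len(clu) != 1 or clu.cluster_index in multi_idx:
            continue
        seq = sequences[clu.representative]
        best: tuple[float, int] | None = None  # (identity, cluster_index)
        best_pos: int | None = None
        for pos2, target in enumerate(out):
            if target.cluster_index not in multi_idx:
                continue
            rep = sequences[target.representative]
            pair = global_identity(rep, seq)
            if not meets_threshold(pair, params.policy):
                continue
            key = (-pair.identity_pct, target.cluster_index)
            if best is None or key < best:
                best, best_pos = key, pos2
        if best_pos is not None:
            out[best_pos].members.append(
                ClusterMember(clu.representative, 2, -best[0]))
            rescued.append(pos)

    for pos in reversed(rescued):
        del out[pos]
    for i, clu in enumerate(out, start=1):
        clu.cluster_index = i
    return out


def finalize_clusters(clusters: Sequence[Cluster],
                      hits: Sequence[BlastHit]) -> list[Cluster]:
    """Renumber clusters by their best hit rank and order members by rank.

    Also copies each member's identity-to-query from its hit, so the
    report can show both identities.  Members without a hit (possible
    only when clustering arbitrary sequence sets) sort last.
    """
    by_subject = {h.subject_id: h for h in hits}
    big = 10 ** 9

    def member_rank(m: ClusterMember) -> int:
        hit = by_subject.get(m.accession)
        return hit.rank if hit else big

    finalized: list[Cluster] = []
    for clu in clusters:
        members = sorted((replace_member(m, by_subject.get(m.accession))
                          for m in clu.members),
                         key=lambda m: (member_rank(m), m.accession))
        finalized.append(Cluster(0, clu.representative, members))
    finalized.sort(key=lambda c: (min((member_rank(m) for m in c.members),
                                      default=big),
                                  c.representative))
    for i, clu in enumerate(finalized, start=1):
        clu.cluster_index = i
    return finalized


def replace_member(m: ClusterMember, hit: BlastHit | None) -> ClusterMember:
    return ClusterMember(m.accession, m.pass_no, m.identity_to_rep,
                         hit.pident_query if hit else None,
                         m.is_representative)


def cluster_hits(sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
                 hits: Sequence[BlastHit],
                 params: ClusteringParams | None = None) -> list[Cluster]:
    """Full clustering: pass 1, pass 2, then finalize against the hit ranks."""
    params = params or ClusteringParams()
    if not isinstance(sequences, Mapping):
        sequences = {s.accession: s for s in sequences}
    if not sequences:
        return []
    pass1 = cluster_pass1(list(sequences.values()), params)
    pass2 = cluster_pass2(pass1, sequences, params)
    return finalize_clusters(pass2, hits)


# ---------------------------------------------------------------------------
# Session state: the frozen search result that re-clustering consumes.

@dataclass
class SessionState:
    query: SequenceRecord
    hits: list[BlastHit]
    hit_sequences: dict[str, SequenceRecord]
    search_params: SearchParams
    clustering_params: ClusteringParams

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "query": _record_doc(self.query),
            "hits": [asdict(h) for h in self.hits],
            "sequences": [_record_doc(r) for r in self.hit_sequences.values()],
            "search_params": asdict(self.search_params),
            "clustering_params": {
                "identity_cutoff_pct": self.clustering_params.policy.user_cutoff_pct,
                "rost_offset_n": self.clustering_params.policy.rost_offset_n,
                "length_diff_limit": self.clustering_params.length_diff_limit,
            },
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SessionState":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"unreadable session state: {exc}") from None
        if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"incompatible session state (expected schema_version "
                f"{SCHEMA_VERSION}, got {doc.get('schema_version') if isinstance(doc, dict) else type(doc).__name__})"
            )
        cp = doc["clustering_params"]
        return cls(
            query=_record_from_doc(doc["query"]),
            hits=[BlastHit(**h) for h in doc["hits"]],
            hit_sequences={r["accession"]: _record_from_doc(r)
                           for r in doc["sequences"]},
            search_params=SearchParams(**doc["search_params"]),
            clustering_params=ClusteringParams(
                ThresholdPolicy(cp["identity_cutoff_pct"], cp["rost_offset_n"]),
                cp["length_diff_limit"],
            ),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SessionState":
        return cls.from_json(Path(path).read_text())


def _record_doc(rec: SequenceRecord) -> dict:
    return {"accession": rec.accession, "description": rec.description,
            "residues": rec.residues}


def _record_from_doc(doc: dict) -> SequenceRecord:
    return SequenceRecord(doc["accession"], doc["residues"],
                          doc.get("description", ""))


def recluster(state: SessionState,
              new_params: ClusteringParams | None = None) -> list[Cluster]:
    """Re-cluster a stored session at new parameters; no search is run."""
    params = new_params or state.clustering_params
    if not state.hits:
        return []
    return cluster_hits(state.hit_sequences, state.hits, params)
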