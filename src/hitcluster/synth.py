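"""Synthetic protein families with planted cluster structure.

Every pipeline stage is testable offline: families are generated as a
random seed sequence plus derivatives carrying point substitutions at a
controlled rate and small terminal truncations/extensions.  Independent
families sit near the random background identity (well under any sensible
cutoff), so the planted partition is what a correct clusterer must
recover.  Matching annotation tables (one lineage and one domain
architecture per family) and a synthetic hit table are emitted alongside.

Substitutions are uniform over the other 19 residues and there is no
internal indel model — enough to exercise the length rule and the
singleton-rescue pass while keeping the expected identity analytic
(within-family expected identity ~ the configured target).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .align import global_identity
from .blast import BlastHit
from .annotate import ProteinAnnotation
from .seqio import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    n_members: int = 5
    seed_length: int = 120
    within_identity_target: float = 85.0  # expected % identity to the seed
    length_jitter: int = 3                # max residues trimmed/added per end
    rng_seed: int = 0
    name: str = "fam"

    def __post_init__(self) -> None:
        if not 0 < self.within_identity_target <= 100:
            raise ValueError("within_identity_target must be in (0, 100]")
        if self.n_members < 1 or self.seed_length < 1 or self.length_jitter < 0:
            raise ValueError("invalid family spec")


def random_protein(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AMINO_ACIDS if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _jitter_ends(seq: str, jitter: int, rng: random.Random) -> str:
    if jitter == 0:
        return seq
    for end in (0, 1):
        n = rng.randint(-jitter, jitter)
        if n > 0:  # extend
            extra = random_protein(n, rng)
            seq = extra + seq if end == 0 else seq + extra
        elif n < 0 and len(seq) + n >= 10:  # truncate, keep a core
            seq = seq[-n:] if end == 0 else seq[:n]
    return seq


def derive_homolog(parent: SequenceRecord, identity_target: float,
                   rng: random.Random, accession: str,
                   length_jitter: int = 0) -> SequenceRecord:
    """A homolog of ``parent`` at roughly the given percent identity,
    produced by point substitutions and optional terminal jitter."""
    if not 0 < identity_target <= 100:
        raise ValueError("identity_target must be in (0, 100]")
    seq = _mutate(parent.residues, 1.0 - identity_target / 100.0, rng)
    seq = _jitter_ends(seq, length_jitter, rng)
    return SequenceRecord(accession, seq, f"synthetic homolog of {parent.accession}")


def make_fragment(parent: SequenceRecord, rng: random.Random, accession: str,
                  fraction: float = 0.5,
                  identity_target: float = 95.0) -> SequenceRecord:
    """An N-terminal fragment of ``parent`` (default half-length) with
    light mutation — the kind of truncated entry the length rule excludes
    in pass 1 and the singleton rescue must recover in pass 2."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = max(10, int(parent.length * fraction))
    frag = _mutate(parent.residues[:n], 1.0 - identity_target / 100.0, rng)
    return SequenceRecord(accession, frag,
                          f"synthetic fragment of {parent.accession}")


def make_family(spec: FamilySpec) -> list[SequenceRecord]:
    """One seed sequence plus n_members - 1 mutated derivatives."""
    rng = random.Random(spec.rng_seed)
    seed = random_protein(spec.seed_length, rng)
    rate = 1.0 - spec.within_identity_target / 100.0
    records = [SequenceRecord(f"{spec.name}_r", seed,
                              f"synthetic family {spec.name} seed")]
    for i in range(1, spec.n_members):
        seq = _jitter_ends(_mutate(seed, rate, rng), spec.length_jitter, rng)
        records.append(SequenceRecord(
            f"{spec.name}_m{i}", seq, f"synthetic family {spec.name} member"))
    return records


@dataclass
class HitSet:
    """A synthetic query + database with its planted truth partition."""

    query: SequenceRecord
    records: list[SequenceRecord]          # database, family by family
    truth: dict[str, int]                  # accession -> family index
    annotations: list[ProteinAnnotation]
    hits: list[BlastHit]                   # synthetic tabular-style hits


def make_hitset(family_specs: Sequence[FamilySpec],
                between_family_identity_max: float = 35.0,
                query_from: int = 0,
                max_retries: int = 20) -> HitSet:
    """Generate independent families and assemble a query/database pair.

    Independent random families sit near the random background identity;
    this is asserted (seed representatives pairwise below
    ``between_family_identity_max``), regenerating with shifted seeds a
    bounded number of times if a random collision occurs.
    """
    specs = list(family_specs)
    if not 0 <= query_from < len(specs):
        raise ValueError("query_from out of range")

    for attempt in range(max_retries):
        shifted = [
            FamilySpec(s.n_members, s.seed_length, s.within_identity_target,
                       s.length_jitter, s.rng_seed + attempt * 10007,
                       s.name or f"fam{i}")
            for i, s in enumerate(specs)
        ]
        families = [make_family(s) for s in shifted]
        if _families_distinct(families, between_family_identity_max):
            break
    else:
        raise RuntimeError(
            f"could not generate families below {between_family_identity_max} % "
            f"between-family identity in {max_retries} attempts"
        )

    records = [rec for fam in families for rec in fam]
    truth = {rec.accession: i for i, fam in enumerate(families) for rec in fam}
    query = families[query_from][0]
    annotations = [
        ProteinAnnotation(
            accession=rec.accession,
            protein_name=f"{shifted[i].name} protein",
            organism=f"Synthetica genus{i}",
            lineage=("Synthetica", "Familiales", f"Family{i}"),
            domains=(f"Dom{i}A", f"Dom{i}B"),
            pdb_ids=frozenset(),
            annotated_length=rec.length,
        )
        for i, fam in enumerate(families) for rec in fam
    ]
    return HitSet(query, records, truth, annotations,
                  mock_hit_table(query, records))


def make_tiered_hitset(rng_seed: int = 0, n_members: int = 5,
                       seed_length: int = 120) -> HitSet:
    """Three families at two levels of relatedness.

    Family B descends from family A's seed at ~50 % identity; family C is
    independent (random background).  A cutoff sweep therefore changes
    the partition: low cutoffs (at the twilight-zone floor) merge A and B,
    the default separates all three, and stringent cutoffs shatter the
    families into singletons.
    """
    rng = random.Random(rng_seed)
    fam_a = make_family(FamilySpec(n_members, seed_length, 85.0, 2,
                                   rng_seed=rng_seed * 3 + 1, name="famA"))
    seed_b = derive_homolog(fam_a[0], 50.0, rng, "famB_r")
    fam_b = [seed_b] + [
        derive_homolog(seed_b, 85.0, rng, f"famB_m{i}", length_jitter=2)
        for i in range(1, n_members)
    ]
    fam_c = make_family(FamilySpec(n_members, seed_length, 85.0, 2,
                                   rng_seed=rng_seed * 3 + 2, name="famC"))
    # family C must sit at background identity to both related families
    for attempt in range(20):
        if all(global_identity(fam_c[0], other).identity_pct < 35.0
               for other in (fam_a[0], seed_b)):
            break
        fam_c = make_family(FamilySpec(n_members, seed_length, 85.0, 2,
                                       rng_seed=rng_seed * 3 + 2 + 10007 * (attempt + 1),
                                       name="famC"))
    records = fam_a + fam_b + fam_c
    truth = {r.accession: i for i, fam in enumerate((fam_a, fam_b, fam_c))
             for r in fam}
    annotations = [
        ProteinAnnotation(r.accession, organism=f"Synthetica genus{truth[r.accession]}",
                          lineage=("Synthetica", "Familiales",
                                   f"Family{truth[r.accession]}"),
                          domains=(f"Dom{truth[r.accession]}",),
                          annotated_length=r.length)
        for r in records
    ]
    query = fam_a[0]
    return HitSet(query, records, truth, annotations,
                  mock_hit_table(query, records))


def _families_distinct(families: list[list[SequenceRecord]],
                       max_identity: float) -> bool:
    reps = [fam[0] for fam in families]
    for i in range(len(reps)):
        for j in range(i):
            if global_identity(reps[i], reps[j]).identity_pct > max_identity:
                return False
    return True


def mock_hit_table(query: SequenceRecord,
                   records: Sequence[SequenceRecord]) -> list[BlastHit]:
    """A deterministic synthetic hit list standing in for a real search.

    Identity-to-query comes from the same global alignment the clusterer
    uses; the bitscore is a monotone surrogate (identity x aligned
    columns) and the e-value a placeholder, so rank order reflects
    similarity the way a real report's would.  For offline fixtures only.
    """
    rows = []
    for rec in records:
        pair = global_identity(query, rec)
        rows.append(BlastHit(
            query_id=query.accession,
            subject_id=rec.accession,
            pident_query=round(pair.identity_pct, 2),
            align_length=pair.aligned_cols,
            evalue=1e-30,
            bitscore=round(pair.identity_pct * pair.aligned_cols / 100.0, 1),
            qstart=1, qend=query.length, sstart=1, send=rec.length,
        ))
    rows.sort(key=lambda h: (-h.bitscore, h.subject_id))
    return [BlastHit(h.query_id, h.subject_id, h.pident_query, h.align_length,
                     h.evalue, h.bitscore, h.qstart, h.qend, h.sstart, h.send,
                     rank=i)
            for i, h in enumerate(rows, start=1)]


def write_hitset(hitset: HitSet, outdir: str | Path) -> Path:
    """Materialize a hit set: query.fasta, db.fasta, hits.tsv (synthetic),
    annotations.tsv and truth.json."""
    from .annotate import write_annotation_table
    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([hitset.query], outdir / "query.fasta")
    write_fasta(hitset.records, outdir / "db.fasta")
    write_annotation_table(hitset.annotations, outdir / "annotations.tsv")
    with (outdir / "hits.tsv").open("w") as fh:
        fh.write("# synthetic hit table\n")
        for h in hitset.hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.pident_query, h.align_length,
                0, 0, h.qstart, h.qend, h.sstart, h.send,
                h.evalue, h.bitscore,
            ])) + "\n")
    (outdir / "truth.json").write_text(
        json.dumps(hitset.truth, sort_keys=True, indent=1) + "\n")
    return outdir
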