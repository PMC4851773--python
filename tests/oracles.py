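"""Independent oracles for the test suite.

* A plain-Python Gotoh (affine-gap) global aligner with free terminal
  gaps, used to cross-check the production identity metric.
* A naive, literal transcription of the two-pass greedy clustering rules,
  used to cross-check the production clusterer on random inputs.

Both are deliberately simple and slow; they never share code with the
implementation paths they check (the clustering oracle evaluates the
twilight-zone curve formula inline).
"""

from __future__ import annotations

import math
from typing import Sequence

from Bio.Align import substitution_matrices

from hitcluster.align import global_identity
from hitcluster.seqio import SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11.0    # cost of a gap of length 1
GAP_EXTEND = 1.0   # additional cost per extra gapped column

NEG = float("-inf")


def nw_identity(a: str, b: str) -> tuple[float, float, int]:
    """Gotoh global alignment (affine gaps, free end gaps), BLOSUM62.

    Returns (score, identity_pct, aligned_cols) where aligned_cols counts
    all alignment columns except terminal gap runs.  Tie-breaking among
    co-optimal alignments is this oracle's own (prefer diagonal on
    traceback), so identity may in principle differ from another optimal
    alignment's; the score may not.
    """
    n, m = len(a), len(b)
    # M: a[i-1] aligned to b[j-1]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gap in b is free
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # leading gap in a is free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if j == m:  # trailing gap in b is free
                X[i][j] = max(M[i - 1][j], Y[i - 1][j], X[i - 1][j])
            else:
                X[i][j] = max(M[i - 1][j] - GAP_OPEN, Y[i - 1][j] - GAP_OPEN,
                              X[i - 1][j] - GAP_EXTEND)
            if i == n:  # trailing gap in a is free
                Y[i][j] = max(M[i][j - 1], X[i][j - 1], Y[i][j - 1])
            else:
                Y[i][j] = max(M[i][j - 1] - GAP_OPEN, X[i][j - 1] - GAP_OPEN,
                              Y[i][j - 1] - GAP_EXTEND)
    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback for identities / columns (excluding terminal gap runs)
    i, j = n, m
    state = max(((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")),
                key=lambda t: t[0])[1]
    cols = []  # list of (a_char or None, b_char or None)
    while i > 0 or j > 0:
        if state == "M":
            cols.append((a[i - 1], b[j - 1]))
            prev = M[i][j] - _BLOSUM62[a[i - 1], b[j - 1]]
            for cand, name in ((M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"),
                               (Y[i - 1][j - 1], "Y")):
                if math.isclose(cand, prev, abs_tol=1e-6):
                    state = name
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append((a[i - 1], None))
            here = X[i][j]
            if j == m or j == 0:
                opts = ((M[i - 1][j], "M"), (Y[i - 1][j], "Y"),
                        (X[i - 1][j], "X"))
            else:
                opts = ((M[i - 1][j] - GAP_OPEN, "M"),
                        (Y[i - 1][j] - GAP_OPEN, "Y"),
                        (X[i - 1][j] - GAP_EXTEND, "X"))
            for cand, name in opts:
                if math.isclose(cand, here, abs_tol=1e-6):
                    state = name
                    break
            i -= 1
        else:  # Y
            cols.append((None, b[j - 1]))
            here = Y[i][j]
            if i == n or i == 0:
                opts = ((M[i][j - 1], "M"), (X[i][j - 1], "X"),
                        (Y[i][j - 1], "Y"))
            else:
                opts = ((M[i][j - 1] - GAP_OPEN, "M"),
                        (X[i][j - 1] - GAP_OPEN, "X"),
                        (Y[i][j - 1] - GAP_EXTEND, "Y"))
            for cand, name in opts:
                if math.isclose(cand, here, abs_tol=1e-6):
                    state = name
                    break
            j -= 1
    cols.reverse()

    # strip terminal gap runs
    lo, hi = 0, len(cols)
    while lo < hi and (cols[lo][0] is None or cols[lo][1] is None):
        lo += 1
    while hi > lo and (cols[hi - 1][0] is None or cols[hi - 1][1] is None):
        hi -= 1
    core = cols[lo:hi]
    if not core:
        return score, 0.0, 0
    identities = sum(1 for x, y in core if x is not None and x == y)
    return score, 100.0 * identities / len(core), len(core)


def rost_curve(L: int) -> float:
    """The twilight-zone minimum-identity curve, evaluated inline
    (formula up to L = 450, constant plateau beyond)."""
    L = min(L, 450)
    return min(100.0, max(0.0, 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))))


def rost_curve_unclamped(L: int) -> float:
    """The curve without the 100 % display clamp: above 100 for very
    short alignments, i.e. nothing at that length is significant."""
    L = min(L, 450)
    return max(0.0, 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0))))


def oracle_two_pass(sequences: Sequence[SequenceRecord], cutoff: float,
                    length_limit: int) -> list[dict]:
    """Literal transcription of the two-pass greedy clustering rules.

    Returns clusters as dicts {"rep": acc, "members": {acc: pass_no}} in
    creation order; identity values come from the shared pairwise metric,
    which has its own oracle (nw_identity).
    """
    pool = sorted(sequences, key=lambda s: (-s.length, s.accession))
    clusters: list[dict] = []
    while pool:
        rep, rest = pool[0], pool[1:]
        members = {rep.accession: 1}
        remaining = []
        for seq in rest:
            pair = global_identity(rep, seq)
            threshold = max(cutoff, rost_curve_unclamped(pair.aligned_cols))
            if rep.length - seq.length < length_limit and \
                    pair.identity_pct >= threshold:
                members[seq.accession] = 1
            else:
                remaining.append(seq)
        clusters.append({"rep": rep.accession, "members": members})
        pool = remaining

    by_acc = {s.accession: s for s in sequences}
    multi = [c for c in clusters if len(c["members"]) >= 2]
    if multi:
        for c in list(clusters):
            if len(c["members"]) != 1 or c in multi:
                continue
            seq = by_acc[c["rep"]]
            best = None
            for idx, target in enumerate(clusters):
                if target not in multi:
                    continue
                pair = global_identity(by_acc[target["rep"]], seq)
                threshold = max(cutoff, rost_curve_unclamped(pair.aligned_cols))
                if pair.identity_pct >= threshold:
                    key = (-pair.identity_pct, idx)
                    if best is None or key < best[0]:
                        best = (key, target)
            if best is not None:
                best[1]["members"][c["rep"]] = 2
                clusters.remove(c)
    return clusters


def random_mixture(seed: int, max_seqs: int = 30) -> list[SequenceRecord]:
    """A small random clustering input: a couple of planted families plus
    random singletons and a fragment — the regime the clusterer must
    handle, at oracle-checkable size."""
    import random

    from hitcluster.synth import AMINO_ACIDS, FamilySpec, make_family

    rng = random.Random(seed)
    seqs: list[SequenceRecord] = []
    for f in range(rng.randint(1, 3)):
        seqs.extend(make_family(FamilySpec(
            n_members=rng.randint(1, 6),
            seed_length=rng.randint(50, 120),
            within_identity_target=rng.uniform(60.0, 95.0),
            length_jitter=rng.randint(0, 4),
            rng_seed=seed * 97 + f, name=f"s{seed}f{f}")))
    for i in range(rng.randint(0, 5)):
        seqs.append(SequenceRecord(
            f"s{seed}r{i}",
            "".join(rng.choice(AMINO_ACIDS)
                    for _ in range(rng.randint(30, 120)))))
    if seqs and rng.random() < 0.7:
        parent = rng.choice(seqs)
        seqs.append(SequenceRecord(
            f"s{seed}frag", parent.residues[: max(10, parent.length // 2)]))
    return seqs[:max_seqs]


def partition_key(clusters: list[dict]) -> frozenset:
    """Order-free canonical form: set of (rep, member->pass mappings)."""
    return frozenset(
        (c["rep"], frozenset(c["members"].items())) for c in clusters
    )
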