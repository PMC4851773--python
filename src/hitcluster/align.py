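"""Pairwise percent identity and the length-dependent identity threshold.

Cluster membership is decided by comparing the global-alignment percent
identity of a candidate against a threshold that is the larger of a fixed
user cutoff (53 % by default) and the twilight-zone curve of Rost, which
demands higher identity for shorter alignments.  The curve acts as a hard
floor: lowering the user cutoff can never admit pairs the curve rejects.

The identity metric: Needleman-Wunsch global alignment with BLOSUM62 and
affine gaps (open 11, extend 1, matching the search defaults), with
terminal (overhang) gaps free and their columns excluded from the
identity denominator.  Free overhangs keep the metric meaningful for the
fragments and splice variants the second clustering pass must rescue —
penalizing them makes any coincidental tail match capture the overhang
as an internal gap and crush the fragment's identity.  The degenerate
flip side (two unrelated sequences "aligning" over a two-residue perfect
core at 100 % identity) is rejected by the curve itself: below ~12
columns the curve demands more than 100 % identity, so membership
decisions evaluate it without the display clamp and such cores can never
pass (see :func:`meets_threshold`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

# Revised (1999) twilight-zone curve constants: the minimum percent
# identity regarded as significant for an alignment of L columns is
#   n + ROST_SCALE * L ** (ROST_BASE_EXP * (1 + exp(-L / ROST_DECAY)))
# with n = 0 for the twilight-zone curve itself.  The formula is defined
# for L <= ROST_PLATEAU_L; beyond that the curve is the constant value it
# reaches there (~19.5 %).  The raw formula is not monotone past 450 —
# it rises again — so the plateau is part of the curve's definition, not
# a numerical convenience.
ROST_SCALE = 480.0
ROST_BASE_EXP = -0.32
ROST_DECAY = 1000.0
ROST_PLATEAU_L = 450

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@dataclass(frozen=True)
class PairIdentity:
    """Percent identity of one aligned pair and the column count behind it."""

    identity_pct: float
    aligned_cols: int


@dataclass(frozen=True)
class ThresholdPolicy:
    """User cutoff combined with the length-dependent curve.

    ``rost_offset_n`` shifts the curve vertically (0 = twilight zone; the
    HSSP family of curves uses positive offsets).
    """

    user_cutoff_pct: float = 53.0
    rost_offset_n: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.user_cutoff_pct <= 100.0:
            raise ValueError(
                f"identity cutoff must be in [0, 100], got {self.user_cutoff_pct}"
            )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    # terminal overhangs are free
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=65536)
def _identity_cached(a: str, b: str) -> PairIdentity:
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    if cols == 0:
        # degenerate optimum with no aligned span; score it as 0 % over the
        # shorter sequence so the threshold machinery still has an L
        return PairIdentity(0.0, min(len(a), len(b)))
    return PairIdentity(100.0 * counts.identities / cols, cols)


def global_identity(a: SequenceRecord, b: SequenceRecord) -> PairIdentity:
    """Percent identity of a global alignment of ``a`` and ``b``.

    Columns inside terminal gap runs are excluded, so an exact fragment
    scores 100 %.  Symmetric by construction: the pair is canonically
    ordered before aligning, which also makes tie-breaking among
    co-optimal alignments independent of argument order.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    x, y = sorted((a.residues, b.residues))
    return _identity_cached(x, y)


def rost_threshold(L: int, policy: ThresholdPolicy | None = None) -> float:
    """Minimum significant percent identity for an alignment of L columns.

    Monotone non-increasing in L: clamped at 100 for very short
    alignments (only exact matches pass below L ~ 12), strictly
    decreasing up to L = 450, then constant at the long-alignment
    plateau (~19.5 % for the twilight-zone curve).
    """
    if L < 1:
        raise ValueError(f"alignment length must be >= 1, got {L}")
    policy = policy or ThresholdPolicy()
    L_eff = min(L, ROST_PLATEAU_L)
    value = policy.rost_offset_n + ROST_SCALE * L_eff ** (
        ROST_BASE_EXP * (1.0 + math.exp(-L_eff / ROST_DECAY))
    )
    return min(100.0, max(0.0, value))


def effective_threshold(L: int, policy: ThresholdPolicy | None = None) -> float:
    """The identity threshold actually applied: max(user cutoff, curve).

    The curve is a floor the user cutoff cannot undercut.
    """
    policy = policy or ThresholdPolicy()
    return max(policy.user_cutoff_pct, rost_threshold(L, policy))


def _rost_unclamped(L: int, policy: ThresholdPolicy) -> float:
    L_eff = min(L, ROST_PLATEAU_L)
    value = policy.rost_offset_n + ROST_SCALE * L_eff ** (
        ROST_BASE_EXP * (1.0 + math.exp(-L_eff / ROST_DECAY))
    )
    return max(0.0, value)


def meets_threshold(pair: PairIdentity,
                    policy: ThresholdPolicy | None = None) -> bool:
    """Does a pair's identity reach the effective threshold for its length?

    The comparison is >= with no epsilon, against the curve WITHOUT its
    100 % display clamp: for very short alignments (under ~12 columns)
    the curve exceeds 100 %, meaning no identity, however perfect, is
    significant at that length.  This is what rejects the degenerate
    perfect micro-cores free-overhang alignment produces between
    unrelated sequences.
    """
    policy = policy or ThresholdPolicy()
    threshold = max(policy.user_cutoff_pct, _rost_unclamped(pair.aligned_cols, policy))
    return pair.identity_pct >= threshold
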