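"""Sequence-identity redundancy filtering.

Training and testing sets are purged of near-duplicate sequences before
modelling: any record whose global-alignment identity to an already-kept
record reaches the threshold (default 90%) is discarded.  The clustering
is the standard greedy longest-first scheme (as in CD-HIT): records are
scanned in order of decreasing length (ties by id) and kept iff they are
below the threshold against every record kept so far.
"""

from __future__ import annotations

from typing import Sequence

from Bio import Align

from .records import HairpinError, RnaRecord

DEFAULT_THRESHOLD = 0.9

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-1.0,
    extend_gap_score=-1.0,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences.

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1; identity is
    matches / alignment length.  The arguments are canonically ordered
    before aligning so the result is exactly symmetric even when several
    co-optimal alignments exist.
    """
    if not a or not b:
        raise HairpinError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _identity_upper_bound(len_a: int, len_b: int) -> float:
    # identities <= min length, alignment length >= max length
    return min(len_a, len_b) / max(len_a, len_b)


def filter_redundant(records: Sequence[RnaRecord],
                     threshold: float = DEFAULT_THRESHOLD) -> list[RnaRecord]:
    """Greedy longest-first redundancy removal at the given identity threshold.

    Returns the retained records ordered by decreasing length (ties broken
    by id).  Idempotent: no two retained records reach the threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise HairpinError(f"identity threshold must be in (0, 1], "
                           f"got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    kept: list[RnaRecord] = []
    for rec in ordered:
        redundant = False
        for ref in kept:
            if _identity_upper_bound(len(rec), len(ref)) < threshold:
                continue
            if pairwise_identity(rec.sequence, ref.sequence) >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append(rec)
    return kept
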