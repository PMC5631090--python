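"""Pairwise sequence identity for amplicon comparisons.

Identity is defined as matching columns divided by alignment columns of the
optimal global alignment, with terminal gap columns excluded.  Amplicons are
extracted between fixed primer loci and are therefore positionally anchored,
so equal-length pairs are compared ungapped (identity = matches/L, the usual
arithmetic for substitution variants: a 250-nt sequence with one substitution
is 249/250 = 99.6% identical to its source).  Pairs of unequal length are
aligned globally with scoring that strongly prefers ungapped alignments for
near-identical sequences (match +1, mismatch -2, gap open -10, gap extend -1,
terminal gaps free), with glocal coverage: the shorter sequence's unaligned
terminal residues still count as alignment columns, so a quality-truncated
read scores 1.0 against its full-length template but a short spurious
overlap cannot masquerade as near-identity.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align

__all__ = ["pairwise_identity", "hamming_distance"]


@lru_cache(maxsize=200_000)
def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    return int(np.count_nonzero(_codes(a) != _codes(b)))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    # terminal gaps are free
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _aligned_identity(a: str, b: str) -> float:
    # canonical argument order: symmetry regardless of which co-optimal
    # alignment the aligner reports
    if a > b:
        a, b = b, a
    alignment = _ALIGNER.align(a, b)[0]
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            # internal gap columns between consecutive aligned blocks
            columns += (ts - prev_t_end) + (qs - prev_q_end)
        columns += te - ts
        matches += int(np.count_nonzero(_codes(a)[ts:te] == _codes(b)[qs:qe]))
        prev_t_end, prev_q_end = te, qe
    # glocal coverage: the shorter sequence must be accounted for end to end,
    # so its unaligned terminal residues count as columns; only the longer
    # sequence's overhangs are free.  Prevents short spurious overlaps from
    # scoring as near-identity.
    if len(a) <= len(b):
        columns += t_blocks[0][0] + (len(a) - prev_t_end)
    else:
        columns += q_blocks[0][0] + (len(b) - prev_q_end)
    if columns == 0:
        return 0.0
    return matches / columns


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity in [0, 1] between two nucleotide sequences.

    Symmetric; 1.0 iff the sequences are equal.  Raises ``ValueError`` on an
    empty input.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if len(a) == len(b):
        k = hamming_distance(a, b)
        return (len(a) - k) / len(a)
    return _aligned_identity(a, b)
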