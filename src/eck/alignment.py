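"""Global pairwise alignment and percent identity.

Percent identity between two chains is computed from an optimal global
(Needleman-Wunsch) alignment under an integer substitution matrix
(BLOSUM62 by default) with affine gap penalties:

    identity = 100 * identical aligned pairs / alignment columns
    coverage = aligned (non-gap/non-gap) columns / length of the shorter chain

Gap columns count against identity, so unrelated chains of very different
length score low even when their overlap matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["AlignmentParams", "DEFAULT_PARAMS", "global_identity", "get_aligner"]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment (gap penalties are additive, <= 0)."""

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode != "global":
            raise ValueError("only global alignment is supported")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=8)
def get_aligner(params: AlignmentParams = DEFAULT_PARAMS) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_identity(
    seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> Tuple[float, float]:
    """Return ``(percent_identity, coverage)`` under an optimal global alignment.

    Symmetric by construction: the pair is put into a canonical order before
    aligning, so co-optimal alignments cannot make identity(a, b) differ from
    identity(b, a).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    alignment = get_aligner(params).align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = alignment.length
    aligned_pairs = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / columns if columns else 0.0
    coverage = aligned_pairs / min(len(seq_a), len(seq_b))
    return identity, coverage
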