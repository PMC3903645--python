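"""Internal pairwise local alignment helpers built on Bio.Align.PairwiseAligner.

Wraps the C implementation of affine-gap Smith-Waterman and extracts the
counts the pipeline needs: matched bases, aligned columns, gap columns on
each sequence, and the aligned span on each sequence (for coverage rules).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner

__all__ = ["LocalAlignment", "local_align", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """Counts extracted from one best local alignment."""

    score: float
    matches: int
    mismatches: int
    gaps_in_query: int  # columns where the query has a gap
    gaps_in_subject: int  # columns where the subject has a gap
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches + self.gaps_in_query + self.gaps_in_subject

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.matches / cols if cols else 0.0


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = -abs(mismatch)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def local_align(
    query: str,
    subject: str,
    match: float = 2.0,
    mismatch: float = 3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> LocalAlignment | None:
    """Best local alignment of ``query`` vs ``subject`` on the given strands.

    Returns None when no positive-scoring alignment exists. ``mismatch``,
    ``gap_open`` and ``gap_extend`` are penalties (magnitudes).
    """
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    try:
        best = alignments[0]
    except (IndexError, StopIteration):
        return None
    if alignments.score <= 0:
        return None

    q_blocks, s_blocks = best.aligned
    matches = mismatches = 0
    gaps_q = gaps_s = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gaps_s += qs - prev_q_end  # query advances alone -> subject gap columns
            gaps_q += ss - prev_s_end  # subject advances alone -> query gap columns
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_q_end, prev_s_end = qe, se

    if not q_blocks.size:
        return None
    query_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    subject_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return LocalAlignment(
        score=float(alignments.score),
        matches=matches,
        mismatches=mismatches,
        gaps_in_query=gaps_q,
        gaps_in_subject=gaps_s,
        query_span=query_span,
        subject_span=subject_span,
    )
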