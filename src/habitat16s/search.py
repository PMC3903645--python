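"""Query-vs-reference search producing the ranked hit list behind the MHIs.

A query is aligned (affine-gap local alignment, both strands) against
reference entries that share at least one seed k-mer with it. Hits are
scored, assigned Karlin-Altschul-style e-values, filtered at the e-value
ceiling (1e-10 by default), capped at the 10,000 most significant, and
finally ranked by the ratio of matched bases to the hit sequence's full
length plus gap columns opened in the hit — a ranking that places short
partial hits below full-length ones, which is why queries are recommended
to be longer than the references (> 500 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from ._align import LocalAlignment, local_align, reverse_complement
from .seqio import ReferenceStore, SequenceRecord

__all__ = ["SearchParams", "AlignmentHit", "align_pair", "evalue", "search_reference", "hits_to_tsv"]


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds and scoring.

    Defaults mirror classic nucleotide-BLAST behavior: e-value ceiling
    1e-10, at most 10,000 significant hits, match +2 / mismatch -3 /
    gap open 5 / gap extend 2. ``karlin_lambda`` and ``karlin_k`` are the
    significance constants of the extreme-value score distribution; the
    defaults (0.625, 0.41) are documented approximations for this scoring,
    not a full edge-corrected recalibration.
    """

    evalue_max: float = 1e-10
    max_hits: int = 10_000
    match_score: float = 2.0
    mismatch_penalty: float = 3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41
    seed_kmer: int = 12

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-reference local alignment.

    ``identity`` (matches / aligned columns) is the quantity thresholded at
    97/95/90/85/80%; ``sort_key`` (matches / (full hit length + gap columns
    in the hit)) is the ranking ratio, a distinct quantity.
    """

    query_id: str
    ref_env: str
    ref_ordinal: int
    matches: int
    aligned_columns: int
    gaps_in_hit: int
    hit_length: int
    score: float
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def sort_key(self) -> float:
        return self.matches / (self.hit_length + self.gaps_in_hit)


def align_pair(
    query: SequenceRecord, subject: SequenceRecord, params: SearchParams | None = None
) -> LocalAlignment | None:
    """Best local alignment of query vs subject over both strands.

    Returns the higher-scoring strand's alignment, or None when no
    positive-scoring alignment exists.
    """
    params = params or SearchParams()
    kwargs = dict(
        match=params.match_score,
        mismatch=params.mismatch_penalty,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    fwd = local_align(query.residues, subject.residues, **kwargs)
    rev = local_align(reverse_complement(query.residues), subject.residues, **kwargs)
    if fwd is None:
        return rev
    if rev is None:
        return fwd
    return fwd if fwd.score >= rev.score else rev


def evalue(
    score: float, query_len: int, db_total_len: int, params: SearchParams | None = None
) -> float:
    """Karlin-Altschul expected hit count E = K * m * n * exp(-lambda * S)."""
    params = params or SearchParams()
    if query_len <= 0 or db_total_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.karlin_k * query_len * db_total_len * math.exp(-params.karlin_lambda * score)


def _canonical_seeds(residues: str, k: int) -> set[str]:
    rc = reverse_complement(residues)
    n = len(residues)
    return {
        min(residues[i : i + k], rc[n - k - i : n - i]) for i in range(n - k + 1)
    }


def search_reference(
    query: SequenceRecord,
    store: ReferenceStore,
    params: SearchParams | None = None,
    prefilter: bool = True,
) -> list[AlignmentHit]:
    """Align a query against the store and return the ranked significant hits.

    Candidates are reference entries sharing >= 1 canonical seed k-mer with
    the query (disable with ``prefilter=False`` for exhaustive search).
    Hits pass the e-value ceiling, the ``max_hits`` most significant are
    retained, and the final order is by sort_key descending with ties
    broken by e-value ascending then (env, ordinal).
    """
    params = params or SearchParams()
    if len(store) == 0:
        raise ValueError("empty reference store")
    db_total_len = sum(len(entry.residues) for entry in store)

    query_seeds = (
        _canonical_seeds(query.residues, params.seed_kmer)
        if prefilter and len(query.residues) >= params.seed_kmer
        else None
    )

    hits: list[AlignmentHit] = []
    for entry in store:
        if query_seeds is not None:
            if len(entry.residues) < params.seed_kmer:
                continue
            subject_seeds = _canonical_seeds(entry.residues, params.seed_kmer)
            if not (query_seeds & subject_seeds):
                continue
        subject = SequenceRecord(id=entry.label, residues=entry.residues)
        aln = align_pair(query, subject, params)
        if aln is None:
            continue
        e = evalue(aln.score, len(query.residues), db_total_len, params)
        if e > params.evalue_max:
            continue
        hits.append(
            AlignmentHit(
                query_id=query.id,
                ref_env=entry.env,
                ref_ordinal=entry.ordinal,
                matches=aln.matches,
                aligned_columns=aln.aligned_columns,
                gaps_in_hit=aln.gaps_in_subject,
                hit_length=len(entry.residues),
                score=aln.score,
                evalue=e,
            )
        )

    # cap at the most significant hits by e-value, then rank by the ratio
    hits.sort(key=lambda h: (h.evalue, h.ref_env, h.ref_ordinal))
    hits = hits[: params.max_hits]
    hits.sort(key=lambda h: (-h.sort_key, h.evalue, h.ref_env, h.ref_ordinal))
    return hits


def hits_to_tsv(hits: Sequence[AlignmentHit]) -> str:
    """Render hits as a ranked tab-separated table."""
    header = (
        "query_id\tenv\tordinal\tidentity_pct\tmatches\taligned_columns\t"
        "gaps_in_hit\tscore\tevalue\tsort_key"
    )
    rows = [header]
    for h in hits:
        rows.append(
            f"{h.query_id}\t{h.ref_env}\t{h.ref_ordinal}\t{100 * h.identity:.2f}\t"
            f"{h.matches}\t{h.aligned_columns}\t{h.gaps_in_hit}\t{h.score:g}\t"
            f"{h.evalue:.3g}\t{h.sort_key:.4f}"
        )
    return "\n".join(rows)
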