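"""Microbial Habitability Index (MHI) computation.

For an identity threshold c, each environmental category e receives

    MHI(e) = 100 * N_c(e) * log(R_total / R(e)) / sum_e' N_c(e') * log(R_total / R(e'))

where N_c(e) counts the significant hits labeled e with identity >= c,
R(e) is the number of reference sequences labeled e and R_total the store
size. The log factor is an inverse-document-frequency-style weight that
down-weights categories that contribute many sequences to the reference;
the normalization makes every emitted threshold column sum to 100%. The
log base is immaterial (it cancels in the normalization).

Thresholds default to 97/95/90/85/80% identity, corresponding roughly to
species, genus, family, order and class. Categories below 1% are grouped
into an "other" entry for presentation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .search import AlignmentHit, SearchParams, search_reference
from .seqio import ReferenceStore, SequenceRecord

__all__ = [
    "ThresholdSet",
    "ThresholdColumn",
    "MhiProfile",
    "count_hits_per_env",
    "compute_mhi",
    "group_other",
    "profile_query",
    "profile_collective",
    "format_statistics",
]

logger = logging.getLogger(__name__)

OTHER_LABEL = "other"
MIN_RECOMMENDED_QUERY_BP = 500


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered identity thresholds, strictly decreasing, each in (0, 1]."""

    levels: tuple[float, ...] = (0.97, 0.95, 0.90, 0.85, 0.80)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("at least one threshold required")
        if any(not 0 < c <= 1 for c in self.levels):
            raise ValueError("thresholds must lie in (0, 1]")
        if list(self.levels) != sorted(self.levels, reverse=True) or len(set(self.levels)) != len(
            self.levels
        ):
            raise ValueError("thresholds must be strictly decreasing")


@dataclass(frozen=True)
class ThresholdColumn:
    """One threshold's result: raw counts and normalized percentages.

    ``degenerate`` flags the corner case where every environment's weight
    log(R_total/R(e)) is zero (a single-category store); percentages are
    then empty rather than divided by zero.
    """

    threshold: float
    counts: dict[str, int]
    mhi_percent: dict[str, float]
    degenerate: bool = False

    @property
    def n_hits(self) -> int:
        return sum(self.counts.values())


@dataclass
class MhiProfile:
    """Per-threshold habitability percentages for one or more queries.

    Thresholds with zero hits are absent: the corresponding column simply
    does not appear.
    """

    query_ids: list[str]
    per_threshold: dict[float, ThresholdColumn] = field(default_factory=dict)

    def to_json(self, other_floor: float | None = 1.0) -> str:
        doc: dict = {"query_ids": self.query_ids, "columns": {}}
        for c, col in sorted(self.per_threshold.items(), reverse=True):
            grouped = (
                group_other(col.mhi_percent, other_floor)
                if other_floor is not None and col.mhi_percent
                else dict(col.mhi_percent)
            )
            other_members = (
                sorted(e for e, p in col.mhi_percent.items() if p < other_floor)
                if other_floor is not None
                else []
            )
            doc["columns"][f"{100 * c:g}%"] = {
                "hits": col.n_hits,
                "counts": col.counts,
                "mhi_percent": grouped,
                "other_members": other_members,
                "degenerate": col.degenerate,
            }
        return json.dumps(doc, indent=2)

    def to_csv(self) -> str:
        rows = ["threshold,environment,n_hits,mhi_percent"]
        for c, col in sorted(self.per_threshold.items(), reverse=True):
            for env in sorted(col.mhi_percent, key=lambda e: -col.mhi_percent[e]):
                rows.append(f"{100 * c:g},{env},{col.counts.get(env, 0)},{col.mhi_percent[env]:.6f}")
        return "\n".join(rows)


def count_hits_per_env(hits: Sequence[AlignmentHit], c: float) -> dict[str, int]:
    """N_c(e): hits labeled e with identity >= c (inclusive threshold)."""
    counts: dict[str, int] = {}
    for hit in hits:
        if hit.identity >= c:
            counts[hit.ref_env] = counts.get(hit.ref_env, 0) + 1
    return counts


def compute_mhi(
    counts: Mapping[str, int],
    store_counts: tuple[Mapping[str, int], int],
) -> tuple[dict[str, float], bool]:
    """IDF-weighted normalized percentages from per-environment hit counts.

    Returns ``(mhi_percent, degenerate)``; ``degenerate`` is True when all
    weights are zero (then percentages are empty and a warning is logged).
    Environments with zero hits are omitted.
    """
    r_per_env, r_total = store_counts
    if r_total < 1:
        raise ValueError("R_total must be >= 1")
    raw: dict[str, float] = {}
    for env, n in counts.items():
        if n == 0:
            continue
        if env not in r_per_env:
            raise ValueError(f"environment {env!r} absent from the reference counts")
        r_e = r_per_env[env]
        if r_e <= 0:
            raise ValueError(f"R({env!r}) must be positive")
        if r_e > r_total:
            raise ValueError(f"R({env!r}) exceeds R_total")
        raw[env] = n * math.log(r_total / r_e)
    denom = sum(raw.values())
    if raw and denom == 0:
        logger.warning("all IDF weights are zero (every hit environment spans the whole store)")
        return {}, True
    if not raw:
        return {}, False
    return {env: 100.0 * w / denom for env, w in raw.items()}, False


def group_other(mhi: Mapping[str, float], floor: float = 1.0) -> dict[str, float]:
    """Merge environments below ``floor`` percent into an "other" entry.

    Totals are preserved; "other" is omitted when nothing falls below the
    floor.
    """
    grouped: dict[str, float] = {}
    other = 0.0
    for env, pct in mhi.items():
        if pct < floor:
            other += pct
        else:
            grouped[env] = pct
    if other > 0:
        grouped[OTHER_LABEL] = other
    return grouped


def _columns_from_hits(
    hits: Sequence[AlignmentHit],
    store: ReferenceStore,
    thresholds: ThresholdSet,
) -> dict[float, ThresholdColumn]:
    store_counts = (store.counts_per_env, store.total)
    columns: dict[float, ThresholdColumn] = {}
    for c in thresholds.levels:
        counts = count_hits_per_env(hits, c)
        if not counts:
            continue  # no hits above this identity: the column does not appear
        mhi_percent, degenerate = compute_mhi(counts, store_counts)
        columns[c] = ThresholdColumn(
            threshold=c, counts=counts, mhi_percent=mhi_percent, degenerate=degenerate
        )
    return columns


def profile_query(
    query: SequenceRecord,
    store: ReferenceStore,
    thresholds: ThresholdSet | None = None,
    params: SearchParams | None = None,
) -> MhiProfile:
    """Search once, then build the per-threshold MHI columns for one query."""
    thresholds = thresholds or ThresholdSet()
    if len(query.residues) < MIN_RECOMMENDED_QUERY_BP:
        logger.warning(
            "query %r is %d bp; more than %d bp is recommended for reliable ranking",
            query.id,
            len(query.residues),
            MIN_RECOMMENDED_QUERY_BP,
        )
    hits = search_reference(query, store, params)
    return MhiProfile(
        query_ids=[query.id],
        per_threshold=_columns_from_hits(hits, store, thresholds),
    )


def profile_collective(
    queries: Sequence[SequenceRecord],
    store: ReferenceStore,
    thresholds: ThresholdSet | None = None,
    params: SearchParams | None = None,
    mode: str = "sum",
) -> MhiProfile:
    """Joint profile for several queries (e.g. the 16S copies of one genome).

    ``mode="sum"`` (primary): per-query hit lists are computed independently
    and per-environment counts are summed per threshold before a single MHI
    computation. ``mode="mean"``: per-query MHI columns are computed first
    and their percentages averaged (re-normalized over the queries that have
    the column).
    """
    if not queries:
        raise ValueError("at least one query required")
    if mode not in {"sum", "mean"}:
        raise ValueError("mode must be 'sum' or 'mean'")
    thresholds = thresholds or ThresholdSet()

    if mode == "sum":
        all_hits: list[AlignmentHit] = []
        for q in queries:
            all_hits.extend(search_reference(q, store, params))
        return MhiProfile(
            query_ids=[q.id for q in queries],
            per_threshold=_columns_from_hits(all_hits, store, thresholds),
        )

    profiles = [profile_query(q, store, thresholds, params) for q in queries]
    columns: dict[float, ThresholdColumn] = {}
    for c in thresholds.levels:
        present = [p.per_threshold[c] for p in profiles if c in p.per_threshold]
        if not present:
            continue
        counts: dict[str, int] = {}
        acc: dict[str, float] = {}
        for col in present:
            for env, n in col.counts.items():
                counts[env] = counts.get(env, 0) + n
            for env, pct in col.mhi_percent.items():
                acc[env] = acc.get(env, 0.0) + pct
        mean = {env: total / len(present) for env, total in acc.items()}
        columns[c] = ThresholdColumn(
            threshold=c,
            counts=counts,
            mhi_percent=mean,
            degenerate=all(col.degenerate for col in present),
        )
    return MhiProfile(query_ids=[q.id for q in queries], per_threshold=columns)


def format_statistics(profile: MhiProfile, other_floor: float = 1.0) -> str:
    """Text statistics block, one line per threshold column.

    Format: ``(97%, 36 hits) freshwater: 88.15%; marine: 11.85%`` with
    environments in descending MHI order, two decimals, sub-floor
    categories grouped as "other".
    """
    if not profile.per_threshold:
        return "no hits above any identity threshold"
    lines = []
    for c in sorted(profile.per_threshold, reverse=True):
        col = profile.per_threshold[c]
        if col.degenerate:
            lines.append(
                f"({100 * c:g}%, {col.n_hits} hit{'s' if col.n_hits != 1 else ''}) "
                "degenerate: all category weights are zero"
            )
            continue
        grouped = group_other(col.mhi_percent, other_floor)
        ordered = sorted(grouped.items(), key=lambda kv: (-kv[1], kv[0]))
        body = "; ".join(f"{env}: {pct:.2f}%" for env, pct in ordered)
        n = col.n_hits
        lines.append(f"({100 * c:g}%, {n} hit{'s' if n != 1 else ''}) {body}")
    return "\n".join(lines)
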