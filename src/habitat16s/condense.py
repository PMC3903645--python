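"""Condensing QC-passed reads into the compact labeled reference.

Per environmental category the pipeline runs: 99% near-duplicate removal
(prefix-anchored, emulating amplicon duplicate cleanup), a shared-k-mer
rRNA screen against a small screening FASTA, a two-parent chimera test, and
greedy 97% centroid clustering (the accepted species boundary). The cluster
representatives, labeled ``env.1, env.2, ...``, form the reference store
that the habitability search runs against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import local_align
from .seqio import ReferenceEntry, ReferenceStore, SequenceRecord

__all__ = [
    "ClusterParams",
    "Cluster",
    "ChimeraVerdict",
    "dedup_near_duplicates",
    "screen_rrna",
    "detect_chimera",
    "cluster_by_identity",
    "build_reference",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for the condensation stages.

    dedup_identity: near-duplicate threshold (0.99, tolerating sequencing
        error); otu_identity: species-level clustering threshold (0.97).
    kmer_size_screen / rrna_score_min: the rRNA screen keeps a read when the
        best screening reference shares at least ``rrna_score_min`` of the
        read's canonical k-mers. chimera_min_improvement: how much better a
        two-parent model must explain a read than any single parent before
        the read is called chimeric.
    """

    dedup_identity: float = 0.99
    otu_identity: float = 0.97
    kmer_size_screen: int = 15
    rrna_score_min: float = 0.2
    chimera_min_improvement: float = 0.02
    min_coverage: float = 0.9  # of the shorter sequence, for OTU clustering

    def __post_init__(self) -> None:
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must be in (0, 1]")
        if not 0 < self.otu_identity <= 1:
            raise ValueError("otu_identity must be in (0, 1]")
        if self.dedup_identity < self.otu_identity:
            raise ValueError("dedup_identity must be >= otu_identity")


@dataclass
class Cluster:
    """A greedy cluster: its representative sequence and member ids."""

    representative: SequenceRecord
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.representative.id not in self.members:
            raise ValueError("representative id must be a member")


@dataclass(frozen=True)
class ChimeraVerdict:
    """Outcome of the two-parent chimera test for one read."""

    is_chimera: bool
    best_single_identity: float
    best_chimeric_identity: float
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None


def _greedy_order(reads: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # longest-first, ties broken lexicographically by id: deterministic
    return sorted(reads, key=lambda r: (-len(r.residues), r.id))


def _prefix_identity(shorter: str, longer: str) -> float:
    """Identity of the shorter sequence against the longer one's 5' prefix."""
    matches = sum(1 for a, b in zip(shorter, longer) if a == b)
    return matches / len(shorter)


def dedup_near_duplicates(
    reads: Sequence[SequenceRecord], identity: float = 0.99
) -> list[Cluster]:
    """Greedy removal of artificial duplicates at 99% identity.

    Reads are processed longest-first; a read joins the first cluster whose
    representative it near-prefixes (5'-anchored, identity over the shorter
    read's length), mirroring how amplicon duplicates arise as re-reads of
    the same molecule. Representatives are the longest member.
    """
    if not reads:
        raise ValueError("dedup requires at least one read")
    clusters: list[Cluster] = []
    for rec in _greedy_order(reads):
        placed = False
        for cluster in clusters:
            rep = cluster.representative.residues
            if _prefix_identity(rec.residues, rep) >= identity:
                cluster.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[rec.id]))
    return clusters


def _canonical_kmers(residues: str, k: int) -> set[str]:
    rc = residues.translate(_COMPLEMENT)[::-1]
    n = len(residues)
    kmers: set[str] = set()
    for i in range(n - k + 1):
        fwd = residues[i : i + k]
        rev = rc[n - k - i : n - i]
        kmers.add(min(fwd, rev))
    return kmers


def screen_rrna(
    rec: SequenceRecord,
    screen_ref: Sequence[SequenceRecord],
    params: ClusterParams | None = None,
) -> tuple[bool, float]:
    """Keep a read iff it shares enough canonical k-mers with a screening reference.

    The score is max over screening sequences of |shared k-mers| / |k-mers
    in the read|; reads shorter than k are discarded with score 0. This is
    a desk-scale stand-in for a dedicated rRNA predictor.
    """
    params = params or ClusterParams()
    if not screen_ref:
        raise ValueError("screening reference must be non-empty")
    k = params.kmer_size_screen
    rec_kmers = _canonical_kmers(rec.residues, k) if len(rec.residues) >= k else set()
    if not rec_kmers:
        return False, 0.0
    best = 0.0
    for ref in screen_ref:
        ref_kmers = _canonical_kmers(ref.residues, k)
        score = len(rec_kmers & ref_kmers) / len(rec_kmers)
        best = max(best, score)
        if best == 1.0:
            break
    return best >= params.rrna_score_min, best


def detect_chimera(
    rec: SequenceRecord,
    candidates: Sequence[SequenceRecord],
    params: ClusterParams | None = None,
    grid_step: int = 10,
    end_exclusion: int = 50,
    min_decisive: int = 3,
) -> ChimeraVerdict:
    """Two-parent chimera test on a fixed breakpoint grid.

    Reads and candidates are 5'-anchored (amplicon convention), so segments
    are compared ungapped and position-aligned. For every breakpoint (every
    ``grid_step`` bp, excluding ``end_exclusion`` bp at each end) and every
    ordered candidate pair (A left, B right), the two-parent model's
    identity is evaluated over the column horizon the pair can explain
    (positions a parent does not cover count as unexplained) and compared
    to the best single candidate over the *same* horizon. The read is
    chimeric when some admissible two-parent model beats the matched
    single-parent model by ``chimera_min_improvement``.

    Two admissibility guards make "the two parents differ" quantitative and
    block coverage artifacts:

    * the parents must diverge from each other by at least twice the
      improvement margin over their shared prefix (closer pairs are
      indistinguishable from sequencing noise);
    * each flank must carry at least ``min_decisive`` columns where the
      read matches that flank's parent but not the other parent (counted
      where both parents are covered), and such yes-votes must outnumber
      counter-votes two to one. Without positive evidence on both flanks,
      a long candidate stitched onto a short one would pass for a chimera
      merely by covering more of the read.
    """
    params = params or ClusterParams()
    if not candidates:
        raise ValueError("chimera detection requires candidate parents")

    n = len(rec.residues)
    rec_arr = np.frombuffer(rec.residues.encode(), dtype=np.uint8)
    k = len(candidates)
    lengths = np.array([min(n, len(c.residues)) for c in candidates])
    # match[i, p]: read base p agrees with candidate i (False beyond coverage)
    match = np.zeros((k, n), dtype=bool)
    cover = np.zeros((k, n), dtype=bool)
    for i, cand in enumerate(candidates):
        li = lengths[i]
        cand_arr = np.frombuffer(cand.residues.encode(), dtype=np.uint8)[:li]
        match[i, :li] = rec_arr[:li] == cand_arr
        cover[i, :li] = True
    # cum_match[i, p]: matches of rec[:p] vs candidate i
    cum_match = np.zeros((k, n + 1), dtype=np.int64)
    np.cumsum(match, axis=1, out=cum_match[:, 1:])

    def single_at(horizon: int) -> float:
        return cum_match[:, horizon].max() / horizon

    def parents_separable(i: int, j: int) -> bool:
        a, b = candidates[i].residues, candidates[j].residues
        shared = min(len(a), len(b))
        if shared == 0:
            return False
        mismatches = sum(1 for x, y in zip(a[:shared], b[:shared]) if x != y)
        return mismatches / shared >= 2 * params.chimera_min_improvement

    pairs = [
        (i, j)
        for i in range(k)
        for j in range(k)
        if i != j and parents_separable(min(i, j), max(i, j))
    ]
    # decisive[(i, j), p]: rec matches i but not j, both covering p
    decisive_cum: dict[tuple[int, int], np.ndarray] = {}
    for i, j in pairs:
        dec = match[i] & cover[j] & ~match[j]
        cum = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(dec, out=cum[1:])
        decisive_cum[(i, j)] = cum

    best_single_full = single_at(n) if n else 0.0
    best_improvement = 0.0
    best_chimeric = best_single_full
    best_single_matched = best_single_full
    best_parents: tuple[str, str] | None = None
    best_breakpoint: int | None = None

    for bp in range(end_exclusion, n - end_exclusion + 1, grid_step):
        singles_cache: dict[int, float] = {}
        for i, j in pairs:  # i: left parent, j: right parent
            horizon = int(lengths[j])
            if horizon <= bp:
                continue
            yes_left = decisive_cum[(i, j)][bp]
            no_left = decisive_cum[(j, i)][bp]
            yes_right = decisive_cum[(j, i)][horizon] - decisive_cum[(j, i)][bp]
            no_right = decisive_cum[(i, j)][horizon] - decisive_cum[(i, j)][bp]
            if (
                yes_left < min_decisive
                or yes_right < min_decisive
                or yes_left < 2 * no_left
                or yes_right < 2 * no_right
            ):
                continue
            left = cum_match[i, min(bp, int(lengths[i]))]
            right = cum_match[j, horizon] - cum_match[j, bp]
            chimeric = (left + right) / horizon
            if horizon not in singles_cache:
                singles_cache[horizon] = single_at(horizon)
            improvement = chimeric - singles_cache[horizon]
            if improvement > best_improvement:
                best_improvement = improvement
                best_chimeric = chimeric
                best_single_matched = singles_cache[horizon]
                best_parents = (candidates[i].id, candidates[j].id)
                best_breakpoint = bp

    is_chimera = (
        best_parents is not None
        and best_improvement >= params.chimera_min_improvement
    )
    return ChimeraVerdict(
        is_chimera=is_chimera,
        best_single_identity=best_single_matched if is_chimera else best_single_full,
        best_chimeric_identity=best_chimeric,
        parents=best_parents if is_chimera else None,
        breakpoint=best_breakpoint if is_chimera else None,
    )


def _otu_identity(query: str, rep: str, params: ClusterParams) -> float:
    """matches / alignment columns of the best local alignment, with a
    coverage floor of ``min_coverage`` of the shorter sequence."""
    aln = local_align(query, rep)
    if aln is None:
        return 0.0
    shorter = min(len(query), len(rep))
    if len(query) <= len(rep):
        span = aln.query_span[1] - aln.query_span[0]
    else:
        span = aln.subject_span[1] - aln.subject_span[0]
    if span < params.min_coverage * shorter:
        return 0.0
    return aln.identity


def cluster_by_identity(
    reads: Sequence[SequenceRecord],
    identity: float = 0.97,
    params: ClusterParams | None = None,
) -> list[Cluster]:
    """Greedy centroid clustering at the species boundary (97% identity).

    Longest-first; a read joins the first cluster whose representative
    aligns at >= ``identity`` (matches / alignment columns of the best
    local alignment covering >= 90% of the shorter sequence), else founds
    a new cluster.
    """
    if not reads:
        raise ValueError("clustering requires at least one read")
    params = params or ClusterParams()
    clusters: list[Cluster] = []
    for rec in _greedy_order(reads):
        placed = False
        for cluster in clusters:
            if _otu_identity(rec.residues, cluster.representative.residues, params) >= identity:
                cluster.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[rec.id]))
    return clusters


def build_reference(
    reads_by_env: Mapping[str, Sequence[SequenceRecord]],
    screen_ref: Sequence[SequenceRecord],
    params: ClusterParams | None = None,
    stage_counts: dict | None = None,
) -> ReferenceStore:
    """Condense QC-passed reads into the labeled reference store.

    Per environment: dedup at 99% -> rRNA screen -> chimera filter (against
    dedup representatives with >= 2 members, an abundance proxy) -> 97%
    clustering. Cluster representatives become entries ``env.1 .. env.R(e)``.
    Environments whose reads are all filtered out are omitted with a warning.
    If ``stage_counts`` (a dict) is supplied it is filled with per-env,
    per-stage surviving counts for flowchart-style accounting.
    """
    params = params or ClusterParams()
    if not any(reads_by_env.values()):
        raise ValueError("at least one environment must have reads")

    entries: list[ReferenceEntry] = []
    for env, reads in reads_by_env.items():
        counts = {"input": len(reads)}
        if not reads:
            logger.warning("environment %r has no reads; omitted", env)
            _record(stage_counts, env, counts)
            continue

        dedup_clusters = dedup_near_duplicates(reads, params.dedup_identity)
        reps = [c.representative for c in dedup_clusters]
        counts["dedup"] = len(reps)

        kept = [rec for rec in reps if screen_rrna(rec, screen_ref, params)[0]]
        counts["rrna_screen"] = len(kept)

        # abundance proxy: dedup representatives backed by >= 2 members
        abundant = [
            c.representative for c in dedup_clusters if len(c.members) >= 2
        ]
        if abundant:
            non_chimeric = []
            for rec in kept:
                others = [c for c in abundant if c.id != rec.id]
                if not others:
                    non_chimeric.append(rec)
                    continue
                verdict = detect_chimera(rec, others, params)
                if not verdict.is_chimera:
                    non_chimeric.append(rec)
        else:
            non_chimeric = kept
        counts["chimera_filter"] = len(non_chimeric)

        if not non_chimeric:
            logger.warning("environment %r lost all reads during filtering; omitted", env)
            _record(stage_counts, env, counts)
            continue

        otus = cluster_by_identity(non_chimeric, params.otu_identity, params)
        counts["clusters"] = len(otus)
        _record(stage_counts, env, counts)

        for ordinal, cluster in enumerate(otus, start=1):
            entries.append(
                ReferenceEntry(env=env, ordinal=ordinal, residues=cluster.representative.residues)
            )

    if not entries:
        raise ValueError("all environments were filtered out; empty reference store")
    return ReferenceStore(entries=entries)


def _record(stage_counts: dict | None, env: str, counts: dict) -> None:
    if stage_counts is not None:
        stage_counts[env] = counts


def stage_counts_to_json(stage_counts: Mapping[str, Mapping[str, int]]) -> str:
    return json.dumps(stage_counts, indent=2, sort_keys=True)
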