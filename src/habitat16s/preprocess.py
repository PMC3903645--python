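"""Amplicon read quality control.

Four bespoke filters applied in a fixed order, mirroring the classic 454
cleanup recipe: (1) 3' quality trimming at Phred < 20, (2) 3' adapter
removal, (3) discarding reads containing ambiguous bases, (4) truncation at
homopolymer runs of 5 bp or longer. After every trimming stage, reads
shorter than the 200 bp floor are dropped and attributed to that stage.
Reads lacking Phred scores are removed at stage 1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import SequenceRecord

__all__ = [
    "QCParams",
    "QCReport",
    "trim_quality",
    "remove_adapters",
    "filter_ambiguous",
    "trim_homopolymers",
    "run_qc",
    "STAGES",
]

STAGES = ("quality", "adapter", "ambiguous", "homopolymer")

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class QCParams:
    """Tunable thresholds for read QC.

    Defaults follow the published pipeline: Phred floor 20, 200 bp minimum
    length, homopolymer runs of >= 5 bp trimmed. Adapters are user-supplied;
    matching tolerates ``adapter_max_error_rate`` mismatches per overlap
    base with at least ``adapter_min_overlap`` bases of overlap.
    """

    quality_floor: int = 20
    min_length: int = 200
    homopolymer_min_run: int = 5
    adapters: tuple[str, ...] = ()
    adapter_min_overlap: int = 3
    adapter_max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.quality_floor < 0:
            raise ValueError("quality_floor must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if not 0 <= self.adapter_max_error_rate < 0.5:
            raise ValueError("adapter_max_error_rate must be in [0, 0.5)")


@dataclass
class QCReport:
    """Per-stage accounting of removed reads and trimmed bases."""

    input_count: int = 0
    surviving_count: int = 0
    removed_by_stage: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STAGES})
    trimmed_bases_by_stage: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in STAGES}
    )

    def check(self) -> None:
        if self.surviving_count + sum(self.removed_by_stage.values()) != self.input_count:
            raise AssertionError("QC accounting violated: removed + surviving != input")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "surviving_count": self.surviving_count,
                "removed_by_stage": self.removed_by_stage,
                "trimmed_bases_by_stage": self.trimmed_bases_by_stage,
            },
            indent=2,
        )

    def to_table(self) -> str:
        lines = [
            f"input\t{self.input_count}",
            f"surviving\t{self.surviving_count}",
        ]
        for stage in STAGES:
            lines.append(f"removed.{stage}\t{self.removed_by_stage[stage]}")
        for stage in STAGES:
            lines.append(f"trimmed_bases.{stage}\t{self.trimmed_bases_by_stage[stage]}")
        return "\n".join(lines)


def _truncate(rec: SequenceRecord, end: int) -> SequenceRecord | None:
    """Keep the first ``end`` bases; None when nothing is left."""
    if end <= 0:
        return None
    if end >= len(rec.residues):
        return rec
    quals = rec.qualities[:end] if rec.qualities is not None else None
    return SequenceRecord(id=rec.id, residues=rec.residues[:end], qualities=quals)


def trim_quality(rec: SequenceRecord, floor: int = 20) -> SequenceRecord | None:
    """Remove the longest 3' suffix in which every base is below ``floor``.

    Returns None when the entire read is below the floor. 5' trimming is
    deliberately not performed: pyrosequencing quality decays at the 3' end.
    """
    if rec.qualities is None:
        raise ValueError(f"record {rec.id!r} lacks quality scores")
    end = len(rec.qualities)
    while end > 0 and rec.qualities[end - 1] < floor:
        end -= 1
    return _truncate(rec, end)


def _adapter_match_start(residues: str, adapter: str, min_overlap: int, max_error_rate: float) -> int | None:
    """Leftmost start of an acceptable 3'-anchored adapter occurrence.

    At a start position the overlap is fixed (the adapter may run off the
    read's 3' end); the occurrence is acceptable when the overlap reaches
    ``min_overlap`` and mismatches stay within ``max_error_rate`` per base.
    Leftmost-first keeps the operation idempotent.
    """
    n, m = len(residues), len(adapter)
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        if overlap < min_overlap:
            break
        mismatches = sum(
            1 for a, b in zip(residues[start : start + overlap], adapter[:overlap]) if a != b
        )
        if mismatches <= max_error_rate * overlap:
            return start
    return None


def remove_adapters(rec: SequenceRecord, params: QCParams) -> SequenceRecord | None:
    """Trim the read at the leftmost acceptable 3' adapter occurrence.

    Everything from the adapter start to the 3' end is removed. Trimming
    repeats until no acceptable occurrence remains (a shorter read can
    expose a new partial occurrence at its fresh 3' end), so the operation
    is idempotent. Reads with no acceptable occurrence pass unchanged.
    """
    current: SequenceRecord | None = rec
    while current is not None:
        best: int | None = None
        for adapter in params.adapters:
            start = _adapter_match_start(
                current.residues, adapter.upper(),
                params.adapter_min_overlap, params.adapter_max_error_rate,
            )
            if start is not None and (best is None or start < best):
                best = start
        if best is None:
            return current
        current = _truncate(current, best)
    return None


def filter_ambiguous(rec: SequenceRecord) -> bool:
    """Keep decision: True iff the read contains only unambiguous A/C/G/T."""
    return bool(rec.residues) and set(rec.residues) <= _UNAMBIGUOUS


def trim_homopolymers(rec: SequenceRecord, min_run: int = 5) -> SequenceRecord | None:
    """Truncate at the first single-base run of length >= ``min_run``.

    The 5' prefix before the run is kept; a read opening with such a run
    collapses to nothing (None).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    match = re.search(r"(.)\1{%d,}" % (min_run - 1), rec.residues)
    if match is None:
        return rec
    return _truncate(rec, match.start())


def run_qc(
    reads: Iterable[SequenceRecord], params: QCParams | None = None
) -> tuple[list[SequenceRecord], QCReport]:
    """Apply the full QC cascade and account for every input read.

    Stage order: quality trim -> adapter removal -> ambiguity filter ->
    homopolymer trim. The length floor is enforced after each trimming
    stage, and each removal is charged to the stage that caused it.
    """
    params = params or QCParams()
    report = QCReport()
    surviving: list[SequenceRecord] = []

    for rec in reads:
        report.input_count += 1
        current: SequenceRecord | None = rec

        # stage 1: quality trimming (reads without Phred scores removed here)
        if current.qualities is None:
            report.removed_by_stage["quality"] += 1
            continue
        before = len(current)
        current = trim_quality(current, params.quality_floor)
        report.trimmed_bases_by_stage["quality"] += before - (len(current) if current else 0)
        if current is None or len(current) < params.min_length:
            report.removed_by_stage["quality"] += 1
            continue

        # stage 2: adapter removal
        if params.adapters:
            before = len(current)
            current = remove_adapters(current, params)
            report.trimmed_bases_by_stage["adapter"] += before - (len(current) if current else 0)
            if current is None or len(current) < params.min_length:
                report.removed_by_stage["adapter"] += 1
                continue

        # stage 3: ambiguity filter (whole-read discard, no trimming)
        if not filter_ambiguous(current):
            report.removed_by_stage["ambiguous"] += 1
            continue

        # stage 4: homopolymer truncation
        before = len(current)
        current = trim_homopolymers(current, params.homopolymer_min_run)
        report.trimmed_bases_by_stage["homopolymer"] += before - (len(current) if current else 0)
        if current is None or len(current) < params.min_length:
            report.removed_by_stage["homopolymer"] += 1
            continue

        surviving.append(current)
        report.surviving_count += 1

    report.check()
    return surviving, report
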