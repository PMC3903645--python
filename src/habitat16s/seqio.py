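"""Sequence I/O and the environment-labeled reference store.

FASTA and FASTQ parsing is delegated to Biopython's :mod:`Bio.SeqIO`; this
module adds the validation the pipeline relies on (non-empty sequences,
Phred+33 qualities present and length-matched) and the reference header
grammar ``>{env}.{ordinal}`` used to carry environmental-category labels
(e.g. ``soil.12``, ``human gut.3``). The environment label may contain
spaces and dots; the ordinal is whatever follows the *last* dot.
"""

from __future__ import annotations

import gzip
import io
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ParseError",
    "SequenceRecord",
    "ReferenceEntry",
    "ReferenceStore",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "load_reference",
    "export_reference",
]

_VALID = set("ACGTN")


class ParseError(ValueError):
    """Raised when a sequence file violates the expected format."""


def _normalize(residues: str) -> str:
    # uppercase and U->T so RNA-space references behave like DNA
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence with optional per-base Phred scores."""

    id: str
    residues: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residues")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality scores for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceEntry:
    """One representative sequence labeled with its environmental category."""

    env: str
    ordinal: int
    residues: str

    def __post_init__(self) -> None:
        if not self.env:
            raise ValueError("environment label must be non-empty")
        if "\n" in self.env or "\r" in self.env:
            raise ValueError("environment label may not contain line separators")
        if self.ordinal < 1:
            raise ValueError(f"ordinal must be >= 1, got {self.ordinal}")
        if not self.residues:
            raise ValueError(f"reference entry {self.env}.{self.ordinal}: empty residues")

    @property
    def label(self) -> str:
        return f"{self.env}.{self.ordinal}"


@dataclass
class ReferenceStore:
    """Environment-labeled representatives plus per-environment counts.

    ``counts_per_env`` holds R(e), the number of representatives carrying
    label *e*; ``total`` is R_total. Both feed the inverse-document-frequency
    weight log(R_total / R(e)) of the habitability index.
    """

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty reference store")

    @property
    def counts_per_env(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for entry in self.entries:
            counts[entry.env] += 1
        return dict(counts)

    @property
    def total(self) -> int:
        return len(self.entries)

    @property
    def environments(self) -> list[str]:
        seen: dict[str, None] = {}
        for entry in self.entries:
            seen.setdefault(entry.env, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_fasta_layout(handle: io.TextIOBase) -> None:
    """Pre-scan a FASTA stream so parse errors can name a line number."""
    header_line: int | None = None
    has_residues = False
    for lineno, line in enumerate(handle, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not has_residues:
                raise ParseError(
                    f"line {header_line}: FASTA header without sequence"
                )
            if len(stripped) == 1:
                raise ParseError(f"line {lineno}: empty FASTA header")
            header_line = lineno
            has_residues = False
        else:
            if header_line is None:
                raise ParseError(f"line {lineno}: sequence before any FASTA header")
            has_residues = True
    if header_line is not None and not has_residues:
        raise ParseError(f"line {header_line}: FASTA header without sequence")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased with U mapped to T; qualities are absent.
    Raises :class:`ParseError` for headers without sequence lines.
    """
    with _open_text(path) as handle:
        _check_fasta_layout(handle)
    with _open_text(path) as handle:
        return [
            SequenceRecord(id=rec.id, residues=_normalize(str(rec.seq)))
            for rec in SeqIO.parse(handle, "fasta")
        ]


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read Phred+33 FASTQ into records carrying integer quality scores.

    Length mismatches between sequence and quality lines surface as
    :class:`ParseError` (via Biopython's validation).
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                records.append(
                    SequenceRecord(
                        id=rec.id,
                        residues=_normalize(str(rec.seq)),
                        qualities=tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as Phred+33 FASTQ; records must carry qualities."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} lacks quality scores")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


def parse_reference_header(header: str) -> tuple[str, int]:
    """Split ``env.ordinal`` on the final dot; env may itself contain dots/spaces."""
    env, dot, ordinal_text = header.rpartition(".")
    if not dot or not env:
        raise ParseError(f"reference header {header!r} does not match '<env>.<ordinal>'")
    try:
        ordinal = int(ordinal_text)
    except ValueError:
        raise ParseError(
            f"reference header {header!r}: ordinal {ordinal_text!r} is not an integer"
        ) from None
    if ordinal < 1:
        raise ParseError(f"reference header {header!r}: ordinal must be >= 1")
    return env, ordinal


def load_reference(path: str | Path) -> ReferenceStore:
    """Load an environment-labeled reference FASTA into a :class:`ReferenceStore`."""
    entries = []
    with _open_text(path) as handle:
        _check_fasta_layout(handle)
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            # header may contain spaces: rejoin id + description
            header = rec.description if rec.description else rec.id
            env, ordinal = parse_reference_header(header)
            entries.append(
                ReferenceEntry(env=env, ordinal=ordinal, residues=_normalize(str(rec.seq)))
            )
    if not entries:
        raise ParseError(f"{path}: empty reference store")
    return ReferenceStore(entries=entries)


def export_reference(store: ReferenceStore, path: str | Path, width: int = 70) -> None:
    """Write the store as FASTA with ``>{env}.{ordinal}`` headers.

    Entries are emitted grouped by environment in first-seen order, ordinals
    ascending, so ``load_reference`` round-trips the store exactly.
    """
    by_env: dict[str, list[ReferenceEntry]] = defaultdict(list)
    for entry in store.entries:
        by_env[entry.env].append(entry)
    with _open_text(path, "wt") as handle:
        for env in by_env:
            for entry in sorted(by_env[env], key=lambda e: e.ordinal):
                handle.write(f">{entry.label}\n")
                for i in range(0, len(entry.residues), width):
                    handle.write(entry.residues[i : i + width] + "\n")
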