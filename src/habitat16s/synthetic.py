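"""Ground-truthed synthetic corpora for pipeline and recovery tests.

The generator emulates an amplicon-style 16S survey: per-environment
template sequences diverged from a common ancestor, and 5'-anchored reads
(as produced by a fixed forward primer) with controlled artifacts —
near-duplicates, two-parent chimeras, ambiguous bases, sub-length products,
a low-quality 3' tail, and an optional appended adapter. Every read carries
a truth record naming its source environment, template and artifact type,
so QC and condensation stages can be checked removal-for-removal.

Two deliberate simplifications keep the arithmetic of the tests analytic:

* substitutions only (an indel rate exists for exercising gap handling but
  defaults to zero), placed on a jittered grid so per-read divergence is
  the stated value rather than a binomial draw;
* sequences are generated free of homopolymer runs >= 5 bp, so the
  homopolymer filter never fires on non-planted content and stage
  accounting stays exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import SequenceRecord, write_fastq, write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SimTruth",
    "generate_templates",
    "simulate_reads",
    "generate_query",
    "write_corpus",
]

_BASES = "ACGT"
_MAX_RUN = 3  # longest homopolymer allowed in generated sequence


@dataclass(frozen=True)
class SimParams:
    """The stated world of the simulator.

    Defaults describe a small two-environment amplicon survey: 5 templates
    per environment at ~10% mutual divergence (comfortably across the 97%
    species boundary), 100 reads per environment of 250-450 bp (the real
    corpus averages ~350 bp with a 200 bp floor), 1.2% read error, and
    artifact rates of 25% duplicates, 5% chimeras, 5% ambiguous reads and
    5% sub-length products. Quality is flat at Phred 38 over the read body
    and ramps from 19 down to 10 across a 50 bp 3' tail, so the Q20 trimmer
    removes exactly the tail.
    """

    n_envs: int = 2
    templates_per_env: int = 5
    template_len: int = 1200
    template_divergence: float = 0.10
    reads_per_env: int = 100
    read_len_range: tuple[int, int] = (250, 450)
    read_divergence: float = 0.012
    indel_rate: float = 0.0
    rate_duplicate: float = 0.25
    rate_chimera: float = 0.05
    rate_ambiguous: float = 0.05
    rate_short: float = 0.05
    adapter: str | None = None
    quality_profile: tuple[int, int, int] = (38, 10, 50)  # (high, low, 3' decay bp)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_duplicate", "rate_chimera", "rate_ambiguous", "rate_short"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rate_chimera + self.rate_ambiguous + self.rate_short + self.rate_duplicate > 1:
            raise ValueError("artifact rates must sum to <= 1")
        if self.template_len < 4 * self.read_len_range[0]:
            raise ValueError("template_len must be >= 4x the read minimum")
        if self.read_len_range[0] > self.read_len_range[1]:
            raise ValueError("read_len_range must be (min, max)")
        high, low, decay = self.quality_profile
        if not (low < 20 <= high):
            raise ValueError("quality profile must decay from >= Q20 to < Q20")

    @property
    def env_names(self) -> list[str]:
        return [f"env{i + 1}" for i in range(self.n_envs)]


@dataclass
class SimTruth:
    """Ground truth: one record per emitted read, plus the templates."""

    reads: dict[str, dict] = field(default_factory=dict)
    templates: dict[str, list[str]] = field(default_factory=dict)

    def ids_of_kind(self, kind: str, env: str | None = None) -> list[str]:
        return [
            rid
            for rid, info in self.reads.items()
            if info["kind"] == kind and (env is None or info["env"] == env)
        ]

    def to_json(self) -> str:
        return json.dumps({"reads": self.reads, "templates": self.templates}, indent=2)


def _run_at(seq: Sequence[str], pos: int, base: str) -> int:
    """Homopolymer run length at ``pos`` if ``base`` were placed there."""
    run = 1
    i = pos - 1
    while i >= 0 and seq[i] == base:
        run += 1
        i -= 1
    i = pos + 1
    while i < len(seq) and seq[i] == base:
        run += 1
        i += 1
    return run


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    seq: list[str] = []
    for _ in range(length):
        choices = [b for b in _BASES if not (len(seq) >= _MAX_RUN and all(c == b for c in seq[-_MAX_RUN:]))]
        seq.append(choices[rng.integers(len(choices))])
    return seq


def _spread_positions(rng: np.random.Generator, length: int, n: int) -> list[int]:
    """n distinct positions, one jittered into each of n equal bins."""
    if n <= 0:
        return []
    edges = np.linspace(0, length, n + 1)
    positions = []
    for i in range(n):
        lo, hi = int(edges[i]), max(int(edges[i]) + 1, int(edges[i + 1]))
        positions.append(int(rng.integers(lo, hi)))
    return positions


def _substitute(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    """Substitute ``pos`` with a different base, avoiding runs >= MAX_RUN+1."""
    orig = seq[pos]
    candidates = [b for b in _BASES if b != orig]
    order = rng.permutation(len(candidates))
    for idx in order:
        base = candidates[idx]
        if _run_at(seq, pos, base) <= _MAX_RUN:
            seq[pos] = base
            return
    seq[pos] = candidates[order[0]]  # degenerate context; accept the run


def _mutate(seq: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for pos in _spread_positions(rng, len(out), round(rate * len(out))):
        _substitute(out, pos, rng)
    return out


def _has_long_run(seq: Sequence[str], min_run: int = 5) -> bool:
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run >= min_run:
            return True
    return False


def generate_templates(params: SimParams) -> dict[str, list[str]]:
    """Per-environment template sequences from a common ancestor.

    Every template is mutated independently at half the stated divergence,
    so any pair of templates (within or across environments) sits at
    approximately ``template_divergence``. Deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed)
    ancestor = _random_sequence(rng, params.template_len)
    templates: dict[str, list[str]] = {}
    per_template = params.template_divergence / 2
    for env in params.env_names:
        templates[env] = [
            "".join(_mutate(ancestor, per_template, rng))
            for _ in range(params.templates_per_env)
        ]
    return templates


def _apply_indels(seq: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0:
        return seq
    out: list[str] = []
    for base in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(base)
        if r >= rate / 2 and r < rate:  # insertion after this base
            out.append(_BASES[rng.integers(4)])
    return out


def _tail_qualities(params: SimParams) -> list[int]:
    high, low, decay = params.quality_profile
    # linear ramp strictly below Q20 so the trimmer removes exactly the tail
    ramp = np.linspace(19, low, decay)
    return [int(q) for q in ramp]


def _finish_read(
    rid: str,
    body: list[str],
    template: str,
    start_in_template: int,
    params: SimParams,
    rng: np.random.Generator,
) -> SequenceRecord:
    """Append adapter (if configured) and the low-quality 3' tail."""
    high, low, decay = params.quality_profile
    residues = list(body)
    quals = [high] * len(body)
    if params.adapter:
        residues.extend(params.adapter)
        quals.extend([high] * len(params.adapter))
    # tail: continuation of the template (or random), destined for the Q20 trim
    tail_src = template[start_in_template + len(body) :]
    tail = list(tail_src[:decay])
    if len(tail) < decay:
        tail.extend(_random_sequence(rng, decay - len(tail)))
    residues.extend(tail)
    quals.extend(_tail_qualities(params))
    return SequenceRecord(id=rid, residues="".join(residues), qualities=tuple(quals))


def simulate_reads(
    templates: Mapping[str, list[str]], params: SimParams
) -> tuple[dict[str, list[SequenceRecord]], SimTruth]:
    """Emit per-environment FASTQ reads with planted artifacts and truth.

    Reads are 5'-anchored template prefixes (amplicon convention). Artifact
    classes are mutually exclusive per read: chimera, ambiguous, short,
    duplicate (of an earlier clean read), else normal. Chimeras join two
    distinct templates of the same environment at a breakpoint in the
    middle of the read, so chimera removal cannot change the environment
    composition; their parents are drawn from the templates that carry
    duplicated reads, reflecting that chimeric amplicons form preferentially
    between abundant parent molecules during PCR.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    truth = SimTruth(templates={env: list(ts) for env, ts in templates.items()})
    reads_by_env: dict[str, list[SequenceRecord]] = {env: [] for env in templates}
    counter = 0

    for env, env_templates in templates.items():
        clean_pool: list[tuple[list[str], int]] = []  # (body, template index)
        duplicated_templates: set[int] = set()
        chimera_slots: list[tuple[int, str]] = []  # (position in env list, read id)
        for _ in range(params.reads_per_env):
            rid = f"read{counter:05d}"
            counter += 1
            u = rng.random()
            lo, hi = params.read_len_range
            length = int(rng.integers(lo, hi + 1))

            if u < params.rate_chimera:
                if len(env_templates) < 2:
                    logger.warning(
                        "environment %r has one template; chimera needs two "
                        "parents, emitting a normal read instead", env,
                    )
                    u = 1.0  # fall through to the normal branch
                else:
                    # parents depend on which templates end up duplicated;
                    # filled in a second pass once the clean reads exist
                    chimera_slots.append((len(reads_by_env[env]), rid))
                    reads_by_env[env].append(None)  # placeholder
                    continue
            if u < params.rate_chimera + params.rate_ambiguous:
                t = int(rng.integers(len(env_templates)))
                body = _mutate(list(templates[env][t][:length]), params.read_divergence, rng)
                n_amb = int(rng.integers(1, 4))
                for pos in rng.choice(np.arange(5, length - 2), size=n_amb, replace=False):
                    body[int(pos)] = "N"
                rec = _finish_read(rid, body, env_templates[t], 0, params, rng)
                truth.reads[rid] = {"env": env, "kind": "ambiguous", "template": t}
            elif u < params.rate_chimera + params.rate_ambiguous + params.rate_short:
                t = int(rng.integers(len(env_templates)))
                short_len = int(rng.integers(60, 191))
                body = _mutate(list(env_templates[t][:short_len]), params.read_divergence, rng)
                rec = _finish_read(rid, body, env_templates[t], 0, params, rng)
                truth.reads[rid] = {"env": env, "kind": "short", "template": t}
            elif (
                u < params.rate_chimera + params.rate_ambiguous + params.rate_short + params.rate_duplicate
                and clean_pool
            ):
                src_idx = int(rng.integers(len(clean_pool)))
                src_body, t = clean_pool[src_idx]
                trunc = int(rng.integers(0, 31))
                body = list(src_body[: max(200, len(src_body) - trunc)])
                _substitute(body, int(rng.integers(10, len(body) - 10)), rng)
                rec = _finish_read(rid, body, env_templates[t], 0, params, rng)
                src_rid = [
                    r for r, info in truth.reads.items()
                    if info["env"] == env and info["kind"] == "normal"
                ][src_idx]
                truth.reads[rid] = {
                    "env": env,
                    "kind": "duplicate",
                    "template": t,
                    "duplicate_of": src_rid,
                }
                duplicated_templates.add(t)
            else:
                t = int(rng.integers(len(env_templates)))
                body = _mutate(list(env_templates[t][:length]), params.read_divergence, rng)
                body = _apply_indels(body, params.indel_rate, rng)
                rec = _finish_read(rid, body, env_templates[t], 0, params, rng)
                truth.reads[rid] = {"env": env, "kind": "normal", "template": t}
                clean_pool.append((body, t))

            reads_by_env[env].append(rec)

        # second pass: chimeras, parents drawn among the duplicated templates
        lo, hi = params.read_len_range
        parent_pool = sorted(duplicated_templates)
        if len(parent_pool) < 2:
            parent_pool = list(range(len(env_templates)))
            if chimera_slots:
                logger.warning(
                    "environment %r has <2 duplicated templates; chimera "
                    "parents drawn from all templates", env,
                )
        for pos, rid in chimera_slots:
            # chimeric amplicons arise from aborted extension products and
            # skew short; keeping them in the lower half of the length range
            # also keeps them within reach of their parent reads
            length = int(rng.integers(lo, (lo + hi) // 2 + 1))
            pick = rng.choice(len(parent_pool), size=2, replace=False)
            t1, t2 = parent_pool[int(pick[0])], parent_pool[int(pick[1])]
            body = None
            for _attempt in range(20):
                bp = int(length * rng.uniform(0.35, 0.65))
                candidate = list(env_templates[t1][:bp]) + list(env_templates[t2][bp:length])
                candidate = _mutate(candidate, params.read_divergence, rng)
                if not _has_long_run(candidate):
                    body = candidate
                    break
            if body is None:
                body = candidate  # pragma: no cover - overwhelmingly unlikely
            reads_by_env[env][pos] = _finish_read(rid, body, env_templates[t2], 0, params, rng)
            truth.reads[rid] = {
                "env": env,
                "kind": "chimera",
                "template": int(t1),
                "chimera_parents": [int(t1), int(t2)],
                "breakpoint": bp,
            }

    return reads_by_env, truth


def generate_query(
    templates: Mapping[str, list[str]],
    env: str,
    divergence: float = 0.02,
    length: int = 800,
    seed: int = 0,
) -> SequenceRecord:
    """A query sequence at a controlled divergence from one of ``env``'s templates.

    Substitutions are per-position Bernoulli draws at ``divergence`` (so the
    observed mismatch count is binomial); the sequence is trimmed, or padded
    with random bases, to ``length``.
    """
    if env not in templates:
        raise ValueError(f"unknown environment {env!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    template = templates[env][int(rng.integers(len(templates[env])))]
    seq = list(template[:length])
    if len(seq) < length:
        seq.extend(_random_sequence(rng, length - len(seq)))
    for pos in np.nonzero(rng.random(length) < divergence)[0]:
        _substitute(seq, int(pos), rng)
    return SequenceRecord(id=f"query_{env}_s{seed}", residues="".join(seq))


def write_corpus(outdir: str | Path, params: SimParams) -> dict[str, Path]:
    """Materialize a corpus on disk: per-env FASTQ, env-map TSV, truth JSON,
    screening FASTA (the templates) and one query FASTA per environment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    templates = generate_templates(params)
    reads_by_env, truth = simulate_reads(templates, params)

    paths: dict[str, Path] = {}
    env_map_lines = []
    for env, reads in reads_by_env.items():
        fname = f"{env.replace(' ', '_')}.fastq"
        write_fastq(reads, outdir / fname)
        env_map_lines.append(f"{fname}\t{env}")
    paths["env_map"] = outdir / "env_map.tsv"
    paths["env_map"].write_text("\n".join(env_map_lines) + "\n")

    screen = [
        SequenceRecord(id=f"screen_{env.replace(' ', '_')}_{i}", residues=t)
        for env, ts in templates.items()
        for i, t in enumerate(ts)
    ]
    paths["screen_ref"] = outdir / "screen_ref.fasta"
    write_fasta(screen, paths["screen_ref"])

    queries = [
        generate_query(templates, env, divergence=0.02, length=800, seed=params.seed + i)
        for i, env in enumerate(templates)
    ]
    paths["queries"] = outdir / "queries.fasta"
    write_fasta(queries, paths["queries"])

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths
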