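import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitat16s.condense import (
    ClusterParams,
    build_reference,
    cluster_by_identity,
    dedup_near_duplicates,
    detect_chimera,
    screen_rrna,
)
from habitat16s.preprocess import QCParams, run_qc
from habitat16s.seqio import SequenceRecord


def rec(seq, rid):
    return SequenceRecord(id=rid, residues=seq)


def _mutate(seq, positions):
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = bases[(bases.index(out[p]) + 1) % 4]
    return "".join(out)


# --- independent oracle: full-DP pairwise identity + the same greedy rule ---

def _oracle_local_identity(a, b, match=2, mismatch=3, gap_open=5, gap_extend=2):
    """Plain affine-gap Smith-Waterman with traceback; returns
    (identity, covered span of the shorter sequence)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.full((n + 1, m + 1), 0.0)
    E = np.full((n + 1, m + 1), NEG)  # gap in a
    F = np.full((n + 1, m + 1), NEG)  # gap in b
    ptr = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else -mismatch)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] == 0:
                continue
            if H[i][j] == diag:
                ptr[(i, j)] = ("d", i - 1, j - 1)
            elif H[i][j] == E[i][j]:
                k = j - 1
                while E[i][k + 1] != H[i][k] - gap_open and k > 0:
                    k -= 1
                ptr[(i, j)] = ("e", i, k)
            else:
                k = i - 1
                while F[k + 1][j] != H[k][j] - gap_open and k > 0:
                    k -= 1
                ptr[(i, j)] = ("f", k, j)
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best_pos is None:
        return 0.0, 0
    matches = cols = 0
    i, j = best_pos
    end_i, end_j = i, j
    while (i, j) in ptr and H[i][j] > 0:
        kind, pi, pj = ptr[(i, j)]
        if kind == "d":
            matches += a[i - 1] == b[j - 1]
            cols += 1
        else:
            cols += (j - pj) if kind == "e" else (i - pi)
        i, j = pi, pj
    span = min(end_i - i, end_j - j) if len(a) <= len(b) else None
    covered = (end_i - i) if n <= m else (end_j - j)
    return (matches / cols if cols else 0.0), covered


def _oracle_greedy(reads, identity, min_coverage=0.9):
    order = sorted(reads, key=lambda r: (-len(r.residues), r.id))
    clusters = []
    for r in order:
        placed = False
        for c in clusters:
            rep = c[0]
            ident, covered = _oracle_local_identity(r.residues, rep.residues)
            shorter = min(len(r.residues), len(rep.residues))
            if covered >= min_coverage * shorter and ident >= identity:
                c[1].append(r.id)
                placed = True
                break
        if not placed:
            clusters.append((r, [r.id]))
    return [(c[0].id, sorted(c[1])) for c in clusters]


class TestDedup:
    def test_identical_reads_one_cluster(self):
        clusters = dedup_near_duplicates([rec("ACGT" * 60, "a"), rec("ACGT" * 60, "b")], 0.99)
        assert len(clusters) == 1 and sorted(clusters[0].members) == ["a", "b"]

    def test_five_percent_divergence_two_clusters(self):
        base = "ACGT" * 60
        other = _mutate(base, range(0, 240, 20))  # 12/240 = 5%
        clusters = dedup_near_duplicates([rec(base, "a"), rec(other, "b")], 0.99)
        assert len(clusters) == 2

    def test_shorter_prefix_read_joins(self):
        long = rec("ACGT" * 100, "long")
        short = rec("ACGT" * 60, "short")
        clusters = dedup_near_duplicates([short, long], 0.99)
        assert len(clusters) == 1 and clusters[0].representative.id == "long"

    def test_planted_duplicates_collapse(self, corpus):
        """Dedup cluster count equals non-duplicate surviving reads."""
        reads_by_env, truth = corpus
        for env, reads in reads_by_env.items():
            surviving, _ = run_qc(reads, QCParams())
            clusters = dedup_near_duplicates(surviving, 0.99)
            non_dup = [r for r in surviving if truth.reads[r.id]["kind"] != "duplicate"]
            assert len(clusters) == len(non_dup)


class TestScreenRrna:
    def test_exact_reference_scores_one(self):
        ref = rec("ACGTTGCA" * 30, "ref")
        keep, score = screen_rrna(rec(ref.residues, "q"), [ref])
        assert keep and score == 1.0

    def test_random_sequence_discarded(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        keep, score = screen_rrna(rec(a, "q"), [rec(b, "ref")])
        assert not keep and score < 0.2

    def test_three_percent_divergence_kept(self):
        """~(1-0.03)^15 of 15-mers survive 3% substitution; well above 0.2."""
        rng = np.random.default_rng(1)
        ref_seq = "".join(rng.choice(list("ACGT"), 500))
        positions = rng.choice(500, size=15, replace=False)  # 3%
        query = _mutate(ref_seq, positions)
        keep, score = screen_rrna(rec(query, "q"), [rec(ref_seq, "ref")])
        # direct count: fraction of query 15-mers untouched by a substitution
        hit = np.zeros(500, bool)
        hit[positions] = True
        clean = sum(1 for i in range(500 - 14) if not hit[i : i + 15].any())
        assert keep
        assert score >= clean / (500 - 14) - 1e-9

    def test_too_short_discarded(self):
        keep, score = screen_rrna(rec("ACGT", "q"), [rec("ACGTACGTACGTACGTACGT", "ref")])
        assert (keep, score) == (False, 0.0)


class TestDetectChimera:
    def _parents(self, rng, length=400, divergence=0.10):
        a = "".join(rng.choice(list("ACGT"), length))
        pos = rng.choice(length, size=int(divergence * length), replace=False)
        b = _mutate(a, pos)
        return a, b

    def test_perfect_chimera_flagged(self):
        rng = np.random.default_rng(2)
        a, b = self._parents(rng)
        chimera = a[:200] + b[200:]
        verdict = detect_chimera(
            rec(chimera, "q"), [rec(a, "A"), rec(b, "B")], ClusterParams()
        )
        assert verdict.is_chimera
        assert verdict.best_chimeric_identity == 1.0
        assert verdict.parents == ("A", "B")
        assert abs(verdict.breakpoint - 200) <= 10

    def test_exact_parent_not_flagged(self):
        rng = np.random.default_rng(3)
        a, b = self._parents(rng)
        verdict = detect_chimera(rec(a, "q"), [rec(a, "A"), rec(b, "B")], ClusterParams())
        assert not verdict.is_chimera
        assert verdict.best_single_identity == 1.0

    def test_planted_chimeras_all_flagged_no_false_positives(self, corpus):
        """Synthetic corpus: every planted chimera flagged, nothing else."""
        reads_by_env, truth = corpus
        for env, reads in reads_by_env.items():
            surviving, _ = run_qc(reads, QCParams())
            clusters = dedup_near_duplicates(surviving, 0.99)
            abundant = [c.representative for c in clusters if len(c.members) >= 2]
            flagged = set()
            for c in clusters:
                others = [a for a in abundant if a.id != c.representative.id]
                if not others:
                    continue
                if detect_chimera(c.representative, others, ClusterParams()).is_chimera:
                    flagged.add(c.representative.id)
            planted = {
                rid for rid in truth.ids_of_kind("chimera", env)
                if any(r.id == rid for r in surviving)
            }
            assert flagged == planted


class TestClusterByIdentity:
    def test_one_template_one_cluster(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 300))
        reads = [rec(_mutate(base, rng.choice(300, 3, replace=False)), f"r{i}") for i in range(5)]
        assert len(cluster_by_identity(reads, 0.97)) == 1

    def test_single_read_singleton(self):
        clusters = cluster_by_identity([rec("ACGT" * 60, "only")], 0.97)
        assert len(clusters) == 1 and clusters[0].members == ["only"]

    def test_two_templates_recovered_with_membership(self):
        rng = np.random.default_rng(5)
        t1 = "".join(rng.choice(list("ACGT"), 300))
        t2 = _mutate(t1, rng.choice(300, 30, replace=False))  # 10%
        reads = []
        for i in range(5):
            reads.append(rec(_mutate(t1, rng.choice(300, 3, replace=False)), f"a{i}"))
            reads.append(rec(_mutate(t2, rng.choice(300, 3, replace=False)), f"b{i}"))
        clusters = cluster_by_identity(reads, 0.97)
        assert len(clusters) == 2
        memberships = [set(c.members) for c in clusters]
        assert {frozenset(m) for m in memberships} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_matches_full_dp_oracle_on_small_input(self):
        """Greedy clustering equals the oracle that scores every pair by
        exhaustive affine dynamic programming and applies the same rule."""
        rng = np.random.default_rng(6)
        reads = []
        for t in range(4):
            base = "".join(rng.choice(list("ACGT"), 60 + 5 * t))
            for i in range(4):
                n_mut = int(rng.integers(0, 3))
                mutated = _mutate(base, rng.choice(60, n_mut, replace=False))
                reads.append(rec(mutated, f"t{t}r{i}"))
        got = [
            (c.representative.id, sorted(c.members))
            for c in cluster_by_identity(reads, 0.97)
        ]
        assert got == _oracle_greedy(reads, 0.97)

    def test_partition_property(self, corpus):
        reads_by_env, _ = corpus
        surviving, _ = run_qc(reads_by_env["env1"], QCParams())
        clusters = cluster_by_identity(surviving, 0.97)
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(r.id for r in surviving)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_cluster_count_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), 120))
        reads = [
            rec(_mutate(base, rng.choice(120, int(rng.integers(0, 15)), replace=False)), f"r{i}")
            for i in range(8)
        ]
        counts = [
            len(cluster_by_identity(reads, thr)) for thr in (0.80, 0.90, 0.95, 0.99)
        ]
        assert counts == sorted(counts)


class TestBuildReference:
    def test_full_collapse_two_envs(self):
        rng = np.random.default_rng(7)
        store_reads = {}
        screen = []
        for env in ("soil", "marine"):
            base = "".join(rng.choice(list("ACGT"), 300))
            screen.append(rec(base, f"screen_{env}"))
            store_reads[env] = [
                rec(_mutate(base, rng.choice(300, 2, replace=False)), f"{env}{i}")
                for i in range(10)
            ]
        store = build_reference(store_reads, screen)
        assert store.counts_per_env == {"soil": 1, "marine": 1}
        assert store.total == 2

    def test_recovers_template_counts(self, corpus, templates, sim_params):
        """End-to-end: per-env representative counts equal template counts."""
        reads_by_env, truth = corpus
        surviving = {
            env: run_qc(reads, QCParams())[0] for env, reads in reads_by_env.items()
        }
        screen = [
            rec(t, f"s{i}") for i, ts in enumerate(templates.values()) for t in ts
        ]
        store = build_reference(surviving, screen)
        assert store.counts_per_env == {
            env: sim_params.templates_per_env for env in reads_by_env
        }

    def test_all_filtered_environment_omitted(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 300))
        unrelated = "".join(rng.choice(list("ACGT"), 300))
        reads = {
            "good": [rec(_mutate(base, [i]), f"g{i}") for i in range(3)],
            "junk": [rec(unrelated, "j0")],  # fails the rRNA screen
        }
        store = build_reference(reads, [rec(base, "screen")])
        assert set(store.counts_per_env) == {"good"}

    def test_no_reads_at_all_error(self):
        with pytest.raises(ValueError):
            build_reference({"e": []}, [rec("ACGT" * 20, "s")])
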