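# Methods

This note documents the models and procedures implemented in `habitat16s`,
the defaults and why they hold, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## 1. The habitability index

A query 16S rRNA sequence is aligned against a reference of
environment-labeled representative sequences. For identity threshold *c*
(defaults 0.97, 0.95, 0.90, 0.85, 0.80 — approximately species, genus,
family, order, class) and environmental category *e*,

    MHI(e) = 100 · N_c(e) · log(R_total / R(e)) / Σ_e' N_c(e') · log(R_total / R(e'))

- `N_c(e)`: significant hits labeled *e* with identity ≥ *c*. "Above" is
  implemented inclusively (≥): the species convention treats a 97.0% hit
  as species-level, and boundary ties should count.
- `R(e)`, `R_total`: per-category and total reference sizes. The log
  factor down-weights categories over-represented in the reference
  (inverse document frequency); the log base cancels in the normalization
  (property-tested), natural log is used.
- Each emitted column sums to 100%. A column with no hits is omitted
  entirely rather than emitted empty.
- Degenerate case: if every hit category spans the whole reference,
  all weights are log(1) = 0. Rather than divide by zero, the column is
  flagged `degenerate` with empty percentages and a warning. A realistic
  multi-category reference never triggers this.
- Categories under a 1% floor are merged into *other* for presentation;
  totals are preserved and the JSON keeps the member list.

**Hit ranking.** Hits passing the e-value ceiling (default 1e-10) are
capped at the 10,000 most significant, then ordered by
`matches / (hit_length + gaps_in_hit)` — matched bases over the *full*
reference length plus gap columns opened in the hit. This ratio, unlike
identity, punishes short partial hits, which is why queries should be
longer than the references (> 500 bp recommended; shorter queries get a
logged warning, not an error). The phrase "aligned nucleotides" is read as
*matched* bases and "length of the hit sequence" as the full reference
length; the alternative readings (all aligned query bases; aligned span
only) would weaken exactly the short-hit penalty the ratio exists for.
Identity for thresholding is the conventional `matches / aligned_columns`,
a deliberately distinct quantity.

**Significance.** E = K·m·n·exp(−λS) with the ungapped Karlin–Altschul
constants as configurable approximations (λ = 0.625, K = 0.41 for the
default +2/−3/5/2 scoring). No edge-effect or gapped recalibration is
attempted; at desk scale the e-value only acts as a permissive
significance gate, and the tests treat it as such.

**Alignment.** Affine-gap Smith–Waterman (via Biopython's C
`PairwiseAligner`), both strands, better strand reported. Candidate
subjects are prefiltered by a shared canonical 12-mer; on stores where
seeds exist this is provably equivalent to exhaustive search (tested
against an all-pairs oracle), the only documented exception being a
subject sharing no 12-mer with the query — which could not reach the
e-value gate anyway.

**Collective mode.** For multiple queries (e.g. the 16S copies of one
genome) the primary mode sums per-environment hit counts across queries
per threshold, then computes one MHI column. An alternative mean mode
averages per-query percentages instead. Both are exposed
(`--collective {sum,mean}`) because either reading of "summed counts" vs
"averaged MHIs" is defensible; summing is primary since it degrades
gracefully when some queries lack a column. For identical queries the two
agree (scale invariance of the normalization, tested).

## 2. Reference construction

Per environmental category:

1. **QC** (order fixed): 3′ quality trimming at Phred < 20 → 3′ adapter
   removal → discard of reads containing non-ACGT characters → truncation
   at the first homopolymer run ≥ 5 bp. After *each trimming stage*, reads
   shorter than 200 bp are removed and charged to that stage; reads
   without Phred scores are removed at stage 1. Quality trimming is
   suffix-only (pyrosequencing error accumulates at the 3′ end; 5′
   trimming would complicate the prefix-anchored steps downstream for no
   benefit). Adapter matching is 3′-anchored with ≤ 10% mismatches over
   ≥ 3 bases of overlap and iterates to a fixpoint, making it idempotent.
   "Removal" of ambiguous reads is whole-read discard, not N-trimming.
2. **Duplicate removal (99%)**: greedy, longest-first, ties broken by id.
   A read joins the first cluster whose representative it matches as a
   5′-anchored near-prefix at ≥ 99% identity over the shorter read.
   Prefix anchoring reflects how artificial duplicates arise: re-reads of
   one molecule from a fixed primer, differing mainly in length and
   sequencing error.
3. **rRNA screen**: keep a read iff the best screening sequence shares
   ≥ 20% of the read's canonical 15-mers. For an on-target read with
   error rate ε, the expected shared fraction ≈ (1−ε)^15 (0.83 at ε = 1.2%,
   0.63 at 3%), while an unrelated sequence shares ≈ 0; the 0.2 floor
   sits far from both. This is a desk-scale stand-in for a dedicated rRNA
   predictor with an external index, not a re-implementation of one.
4. **Chimera removal**: see §3.
5. **OTU clustering (97%)**: greedy centroid clustering, longest-first;
   identity is `matches / alignment_columns` of the best local alignment,
   and the alignment must cover ≥ 90% of the shorter sequence (prevents
   tiny-overlap joins). Equivalent, on small inputs, to an oracle that
   scores every pair by full dynamic programming and applies the same
   greedy rule (tested).

Cluster representatives become `env.1 … env.R(e)`; categories whose reads
are all filtered out are omitted with a warning (the reference invariant
requires at least one entry overall). Headers are parsed by splitting on
the *last* dot, so category names may contain spaces and dots.

## 3. Chimera detection

PCR chimeras are two-parent crossovers. The detector is reference-free:
candidate parents are the duplicate-removal representatives backed by ≥ 2
members (abundance proxy — chimeras form *from* abundant molecules, so a
chimera is compared against sequences more abundant than itself).

Because reads are 5′-anchored, segments are compared ungapped and
position-aligned. For every breakpoint on a fixed grid (every 10 bp,
excluding 50 bp at each end) and every ordered candidate pair (A left,
B right):

- the two-parent model's identity is computed over the column horizon the
  pair can explain (min of read length and B's length; columns a parent
  does not cover count as unexplained);
- it is compared against the best *single* candidate over the same
  horizon. Matching horizons is essential: comparing models that explain
  different column sets rewards coverage, not chimerism.

A read is called chimeric when the best admissible two-parent model beats
the matched single-parent model by `chimera_min_improvement` (default
0.02). Admissibility encodes "the two parents differ":

- parents must mutually diverge by ≥ 2 × the margin over their shared
  prefix — two noisy reads of one template are not distinct parents;
- each flank needs ≥ 3 decisive columns (read matches that flank's parent
  but not the other, where both cover) with yes-votes outnumbering
  counter-votes 2:1 — positive evidence on *both* sides of the breakpoint,
  in the spirit of UCHIME's vote heuristic.

Without the first guard, combining two same-template reads whose errors
lie on opposite halves fakes an improvement; without the second, stitching
a short same-template candidate to any long candidate wins on coverage
alone. Both failure modes were observed on synthetic corpora and are
exercised by the tests. The detector is a deliberately simplified stand-in
for UCHIME and is not expected to reproduce its calls.

Limitations: a chimera whose parents are not both represented among the
abundant candidates cannot be flagged (shared with any reference-free
detector); breakpoints within 50 bp of either end are invisible by
construction.

## 4. The synthetic world

The generator states a small amplicon survey and is the fixture for every
recovery test:

| parameter | default | rationale |
|---|---|---|
| environments × templates | 2 × 5 | smallest world where cross- and within-category structure both exist |
| template length | 1,200 bp | full-ish 16S gene |
| template divergence | 10% | all template pairs sit well across the 97% species boundary |
| reads per environment | 100 | two-environment corpus of 200 reads |
| read length | 250–450 bp | the real corpora this emulates average ≈ 350 bp with a 200 bp floor |
| read error | 1.2% substitutions | 454-scale; keeps same-template read pairs (≈ 2.4%) above the 1% dedup radius and below the 3% OTU radius |
| duplicates / chimeras / ambiguous / short | 25% / 5% / 5% / 5% | duplicates are the dominant amplicon artifact; chimera rate at the low end of the reported 5–45% range |
| quality profile | Phred 38 body, 19→10 over a 50 bp tail | the tail is strictly below Q20, so the trimmer removes exactly the tail and the planted read body is recovered deterministically |

Design choices that make truth recovery exact rather than probabilistic:

- **5′-anchored reads** (fixed forward primer): makes prefix dedup and
  position-aligned chimera segments faithful to their models.
- **Grid-jittered substitutions**: each read receives exactly
  `round(rate·len)` substitutions, one per equal-width bin. Divergences
  concentrate at their nominal values instead of fluctuating binomially,
  so the 99% / 97% thresholds separate cleanly. `generate_query` keeps
  per-position Bernoulli mutations, where binomial spread is the point.
- **No homopolymer runs ≥ 5 bp** are ever generated (runs capped at 3
  during sequence generation and mutation; chimera junctions re-drawn if
  a run forms): the homopolymer filter then fires only on planted
  content, keeping per-stage accounting exact.
- **Chimera parents are duplicated templates** (abundance-driven chimera
  formation), guaranteeing both parents have abundance-proxy candidates;
  chimeras are drawn from the lower half of the length range (aborted
  extension products skew short), keeping them within their parents'
  reach. Parents are always from the *same* environment, so chimera
  removal cannot alter category composition.
- All randomness flows from one integer seed; re-runs are byte-identical
  (tested).

What the generator does **not** emulate: flowgram-specific 454 error
models (indels at homopolymers), phylogenetically realistic evolution
(templates form a star around one ancestor — one visible consequence:
between-category and within-category template distances are equal, so
low-threshold columns split evenly), chimeras with more than two parents,
quality-dependent substitution rates, and paired-end structure. A green
recovery test therefore establishes that the pipeline inverts *this*
generative model exactly; it does not certify behavior on real 454 data.

## 5. Numerical and policy choices

- Thresholds are inclusive (≥) everywhere: dedup, OTU, rRNA floor, MHI
  identity levels, e-value ceiling.
- Greedy clustering order is longest-first with lexicographic id
  tie-break; output is deterministic and order-independent of the input.
- Ties in hit ranking break by e-value ascending, then (env, ordinal) —
  a total, reproducible order.
- FASTQ is Phred+33 only; records without qualities are rejected at QC
  stage 1 rather than silently passed.
- Sequences are uppercased with U→T on input; `N` survives parsing and is
  handled by the ambiguity filter.
- The 10,000-hit cap is applied at search time (before identity
  thresholding), so every MHI column draws from the same significant-hit
  pool.
- Reported percentages: two decimals in text output, full precision in
  JSON/CSV.

## 6. Known limitations

- The e-value constants are ungapped approximations; absolute e-values
  should not be compared against other tools'.
- Dedup assumes 5′-anchored duplicates; shotgun-style duplicates starting
  at random offsets would not be merged.
- The chimera detector's grid and end-exclusion make short reads
  (< ~120 bp) effectively untestable — irrelevant after the 200 bp floor.
- `build_reference` holds each environment's reads in memory; the
  intended scale is desk-size corpora, not archive-scale runs.
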