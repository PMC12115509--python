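# Methods

This note documents the models, conventions and numerical choices behind
`mpact`, and what the synthetic-data tests do and do not demonstrate.

## Pairwise alignment and percentages

Global alignment uses the three-state affine-gap (Gotoh) dynamic program.
A gap run of length L costs `gap_open + (L−1)·gap_extend`; defaults are
10.0 / 0.5 with **end gaps unpenalized**, matching the defaults of the
EMBOSS needle program, the de-facto standard for all-against-all pairwise
comparison in virus-demarcation tools. Both conventions are configurable
(`end_gaps_penalized=True` switches to true global scoring).

Percentages are computed over the **full alignment length including gap
columns**: identity counts exact residue matches; similarity counts columns
with two non-gap residues whose substitution score is positive. Identity ≤
similarity holds for all bundled matrices because their self-scores are
positive; it is not asserted for arbitrary user matrices.

Traceback ties are broken deterministically — diagonal > up (gap in the
second sequence) > left — so outputs are bit-stable across runs and
platforms. The DP kernel is compiled with numba; its correctness is checked
in the test suite against exhaustive enumeration of the alignment space
(short pairs) and against an independent aligner implementation.

Substitution matrices: BLOSUM62 for proteins and EDNAFULL/NUC.4.4 for
nucleotides (via Biopython), extended so every alphabet character is
scored: U→C, O→K, and J as the elementwise minimum of the I and L rows
(minimum keeps the extension symmetric and conservative); nucleotide U
scores as T. The 3Di structural-alphabet matrix is the one published with
the Foldseek structural-search method, loaded from biotite's bundled copy;
`SubstitutionMatrix.from_emboss_file` lets users override any matrix with a
standard EMBOSS/NCBI-format text file. 3Di alignments use the same gap
defaults (10.0 / 0.5).

Strict alphabet validation is the default; a `permissive` flag maps unknown
residues to N/X instead, because silently coercing characters corrupts
similarity scores.

## Maximum-likelihood distances

The `ml_distance` matrix has two modes:

* **Pairwise mode** (self-contained default): for each pair of MSA rows,
  the distance is the t ≥ 0 maximizing the log-likelihood of the observed
  site patterns, by bounded scalar optimization on [0, 10] to 1e-6.
  Columns with a gap or ambiguity code in *either* row are excluded
  pairwise (not listwise), which maximizes the usable signal per pair.
  Saturated pairs are capped at t_max = 10 substitutions/site with a
  warning — unbounded optimization diverges once the observed divergence
  reaches the model's saturation point, which highly divergent datasets
  will hit.
* **Patristic mode**: with an externally inferred tree (e.g. from a
  maximum-likelihood phylogenetics program run on the same MSA), the matrix
  entry is the sum of branch lengths on each leaf-to-leaf path. This
  reproduces the tree-based definition of pairwise ML distance exactly when
  the user supplies such a tree; both readings of "ML distance matrix" are
  therefore available.

Models: JC69 and K80(κ) for nucleotides; Poisson and an equal-input model
with WAG stationary frequencies (`WAG_F`) for proteins. All rate matrices
are normalized to mean rate 1 so t is in expected substitutions/site, and
P(t) = exp(Qt) is computed from a one-time eigendecomposition of the
reversible generator. Model selection is out of scope: the model is a user
choice (JC69/Poisson defaults).

The progressive aligner included for self-contained runs builds a UPGMA
guide tree on k-mer distances (k = 3 amino acid, 6 nucleotide) and merges
profiles with the same affine DP on expected-score columns. End gaps *are*
penalized in profile merging: with free ends, two dissimilar profiles
collapse into a fully staggered all-gap merge. It is deliberately minimal —
an external MSA should be preferred whenever available.

## Structure comparison

Superposition is the closed-form SVD (Kabsch) solution with the reflection
guard (det = +1). TM-score uses the standard distance scale
d₀(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å, and is normalized by the
**average** of the two chain lengths, rounded half up — this makes the
all-against-all matrix symmetric by construction, so each unordered pair is
computed once.

`align_structures` is an iterative heuristic in the TM-align family:
initial candidates are gapless threadings at every offset (top 5 by
initial TM) plus half-length fragment superpositions at three anchor
positions; each candidate is refined by iterating {superpose on current
pairs → all-against-all Cα distance matrix → NW DP on the similarity table
1/(1+(d/d₀)²) with gap penalty 0.6 and free end gaps → new pairs} until the
pair set repeats or 30 iterations. The reported score additionally
maximizes TM over superposition subsets of the final pairing (seed
fragments of decreasing length with distance-cutoff extension), as the
TM-score convention requires. Alignment is sequential (order-preserving)
only; circular permutations are not searched. Secondary-structure seeding
and multimer logic are out of scope.

PDB input: Cα atoms of MODEL 1, first chain by default; alternate
locations resolve to the highest-occupancy conformer (ties → altloc 'A');
insertion-coded residues count as distinct residues. These are the common
single-conformer conventions.

## Trees, clustering, partitioning

* **Neighbor-joining** (Saitou–Nei) with the deterministic tie-break
  "smallest (i, j) index pair" on Q-matrix minima. Negative branch-length
  estimates are clamped to 0 with the deficit moved to the sibling edge so
  their sum is preserved — standard practice, but note it perturbs
  patristic round-trips on non-additive input (on additive input NJ is
  exact to 1e-9, which the tests quantify over random trees).
* **UPGMA** for display clustering: average linkage, node heights = half
  the merge distance, ties broken by the lexicographically smallest pair of
  cluster representative labels.
* **Midpoint rooting** places the root halfway along the longest
  leaf-to-leaf path (ties: lexicographic leaf pair); if the midpoint falls
  on a node the tree is rooted there. All-zero branch lengths trigger a
  warning and an arbitrary rooting.
* **Ladderization** sorts every node's children by ascending subtree
  height (max root-to-leaf length within the child), ties by smallest leaf
  label. Height — rather than the child's own edge length — is the reading
  that yields a deterministic leaf order usable for partitioning; an
  edge-length key can be selected in the pipeline config.

Partitioning converts the metric to distances ((100−v)/100 for
percentages, 1−v for TM, identity for ML distance), builds the
midpoint-rooted ladderized NJ tree, and walks clades root-down: a clade is
emitted as a cluster iff *all* pairwise metric values among its leaves lie
within the inclusive bounds and its parent clade's do not; uncovered leaves
become singletons. Values are rounded to 4 decimals before comparison to
avoid float-boundary flapping. Clade extraction is deterministic and
robust to input order; the alternative reading — maximal qualifying runs
of the ladderized leaf order — is available as `mode="runs"` for
comparison, and the two can give different cluster counts on borderline
data. With fewer than 3 records NJ is impossible and the engine falls back
to threshold-only grouping with a warning. The within-cluster bound
invariant is re-verified by assertion on every run.

## Visualization

Heatmaps are ordered by the ladderized UPGMA tree of the
distance-converted matrix on both axes, with the dendrogram drawn above
and exported as Newick; the leaf order shown equals the ladderized UPGMA
order (asserted in tests). Color anchors are fixed per metric (0–100 for
percentages, 0–1 for TM, 0–data-max for ML distance; warm = similar) so
figures are comparable across runs; anchors are config-exposed. Frequency
plots bin the upper-triangle values (default widths 5 percentage points,
0.05 TM, 0.25 substitutions/site) into left-closed bins, last bin closed,
and draw count vs bin midpoint.

## Synthetic data: what it shows and what it does not

`simulate_family` evolves a root sequence down a random bifurcating
ancestor topology (exponential branch lengths rescaled so the *closest*
ancestor pair sits at `inter_divergence`, guaranteeing at least that much
between-group separation) and then attaches `seqs_per_group` tips at
`intra_divergence/2` per branch, under JC69 (nt) or Poisson (aa). Defaults
— 3 groups × 4 sequences × 300 sites, intra 0.1, inter 1.0 — represent a
family-level demarcation problem: within-group similarity in the 90s,
between-group similarity well below 40%. There is **no indel process**, so
the true alignment is the identity column map; fixtures exercise
substitution-driven divergence, not alignment uncertainty. Consequences:
passing the planted-partition tests shows the metric → tree → partition
chain recovers clean group structure; it does not show robustness to
gappy, length-variable real sequence families, nor to rate heterogeneity
across sites (no +G/+R models).

`simulate_structures` builds an ideal α-helical Cα trace (rise 1.5 Å,
radius 2.3 Å, 100°/residue) with isotropic Gaussian noise and optional
terminal deletions with the true pairing recorded. It validates
superposition and the TM machinery with known correspondences; it does not
emulate domain motion, topology changes or realistic protein folds.

All generators are bit-reproducible from (spec, seed).

## Problem sizes

The acceptance script and test suite run at desk scale, chosen to exercise
every code path with exact or tight oracles: 200 enumeration-checked
alignments (length ≤ 6, where exhaustive enumeration is feasible), a
70-point closed-form grid for JC69, 100 random additive matrices (n ≤ 12)
for NJ, 45-residue chains for TM checks, and a 12×250-residue planted
family for end-to-end partition recovery. Larger datasets run through the
same code paths via the CLI.

## Known limitations

- Pairwise-mode ML distances ignore among-site rate variation and shared
  ancestry between pairs; they are not substitutes for full phylogenetic
  inference.
- The progressive aligner has no iterative refinement and will not match a
  dedicated MSA program on divergent data.
- The structural aligner's seed set can miss the optimal alignment for
  repetitive or multi-domain structures (TM-score is reported for the best
  alignment found).
- Cluster counts from bound-based demarcation depend on the partition-mode
  reading (clades vs runs) for borderline clades; both modes are exposed.
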