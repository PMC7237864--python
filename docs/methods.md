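# Methods

This note documents the models and procedures implemented in `embryostrat`,
their assumptions, the parameters that matter, and the design choices made
where the methodology was genuinely open.  All empirical statements below
are properties that the test suite or `scripts/acceptance.py` computes.

## Data model and shared transforms

Expression lives in an `ExpressionMatrix` (cells × genes) with an explicit
unit tag (`raw_counts`, `rpm`, `log2rpm`, `zscore`); each operation states
the unit it expects, so transforms are applied exactly once and in one way.
Pseudocounts are implemented by **clipping at 1 RPM, never by adding**, so
zeros map to exactly 0 on the log₂ scale; all logs are base 2.  Sample
variance uses the n−1 denominator (unbiased on small embryos).  On disk,
tables are genes × cells (common supplementary-table layout) and are
transposed to cells × genes in memory.

## Normalization

Two multiplicative steps, each a single count-independent scalar per cell:

1. **Coarse**: each cell scaled so its total is 10⁶ reads (RPM).
2. **Fine**: constitutive genes are those with minimum expression > 64 RPM
   over all cells; each cell's factor is 2^(−offset), where offset is the
   median over constitutive genes of log₂(cell) − log₂(reference).  The
   median makes the estimate robust to a minority of genuinely regulated
   genes; a mean (least-squares) variant is available.  Pairwise matching
   is anchored to one reference cell (the cell with the median total) — an
   all-pairs consensus would be equivalent up to a global scale at O(n²)
   cost.  Fine factors are applied last; totals are not re-normalized
   afterwards.  The step is idempotent to machine precision.

## Maternal-factor detection

Before zygotic genome activation, expression differences between cells of
one embryo can only come from selective inheritance or degradation of
maternal mRNA, which (i) affects an even number of cells in a bilaterally
symmetric embryo and (ii) is reproducible across embryos.  The detector:

* candidate genes: max > 16 RPM in at least one cell, ≥ 4-fold between
  cells (after clipping at 1 RPM);
* per gene, cells are rank-ordered in log₂ expression and split at the
  single largest consecutive difference (ties broken toward the smaller
  high set, logged);
* **even-sampling rule**: the *minority* category must contain at least one
  cell from every embryo, and the completeness-rescaled per-embryo counts
  may spread by at most 1.  Applying the rule to the minority side is
  essential: a spread-only rule admits single-outlier splits (one noisy
  cell in one embryo), which are exactly what reproducibility across
  embryos should exclude;
* genes are grouped by their exact high set; the largest agreeing group is
  the classifier set and its shared high set the singled-cell set.  The
  probability that independent genes single out an identical k-subset of n
  cells by chance is Σ_k 1/C(n,k), computed exactly in arbitrary-precision
  integers;
* the co-segregation screen then returns genes whose mean clipped-log
  expression is higher in the singled cells than in the rest in *every*
  embryo (log-scale means, consistent with the module's clipping).

## SCECTION (recursive consensus NMF)

Each embryo is bipartitioned recursively.  At a node with cell subset S:

1. genes with max > 4 RPM in S and ≥ 16-fold range within S (clipped at
   1 RPM) are selected; an empty set terminates the node;
2. expression is clipped, log₂-transformed and z-scored over S; because
   NMF needs non-negative input, each gene is then shifted by its minimum
   over S — a rank-preserving per-gene offset (a flag factorizes clipped
   log values without z-scoring instead);
3. 50 two-metaprofile NMF runs (multiplicative updates, random uniform
   init, per-run seed = base seed + run index, ≤ 500 iterations, relative
   tolerance 10⁻⁶).  Each run assigns cells to the metaprofile with the
   larger coefficient; co-assignment indicators average into the consensus
   matrix.  Degenerate runs (an empty metaprofile) are re-initialized, with
   a hard failure after 10× the requested runs;
4. the final 2-cluster call is average-linkage clustering of
   (1 − consensus); the split is accepted only if the mean within-cluster
   consensus exceeds 0.75, and each side recurses (minimum subset size to
   attempt a split: 3 — a pair cannot be meaningfully consensus-split).

**NMF objective.** The default objective is the generalized
Kullback-Leibler divergence of the classic consensus-NMF formulation.  On
cleanly block-separated subsets the Euclidean (Frobenius) multiplicative
updates converge, from most random initializations, to a local optimum that
splits the *dominant* block and leaves a small block (e.g. the two
maternal-factor-rich germ cells) unmodelled, collapsing the consensus; the
KL updates recover the planted split from essentially any initialization.
Frobenius remains available (`beta_loss="frobenius"`).

**What the consensus score does and does not detect.** The score measures
stability across random initializations on *fixed* data.  A pure-noise
matrix still has a well-defined leading sample direction, so k = 2 runs can
agree and the score is not a significance test: in simulations
(12 cells × 100 z-scored noise genes) the median score over seeds falls
below 0.75, but individual noise datasets can score high.  The practical
guards against over-splitting are the 16-fold differential-gene filter and
the minimum subset size; the consensus score degrades monotonically as
planted separation shrinks (tested), and rejects the ambiguous
intermediate regime.

**Cross-embryo matching** computes per-embryo, per-type mean log profiles
*on the classification-associated genes* (the union of split genes recorded
in the partitions; matching on all genes lets thousands of standardized
noise genes swamp the informative distances), standardizes each gene across
the embryo's type profiles (removing embryo-specific trends), clusters all
(embryo, type) profiles by average linkage and cuts at the largest
per-embryo type count.  A canonical type supported by a single embryo is
merged back into its sibling from the last split, and matching repeats.

**Classifier validation** compares each candidate gene's rank-gap
bipartition with a reference bipartition (e.g. maternal-high cells) in a
2 × 2 χ² test (Fisher's exact test when any expected count is below 1,
flagged), Benjamini-Hochberg corrected; both the association direction and
the surviving genes are reported, since the biological criterion can be
read as either association or difference.

## Lineage tree

Between consecutive cleavage stages every cell divides once, so daughter
cell counts must sum to twice the mother's.  Profiles are per-stage,
per-type mean log₂ values, standardized per gene across the stage's types
(removing stage trends); when a bulk stage × gene table is available, genes
are first restricted to the union of the two stages' developmental filters
(max > 1 RPM and ≥ 2-fold change against the 4-cell baseline).  This
restriction matters: without it, distances between standardized profiles
are dominated by genes whose between-type variance is pure noise.
Matching is greedy under the doubling budget: mothers are processed
most-confident-first (smallest distance to any daughter), each accumulating
its closest unclaimed daughters until the budget is exactly met; daughters
that would overshoot are skipped; equidistant options fall back to
lexicographic type order (logged).  The transcriptionally silent germ
lineage is carried through the tree by its maternal-factor signature.  The
assembled tree validates the doubling invariant exactly at every node and
exports to Newick (labels quoted as `stage:type:n`) and JSON.

Individual cells embed on local lineage axes: the progression coordinate is
the scalar projection of (cell − mother mean) on the unit mother→daughter
direction (optionally normalized so the daughter mean is 1); the second
coordinate is the normalized rank along a greedy nearest-neighbour chain
through the type's cells.

## Embryonic axes

PCA is computed per embryo on clipped-log profiles of genes with a ≥ 4-fold
within-embryo range.  The two leading components span the anatomical axes
but mix them; the pooled within-pole covariance matrix of the leading
coordinate pair (poles = the embryo's first consensus split) is
diagonalized, which is the minimal in-plane rotation nulling the
within-pole covariance.  Because the nulling rotation is defined only up to
a 90° swap, the rotated axis with the larger standardized between-pole
separation is designated axis 2 (the animal-vegetal pole axis), the other
axis 1 (the anterior-posterior trend).  Orientation is fixed by convention:
a designated anchor type (the posterior reference) sits negative on axis 1
and pole 0 positive on axis 2.  Axes remain orthonormal; the stored PCA
spectrum is non-increasing, and per-axis projection variances are kept
separately since rotation can reorder variance within the pair.  Cells from
later stages and type-mean profiles are projected into the same space;
types with flat profiles (silent lineages) are flagged unmappable.  Finer
axes are built from sister-type classifier directions (normalized mean
difference) plus the leading residual direction, which is orthogonal by
construction.  Cross-embryo sign harmonization maximizes loading
correlation with a reference embryo; the colinearity report includes the
closed-form null probability P(|cos| ≥ c) from cos² ~ Beta(1/2, (d−1)/2)
for random unit vectors in d dimensions (verified against Monte-Carlo).

## RNA velocity

Constant-rate model: v = u − γs with u unspliced and s spliced abundance on
a common per-cell scale.  γ is the through-origin least-squares slope of u
on s over the cells in the top decile of spliced expression (ties at the
boundary included; at least 10 expressing cells for a decile, else all
expressing cells down to a minimum of 3; genes below that are skipped and
flagged).  Through-origin is implied by the steady-state relation u ≈ γs.
Extrapolated abundance s_ext = s + v/γ = u/γ; γ = 0 leaves the
extrapolation undefined (flagged).  Neither genes nor cells are pooled.
Arrows in an embedding run from the projected spliced profile to the
projected extrapolated profile after the standard clip-at-1 log transform;
genes without a valid extrapolation contribute zero arrow length.  The
identity v = u − γs is audited on every fit.

## Noise and timing

* **CV analysis**: per embryo, genes with max > 16 RPM in that embryo get a
  CV across its cells; the reference is the mean CV over 100 random
  samplings of equally many cells from all same-stage embryos.  A
  within/across ratio below 1 means individual embryos are internally more
  uniform than the stage pool.
* **Markers**: genes with max type-mean > 4 RPM and ≥ 4-fold between high-
  and low-expressing type groups (rank-gap split on clipped type means —
  reusing the maternal operator for determinism).  Per category the report
  gives the fraction of cells with detectable expression (> 0 RPM by
  default, configurable) and the median level among expressing cells,
  separating on/off (Boolean) control from level control.
* **Coordination**: genes upregulated > 4-fold mother→daughter are rescaled
  per gene to mother mean 0 / daughter mean 1; cells and embryos sort by
  summed rescaled level; per-embryo type scores are correlated between type
  pairs with an embryo-label permutation null (exact enumeration when the
  embryo count allows, else 1000 draws; add-one correction), two-sided.
* **Temporal model**: x_ij = α_i · max(t_j − t0_i, 0) with α_i ≥ 0, fitted
  by alternating least squares on expression pre-normalized to mother mean
  0 / grand-daughter mean 1.  Given times, each gene's (α, t0) has a closed
  form per active-set segment: an unconstrained line fit on the active
  cells with the onset at the line's root, clamped into the segment.  Given
  gene parameters, each cell time is the exact minimizer of its piecewise
  quadratic objective over the onset-defined segments.  Iteration stops at
  relative improvement < 10⁻⁶ or 200 rounds (non-convergence returns the
  best iterate, flagged).  The likelihood is invariant under affine time
  maps; the gauge is fixed afterwards by mean(t) = 0 and mean(α) = 1.
  Identifiability caveat: cells captured before every onset are silent in
  all genes and their times are unconstrained (tests compare only
  identifiable cells); noiseless realizable data are recovered to machine
  precision.

## Geometry scores

Relative apical surface is normalized by the cell's own total surface
(dimensionless, bounded in [0, 1]; the denominator is a modeling choice —
per-embryo or per-group normalizations would not be bounded per cell).
Cadherin contact strength is Σ_j min(C_i, C_j)·l_ij over apical neighbours,
with C on the RPM scale (the score multiplies a physical length; the min
models homophilic binding, making the score monotone in any neighbour's
expression).  The sister-volume formula v₁/v₂ = (x₀ − x₂)/(x₁ − x₀)
follows from conservation of maternal RNA mass through division,
x₀(v₁+v₂) = x₁v₁ + x₂v₂, and holds for any partition bias; negative ratios
are inconsistent with conservation and rejected.  A multi-gene version
reports per-gene ratios and their median.

## Synthetic embryos: what is emulated, and what is not

The generator plants a fixed bilaterally symmetric lineage tree (2 → 64
cells; at 16 cells: 5 types of 4+4+4+2+2; 8 types at 32; 14 types at 64),
with a transcriptionally silent germ lineage that inherits the 10 maternal
factors and divides volume-asymmetrically (sister ratio 3 by default; the
maternal pool has constant total mass per embryo, so concentrations scale
inversely with carrier volume).  Zygotic type markers (5 per type, log₂
fold 4 relative to the 1 RPM floor) ramp linearly in log space after a
per-gene onset and saturate at 1.5× the fold; animal/vegetal pole programs
(25 genes per pole) make the pole contrast the dominant one, as the first
consensus split of real embryos requires; 20 maternally deposited
AP-graded transcripts (amplitude 1.5 log₂ per AP unit) give every cell,
including the silent germ cells, a position signature.  Marker-negative,
non-silent cells express each marker spuriously in 10 % of cells at a
tenth of the on level.  The library is filled to ~10⁶ RPM with 200
constitutive and 1500 background genes.

Noise has four layers: log-normal biological noise (SD 0.5 log₂ for
regulated genes, 0.25 for constitutive/background — housekeeping genes are
empirically much less variable than developmental ones, and equal noise
would fabricate 16-fold splits inside pure types), per-(embryo, gene)
oocyte-deposition offsets (SD 0.2 log₂, the source of the within < across
CV signature), negative-binomial counts (dispersion 0.1) at 3 × 10⁶ reads
per cell (deep enough that technical zeros are negligible, matching the
data regime the methods assume), and per-cell depth factors log-uniform in
[0.5, 2].  Per-embryo timing offsets (uniform window 0.3 cleavage units)
shift all zygotic ramps coherently.  Unspliced counts follow u = γs
(γ log-uniform in [0.02, 0.5]) except during a gene's ramp, where u is
doubled.  Cells come in bilateral pairs with identical expected profiles;
with all noise switched off the generator is exactly deterministic and
pair-symmetric.

Two documented configuration variants express different planted designs:
the axis-recovery analyses use a gradient-dominant embryo (60 AP-graded
genes, amplitude 3.0) in which anterior-posterior variation dominates
within-pole variance, as the recoverability of the axes presupposes; the
coordination analyses use a wider timing window (0.5) and 12 embryos per
stage, since with few embryos a real shared clock cannot clear a 0.01
permutation threshold.  Typing, lineage, maternal, velocity, noise and
normalization analyses all run on the defaults.

What the generator does **not** emulate: empirical mean-variance
relationships of real protocols, batch effects, allele-level polymorphism
(allele collapsing is accepted as an optional input map but never
inferred), realistic 3-D geometry beyond scalar measures and a ring-shaped
apical contact graph, and continuous developmental trajectories within a
stage beyond the linear ramp model.  Passing planted-truth tests therefore
demonstrates algorithmic correctness under the stated statistical
assumptions, not performance on any particular real dataset.

## Problem sizes

Test and acceptance runs use desk-scale conditions chosen as scaled-down
study designs: 1-4 embryos per stage for typing (20 independent seeds), 3
embryos per stage for the 4/16/32/64-cell lineage series, 8 four-cell
embryos for maternal detection, 12 embryos for coordination, 100 cells per
gene for velocity, 40 cells × 20 genes for the temporal model.  The full
acceptance script completes in well under a minute.
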