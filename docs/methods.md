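# Methods

This note documents the models, statistics and numerical choices behind
`ppl`, and what the synthetic data generator does and does not emulate.

## The analysis problem

A combined molecular + morphological study of a large plant group
produces several partially overlapping data blocks: per-marker sequence
alignments, a binary morphological matrix scored for (nearly) all
species, a small morphometric table measured on the sequenced vouchers,
and a working classification into sections/subgenera. The analyses this
package implements answer, in order: do the markers tell one story
(congruence)? what does the tree's diversity look like in the plane
(ordination + density)? does morphology retain that picture
(Procrustes)? which characters track the phylogeny (molecular weights)?
can morphology place species that lack DNA (k-NN placement)? and can a
classifier over morphological characters be read as an identification
key (recursive partitioning)?

## Congruence among distance matrices (CADM)

Each marker's mismatch distance matrix is vectorized over the shared
upper triangle, midranked, and Kendall's W computed with the standard
tie-correction term:

    W = 12 S / (m² (n³ − n) − m ΣT),

where S is the sum of squared deviations of the rank sums over the
n = taxon·(taxon−1)/2 pairs, m is the number of matrices and T the
per-matrix tie correction Σ(t³−t). The chi-square form is
χ² = m(n−1)W exactly (asserted to 1e-9). For m = 2,
W = (1 + ρ_s)/2 with ρ_s the Spearman correlation of the two distance
vectors — a test cross-checks this identity, and another cross-checks W
and χ² against the reference implementation in R's `ape` package.

The permutation null holds the first matrix fixed and permutes the taxon
order (rows and columns jointly) of each remaining matrix independently.
Permuting taxa only re-pairs existing distances, so each permuted rank
vector is a gather of the original one; the implementation exploits this
to evaluate tens of thousands of permutations vectorized. The p-value
uses the add-one estimator p = (1 + #{W* ≥ W}) / (B + 1), whose smallest
attainable value is 1/(B+1): 1/10001 ≈ 0.0001 at the default B = 10,000.
An `exhaustive` mode enumerates all (n!)^(m−1) joint permutations on
tiny inputs and is used as the oracle in tests.

## Ordination and density surfaces

Cophenetic distances come from the tree as path-length sums (dendropy).
Classical MDS (principal coordinates) double-centers −D²/2 and keeps the
top eigenpairs, scaling eigenvectors by √λ. Mismatch-proportion
distances are generally non-Euclidean; negative eigenvalues are dropped
with a logged warning rather than silently, and requesting more
dimensions than there are positive eigenvalues is an error. The
embedding is cross-checked against scikit-bio's PCoA in a test.

Density surfaces bin the 2-D configuration on a grid spanning the data
range padded by three bandwidths, convolve the counts with a Gaussian
kernel (`scipy.ndimage.gaussian_filter`, sigma expressed in grid cells),
and normalize to unit trapezoidal integral. The default per-axis
bandwidth is the 1-D normal reference rule h = 1.06 σ̂ n^(−1/5); the
default grid is 128×128. Degenerate (zero-variance) axes raise an error
suggesting jitter rather than producing a spike.

## Procrustes superimposition and PROTEST

Both configurations are centered and scaled to unit total sum of
squares — the convention under which the residual statistic
m₁₂² = 1 − (Σσ_i)² lies in [0,1] and is symmetric — where σ_i are the
singular values of the cross-covariance X̃ᵀỸ. The Procrustes
correlation is √(1−m₁₂²). Reflections are allowed by default (full
orthogonal group); with `allow_reflection=False` the smallest singular
value's sign is flipped when det < 0. Per-taxon residual lengths (the
overlay-plot arrows) are reported. PROTEST permutes the row assignment
of the second configuration; the batched null evaluates the sum of
singular values for all permutations with one stacked SVD. 999
permutations (the default) floor the add-one p-value at 0.001. The
statistic is cross-checked against `scipy.spatial.procrustes`, against
R `vegan::protest`, and against a grid + local-refinement direct
optimization over rotation angle.

## Character "molecular weights"

Each character is summarized as a vector of pairwise dissimilarities
(0/1 mismatch for binary states over mutually scored pairs, absolute
difference for continuous traits) and Spearman-correlated with the
matching cophenetic distances. Taxa are resampled with replacement
(bootstrap; self-pairs dropped, because a taxon drawn twice contributes
a structurally zero pair) and the median and maximum of the bootstrap ρ
distribution are reported per character, 1000 replicates by default.
Resampling taxa rather than pairs preserves the exchangeable unit; a
pair-level bootstrap would break the dependence structure of a distance
vector. Characters with fewer than two distinct observed states have no
defined ρ and are reported as missing with a warning. Because the
statistic is rank-based, it is invariant to monotone transformations of
the reference distances (tested).

Association between categorical labelings (e.g. presence of a taproot
versus section membership) uses the Pearson chi-square with the Bergsma
bias-corrected Cramér's V: φ̃² = max(0, χ²/n − (r−1)(c−1)/(n−1)) with
r̃ = r − (r−1)²/(n−1) and Ṽ = √(φ̃²/min(r̃−1, c̃−1)). Note that for a
perfectly associated square table the correction cancels and Ṽ = 1
exactly.

## k-NN placement

Distances between character rows are mismatch proportions over mutually
scored characters (pairwise deletion); gaps count as missing. Queries
overlapping no reference taxon are an error naming the query. The
predicted label is the majority among the k nearest references, ties
broken by summed inverse distance and then alphabetically; neighbor
order breaks distance ties by taxon name, so placement is fully
deterministic. k defaults to 5 (a middle odd value; leave-one-out
selection over odd 1–9 is available to callers via
`leave_one_out_accuracy`). Confidence is a character bootstrap: columns
are resampled with replacement (implemented as multinomial column
weights so one matrix product evaluates all replicates) and confidence
is the fraction of replicates reproducing the full-data label;
placements above 0.90 are flagged high-confidence. Bootstrapping
characters rather than reference taxa measures the stability of the
character signal for that query, which is the quantity of interest when
the query's characters are few.

## Recursive partitioning and key rendering

Trees are grown greedily by minimizing weighted Gini impurity. Binary
characters split on state; numeric characters split on midpoints between
sorted distinct values. Missing values follow the branch with more
scored training rows at that node (no surrogate splits — simpler and
deterministic; the same rule is applied at prediction time). Growth
stops at purity, `min_node` = 4, `min_gain` = 1% of root impurity, or
`max_depth` = 10. Ties between splits of equal gain resolve by character
name then threshold. Repeated runs exclude the union of characters used
by earlier runs, stopping early with a warning when none remain. The
rendered key assigns one couplet per internal node, numbered in
pre-order; a key-walk over the rendered text is used as an independent
oracle for the resubstitution error. Resubstitution error is reported
as-is (no cross-validation or cost-complexity pruning); it measures how
cleanly the characters separate the groups, not generalization.

## Synthetic data generator

The generator emulates the *shapes and statistical structure* the
analyses assume, not any real dataset:

- **Tree**: pure-birth (Yule) with exponential waiting times, stopped at
  the requested tip count plus one further increment, then rescaled to
  unit root-to-tip height so rates read as expected changes per unit
  height. Trees are binary, rooted, ultrametric.
- **Sequences**: Jukes–Cantor; per-branch change probability
  ¾(1 − e^(−4μt/3)).
- **Binary morphology**: symmetric two-state Markov model from a
  stationary (½,½) root; flip probability ½(1 − e^(−2λt)) where λ is the
  per-transition rate.
- **Morphometrics**: Brownian motion from a zero root; the two binary
  traits (taproot, inflorescence gaps) threshold a Brownian liability at
  zero.
- **Sections**: the rooted tree is cut into exactly k tip-disjoint
  clades by repeatedly splitting the largest current clade at its root
  (ties by the alphabetically smallest contained tip), so labels are
  monophyletic and deterministic.
- **Missing data**: cell-wise uniform injection blanks an exact
  round(f·cells) count (one random cell per row is reserved first so no
  taxon is ever blanked completely — a slight, documented deviation from
  uniformity); block-wise injection blanks whole (taxon, marker) blocks,
  keeping at least one marker per taxon, to emulate the union fill-in of
  real supermatrices. Block injection undershoots the target by at most
  one smallest-block share of the matrix.

Two preset configurations mirror the real supermatrix shapes: tall
(273 taxa; ITS2 497 bp + trnL-F 1565 bp; 18% missing) and broad
(87 taxa; COI 656, ITS2 497, rbcL 561, trnL-F 1565, matK 909 bp; 23%
missing), both with 114 binary characters, seven morphometric traits and
seven sections. Default rates (substitution 0.3/site over tree height,
character flips 0.5, Brownian σ = 1) give realistic variability: most
binary characters vary, sequence divergence sits in the 10–20% range.
Seven sections reflect the subgenus-level clades a classification of a
three-genus tribe would track.

What the generator does **not** emulate: rate heterogeneity among sites
or lineages, correlated character evolution, extinction, alignment
error, or non-clade-derived (polyphyletic) classifications. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under clean generative assumptions — not that real data are
as well-behaved.

## Numerical choices

- Neighbor joining breaks Q-criterion ties by the lexicographically
  smallest label pair; negative branch lengths are clamped to zero with
  the deficit moved to the sister edge (logged). On additive input the
  topology and lengths are recovered exactly (tested by round-trip).
- Parsimony scoring uses Hartigan's generalization of the Fitch pass
  (states attaining the maximum child-set count; changes += children −
  max count), which is exact on multifurcating trees and re-rooting
  invariant; missing states are uninformative full sets.
- All permutation tests use the add-one estimator and compare with a
  1e-12 slack so ties with the observed statistic count as exceedances.
- All generators and tests are pure functions of (config, seed); seeds
  derived from a master seed stay below 2³¹.

## Problem sizes

The analysis drivers and the acceptance script run the tall and broad
bundles at full shape (273 and 87 taxa). Bootstrap and permutation
counts are 10,000 (CADM), 999 (PROTEST) and 1000 (placement confidence)
as in the study design; character-weight bootstraps default to 1000 but
the drivers use 200 replicates, which stabilizes the median/max summary
at these matrix sizes while keeping a full run under a minute. Null
calibration uses 1000 simulations of 12-taxon matrices with 999
permutations each.

## Known limitations

- CADM's add-one p-value is mildly conservative at small permutation
  counts (visible as a size slightly below 0.05 in the calibration run).
- Mismatch-proportion distances are non-Euclidean; the 2-D principal
  coordinates keep only part of the signal, and the dropped negative
  eigenvalues are only reported in logs.
- The morphometric table simulates the seven standard traits only, and
  binary liabilities are thresholded independently per trait.
- Resubstitution error understates out-of-sample error; the key builder
  deliberately performs no pruning.
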