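# Methods

## Model

Each group's network is a linear-Gaussian Bayesian network over d = 8
continuous variables (mean gray-matter volumes of the default-mode-network
regions PCC, mPFC, lHP, rHP, lIPC, rIPC, lITC, rITC). Given a DAG G with
parent sets π_j, the joint density factorises node-by-node,

    p(x) = ∏_j N( x_j | b0_j + b_j' x_{π_j}, σ²_j ),

i.e. every conditional is Gaussian with a mean linear in the parents and a
constant residual variance. The model assumes (i) joint Gaussianity of the
volume vector within group, (ii) independent subjects, and (iii) that a DAG
factorisation is an adequate description of the covariance structure — the
orientation of an individual edge is identified only up to the Markov
equivalence class (same skeleton and colliders), a fundamental limit of
likelihood-based learning from observational Gaussian data, so edge
directions should be interpreted with corresponding caution.

### Estimation

Parameters are maximum likelihood per node family: least-squares
coefficients, intercept, and residual variance with the MLE denominator n
(not n − k; the structure score below is a maximised log-likelihood).
Volumes are z-scored within group (n − 1 sd) before fitting, so
coefficients are standardized weights in roughly (−1, 1); a single-parent
weight equals the parent–child Pearson correlation. The transform is stored
on the fitted network and re-applied to any new subject it evaluates.
Reported coefficient standard errors are conventional OLS ones (unbiased
variance denominator); they are reporting aids and play no role in scoring.

### Structure score and search

Structures are compared with the decomposable BIC,
`Σ_j [L_j − (k_j/2) log n]` with k_j = |π_j| + 2 counting intercept, parent
coefficients and residual variance. Counting the variance keeps k_j
symmetric under edge reversal, so Markov-equivalent DAGs score identically
(verified to 1e-6 in the tests over all 3-node equivalence classes).

Search is greedy hill climbing from the empty graph over single-edge
additions and removals (reversal available, off by default), accepting the
best acyclicity-preserving move until no move improves the score by more
than 1e-9. Near-equal improvements (within that tolerance) are treated as
ties and broken deterministically — move type add < remove < reverse, then
the lexicographically smallest (parent, child) name pair. This matters in
practice: the two orientations of a fresh edge improve the score *equally*
by score equivalence, and letting float noise pick the orientation
occasionally strands the climber in the wrong equivalence class, after
which add/remove moves cannot recover.

Greedy search from a single start can still end in a local optimum that
keeps spurious "covering" edges (observed as skeleton precision dips on
some replicates while recall stays at 1.0). Full-cohort analyses therefore
run the climber with 20 seeded random restarts and keep the best score; the
`SearchConfig` default remains a single deterministic run. An exhaustive
enumeration of all labelled DAGs (25 at d = 3, 543 at d = 4) is provided
for d ≤ 4 and serves as the search oracle in the tests.

Family scores are computed from the centred cross-product (Gram) matrix, so
a candidate parent set costs O(|π|³) independent of sample size, and are
cached by (child, parent set); results are identical with the cache on or
off.

## Group comparison

One network is learned per group. The weight table lists every directed
edge of either network with both weights and a category: I (present in
both), II (group a only), III (group b only), IV (present in both skeletons
with opposite orientation).

Weight differences are tested by label permutation: group assignments are
shuffled with group sizes preserved exactly, and the complete per-group
procedure — standardize within group, re-learn the structure, re-fit — is
re-run per permutation. Re-learning (rather than refitting fixed
structures) is the default because the observed models were themselves
structure-learned; pinning the structures would understate the null
variance. A fixed-structure fast mode exists for testing. An edge absent
from a permuted model contributes weight 0 ("no association"). Per edge the
two one-sided type-I error probabilities are plain proportions of permuted
differences ≥ (respectively ≤) the observed difference; the +1-smoothed
estimator is available behind a flag but is not the default, since plain
proportions can legitimately reach 0 and 1. Significance flags use p ≤ α
(inclusive) at α = 0.05 by default, uncorrected for multiplicity; a strict
comparator is available.

## Classification

A subject's raw volume vector is scored under both group networks; each
network applies its own standardization and adds the Jacobian term
−Σ log(sd), so both log densities refer to the *raw* scale and are
comparable even when the groups' per-region variances differ. The decision
score is the difference of log densities (equal priors); ties go to the
positive class, which defaults to "young" when that label exists, else to
the larger group. Post-hoc (in-sample) classification is the default;
leave-one-out cross-validation re-learns both models per fold. The ROC is a
threshold sweep over the scores with trapezoidal AUC (equal to the
Mann–Whitney U statistic over n_a·n_b, cross-checked in the tests).

The post-hoc design is intrinsically optimistic: each model is fitted to
its own group's subjects, so even with *identical* generating distributions
the in-sample AUC sits above 0.5 (≈ 0.56 at n = 1000/group in our null
simulations). Held-out evaluation (a fresh cohort or LOOCV) removes this
bias, and the null-calibration tests use held-out subjects for exactly that
reason.

## ROI volume extraction

A region's volume is the mean of the gray-matter probability over voxels
that lie inside the region's atlas labels *and* exceed a 0.15 cut-off —
i.e. the average over surviving voxels only. The alternative reading
(zeroing sub-threshold voxels and averaging over all region voxels) is
available as `mode="all_roi"`. An ROI with no surviving voxel yields NaN
and the subject is flagged, never silently dropped or zeroed. Images and
label masks must share a grid; resampling is out of scope. Segmentation,
normalisation, modulation and smoothing are upstream of this package: it
consumes their NIfTI outputs.

## Synthetic cohorts

The default generator reproduces the study conditions: two groups ("young",
n = 109; "old", n = 82) drawn from the published network structures with
the published standardized weights as structural coefficients — the groups
share three edges, differ in four young-only and three old-only edges, and
reverse the two inter-hemispheric (hippocampal and parietal) edges.
Residual variances default to 1 − (variance explained by the parents), so
every node is marginally standard normal on the z scale and the chosen
coefficients are exactly the model-implied standardized weights. Samples
are mapped to a plausible gray-matter probability scale (mean 0.5, sd 0.05
per region — arbitrary but realistic constants, configurable; no raw
region-level statistics are published to match). Sexes are Bernoulli with
the reported group frequencies (65/109 and 60/82 female) and ages uniform
in the reported ranges (20–28, 60–90). One integer seed makes the whole
cohort byte-identical across runs.

What the generator does *not* emulate: measurement noise from segmentation
and registration, non-Gaussian tails, site/scanner effects, age–volume
trends within group, or any spatial structure in the images (the NIfTI
fixture uses constant rectangular blocks). Tests passing on these cohorts
therefore demonstrate correctness of the estimation and testing machinery
under the model's own assumptions, not robustness to real-data violations
of them.

## Problem sizes and numerical choices

- Permutation tests default to 5000 permutations (p resolution 2×10⁻⁴);
  the null-calibration check uses 200 replicate datasets × 500 permutations
  on a 3-node chain (coefficients 0.6, 100 subjects/group), chosen so the
  full re-learning null is exercised ~10⁵ times at reasonable cost.
- Structure-recovery checks use 2000 subjects/group, where the skeleton is
  reliably identifiable; the default 109/82 cohort mirrors the study's
  power regime, in which learned structures visibly fluctuate.
- Residual variances are floored at 1e-10 (clamped with a warning);
  densities with variance below the floor raise rather than return ±inf.
- Collinear parent sets are detected via the Cholesky pivot of the Gram
  matrix relative to its scale and reported with the offending node.
- Zero-variance columns are rejected before standardization with the
  region named.
- Score-improvement and tie tolerances are both 1e-9.
- All randomness flows through `numpy.random.Generator`; library calls
  accept either a seed or a Generator, and composite procedures spawn
  per-group child streams from one `SeedSequence` so outputs are
  reproducible end-to-end.

## Known limitations

- Edge orientations within a Markov equivalence class are decided by the
  deterministic tie-break, not by evidence; only skeleton-level claims are
  supported by the score.
- The permutation test treats "edge absent" as weight 0, conflating
  absence with zero strength; selection of the tested edge set by the
  observed fit can make the union's weakest members mildly anti-conservative.
- Post-hoc classification metrics are optimistic (see above).
- The sex-ratio chi-square uses no continuity correction (df = 1), matching
  standard large-sample practice.
- LOOCV re-learns structures per fold and is O(n) times the cost of a
  single fit; it is practical at cohort sizes here (hundreds) but not
  optimised beyond that.
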