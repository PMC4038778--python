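# graybn

Gaussian Bayesian networks for **gray-matter structural covariance**: learn a
directed network over regional gray-matter volumes for each subject group,
test between-group differences in connection weights by permutation, and
classify subjects by comparing joint probability densities under the two
group models.

The package is aimed at structural-MRI researchers studying how
inter-regional dependencies of regional morphometry (for example, among the
eight core default-mode-network regions: PCC, mPFC, bilateral hippocampus,
inferior parietal and inferior temporal cortices) differ between groups such
as young versus old adults.

## The model

For d regions with per-subject mean gray-matter volumes
x = (x_1, …, x_d), a linear-Gaussian Bayesian network over a DAG G
factorises the joint density as

    p(x) = ∏_j N( x_j | b0_j + b_j' x_{π_j} , σ²_j )

where π_j is node j's parent set in G. Per node, maximum likelihood gives
the least-squares coefficients and the n-denominator residual variance.
Structures are scored with the decomposable BIC

    BIC(G) = Σ_j [ L_j(θ̂_j) − (k_j / 2) log n ],   k_j = |π_j| + 2,

with L_j the maximised Gaussian log-likelihood of node j's family, and
learned by greedy hill climbing (edge additions/removals, optional
reversals and random restarts) from the empty graph. Volumes are z-scored
within group before fitting, so fitted edge coefficients are **standardized
weights** (for a single-parent child, the parent–child Pearson correlation).

Between-group weight differences are assessed with a label-permutation test
(default 5000 permutations; the full standardize → learn → fit procedure is
re-run per permutation), reporting both one-sided type-I error
probabilities per connection. Group membership of a subject is predicted by
comparing the log joint densities under the two fitted networks, summarised
by accuracy / sensitivity / specificity and a ROC curve with trapezoidal
AUC.

## Worked example

```python
import graybn as gb

# two-group synthetic cohort generated from the default young/old network
# structures (109 + 82 subjects, 8 ROIs)
cohort = gb.make_cohort(gb.default_spec(seed=0))

res = gb.GroupComparison(cohort, gb.SearchConfig(restarts=20, seed=0)).fit()
print(res.summary())
perm = res.permutation_test(n_perm=1000, seed=0)
print(perm.flag_significant())
print(res.classify().summary())
```

prints (abridged)

```
Two-group Bayesian network comparison
============================================================
Groups: a='young' (n=109), b='old' (n=82)
Edges: 10 (a), 10 (b), union 17
------------------------------------------------------------
edge               cat     w_young       w_old
lITC->rITC           I       0.789       0.705
mPFC->lHP            I       0.585       0.235
rITC->mPFC           I       0.514       0.599
lIPC->PCC           II       0.472          --
...
lHP->rHP            IV       0.923          --
rHP->lHP            IV          --       0.711

{'a_greater': [('lHP', 'rHP'), ('lIPC', 'rIPC'), ('mPFC', 'PCC'),
               ('mPFC', 'lIPC')],
 'b_greater': [('PCC', 'lITC'), ('PCC', 'rIPC'), ('rIPC', 'lHP'),
               ('rIPC', 'rHP'), ('rITC', 'rIPC')]}

Density-based group classification
==============================================
Positive class: 'young'   mode: post_hoc
Confusion: TP=80 FN=29 TN=59 FP=23
Accuracy:     72.77%
Sensitivity:  73.39%
Specificity:  71.95%
AUC:           0.811
```

The weight table groups every connection of either network into category I
(present in both groups), II (first group only), III (second group only) or
IV (present in both skeletons with opposite orientation). The permutation
flags list connections whose weight is significantly larger in one group at
uncorrected p ≤ 0.05. The classification block is the in-sample (post hoc)
density comparison; `mode="loocv"` gives the cross-validated variant.

A command-line interface wraps the same steps:

```bash
graybn simulate --seed 7 --out cohort.csv
graybn fit      --cohort cohort.csv --out models.json
graybn compare  --cohort cohort.csv --n-perm 5000 --seed 7 --out report.json
graybn classify --cohort cohort.csv --models models.json --out classif.json
graybn extract  --images maps/ --mask atlas.nii.gz --out cohort.csv   # NIfTI input
```

`graybn extract` computes each region's volume as the mean gray-matter
probability over voxels above a 0.15 cut-off inside the region's atlas
labels.

## Layout

- `graybn.cohort` — cohort CSV I/O, validation, demographics, sex-ratio chi-square
- `graybn.volumes` — ROI mean gray-matter extraction from NIfTI probability maps
- `graybn.dag`, `graybn.bn` — DAGs, linear-Gaussian CPDs, MLE, BIC, sampling,
  `GaussianBN` / `GaussianBNResults`
- `graybn.search` — BIC hill climbing and exhaustive small-graph search
- `graybn.group` — `GroupComparison`, weight table, permutation test
- `graybn.classify` — density-based classification, ROC/AUC
- `graybn.synthetic` — cohort and NIfTI fixture generators
- `graybn.cli` — the `graybn` command

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
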