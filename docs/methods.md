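# Methods

## Data model

Beta values are methylation proportions in the closed interval [0, 1]; 0 and
1 are legal values. Matrices are probes × samples everywhere in the public
API; algorithms that want samples as rows (KNN imputation, classification)
transpose internally. Readers never clip: any value outside [0, 1] is an
error, because silent clipping would hide upstream normalization problems.
Missing values are empty cells on disk (NA/NaN also accepted on read) and
NaN in memory. The paired-columns TSV dialect stores two adjacent columns
per sample (`<sample>.beta`, `<sample>.pval`, suffixes configurable, since
GEO supplements vary in their header conventions); sample count is exactly
half the data-column count and an odd count is a format error.

## Quality control

The low-confidence rule is applied in two coherent steps: individual beta
values with detection p **strictly above** 0.05 are masked, then probes
whose post-masking missing fraction **strictly exceeds** 50% are removed.
This single reading subsumes both the per-value and the per-probe clause of
the usual filtering recipe; the "low confidence" count in the filter report
is the set removed by the missing-fraction rule. The SNP filter is
inclusive (MAF ≥ 5% removes the probe). Probe removal is the union of four
category sets, reported per category, so the unique-removal total equals the
sum exactly when the categories are disjoint. No probe list is pinned: any
annotation table (chromosome, cross-reactive flag, max MAF within 50 bp)
can be supplied, because published cross-reactive/SNP lists differ by
version.

KNN imputation treats samples as the units. Distance between two samples is
the Euclidean distance over mutually observed probes rescaled by
sqrt(n_probes / n_shared), so sparsity does not shrink distances; each
missing value is the unweighted mean of the k nearest samples observed at
that probe. This is the nan-Euclidean convention of
`sklearn.impute.KNNImputer`, which implements the step; a brute-force
neighbor search (full pairwise distance table, explicit top-k) is kept in
the test suite as an independent oracle. k defaults to 10; it is not a
sensitive choice on these data and is recorded in run metadata. Imputation
never alters observed entries and is idempotent on complete matrices.

Top-variance selection uses the unbiased (n−1) variance across samples,
breaking ties toward the lexicographically smaller probe id so selection is
deterministic; retained probes keep matrix order. The default of 10,000
probes matches the dimensionality at which the factorization is typically
run on 450K data.

## Factorization

NMF uses Lee–Seung multiplicative updates with the generalized
Kullback–Leibler divergence by default (the historical convention for
metagene extraction from arrays) and squared Frobenius error by flag.
Factors are initialized uniform on (0, 1] from a seeded generator — strictly
positive, since multiplicative updates lock zeros permanently. A 1e-12
epsilon guards denominators. Updates alternate H then W with a fresh product
between them, which preserves the monotonicity guarantee; the per-iteration
objective trace is stored and tested to be non-increasing within 1e-9
relative tolerance. Convergence is declared when the relative objective
change per iteration drops below 1e-6 (default), capped at 2,000 iterations.

Consensus stability at a rank runs 30 restarts by default (seeds
`base_seed .. base_seed+n_runs−1`). Each restart assigns every sample to
its dominant metagene (argmax over its H column, ties to the lowest index);
the consensus matrix averages the co-assignment indicator over restarts.
The cophenetic correlation coefficient is computed on distances
1 − consensus with **average linkage** (the consensus-clustering
convention); hierarchical clustering and cophenetic distances come from
scipy, with an explicit pairwise-merge simulation as the test oracle. A
consensus whose off-diagonal distances are all equal has no defined
coefficient and raises. Rank selection is reported as a scan table
(rank, cophenetic, best objective); the package does not auto-select a rank
beyond reporting the scan, but on rank-6 synthetic cohorts the score peaks
at 6.

## Projection

New cohorts are projected per sample by non-negative least squares against
the fixed basis: scipy's Lawson–Hanson active-set solver, wrapped with an
explicit Karush–Kuhn–Tucker check (gradient components at zero coordinates
must be ≥ −1e-8, relative). The unconstrained (pseudoinverse) solution is
used only as a test oracle for the case where it happens to be nonnegative —
it is not exposed in the pipeline, because negative metagene activities have
no interpretation. Cohort probes are first aligned to the basis probe order;
basis probes absent from the cohort are either an error or filled with
stored training-probe means (`fill_policy`), and coverage below 95% (by
default) is always an error. The validation cohort's own variance ranking
is never used — the probe set is the one selected on the primary cohort.
Projected coefficients are not renormalized; scaling happens in the
classifier via the training-set min–max scaler.

## Classification

The stratified split draws ceil(train_fraction × n_c) samples per class,
uniformly at random with a seed. Ceiling rounding is deliberate: with the
primary cohort's class sizes (33, 38, 65, 65, 50, 85, 73) and an 80% train
fraction it yields training counts (27, 31, 52, 52, 40, 68, 59) and the
329/80 totals, i.e. the exact arithmetic of the reference workflow.

Min–max scaling maps each metagene by the training minimum and range,
clips transferred sets to [0, 1], and sends constant training features to 0.

Hyperparameter tuning samples configurations at random from bounded grids
(SVM C ∈ [0.01, 50], RBF sigma ∈ [0.001, 1] in the kernlab convention
k(x,y) = exp(−σ‖x−y‖²), i.e. sklearn's gamma; random-forest mtry ∈ [2, 6];
boosting rounds {50,100,150,200}, eta [0.01,0.3], depth [3,10], gamma
[0,5], colsample [0.5,1], min-child-weight [1,10], subsample [0.5,1]; k-NN
k odd in [3, 15]) and scores each by mean stratified-k-fold balanced
accuracy. Published "best" values for these grids are not hard-coded: the
tuned optimum is data- and seed-dependent, so tuning is re-run per dataset
and the selected configuration is persisted with the model. Underlying
estimators are sklearn's SVC/RandomForest/KNeighbors and xgboost; predicted
probabilities are renormalized to sum to 1 and label predictions are the
probability argmax, so the misclassification table (true label, predicted
label, both probabilities) is internally consistent by construction.

Two balanced-accuracy conventions are reported because both are in use and
they differ for more than two classes: the macro-averaged recall, and the
macro average of per-class (sensitivity + specificity)/2. The second is the
headline metric (it is the convention under which the reference workflow's
printed values are reproduced exactly from its confusion data) and is also
the model-selection score during cross-validation. One-vs-rest AUC is the
rank-based Mann–Whitney statistic with ties counted 1/2, which equals the
trapezoidal area under the threshold-swept ROC curve; an exhaustive
pair-counting oracle verifies it in tests. Classes with no true members in
an evaluation set get NaN metrics and are excluded from macro means with a
warning.

## Synthetic cohorts

`generate_cohort` plants: (a) a sparse nonnegative basis — k disjoint
high-loading probe blocks (loadings U(0.7, 1.0)) over a U(0, 0.05)
background, covering 60% of probes; (b) per-subgroup characteristic
coefficient vectors — six subgroups anchor one metagene each and
Group3-HighRisk is a convex mixture leaning from the Group 3 anchor toward
the Group4-HighRisk anchor, with the `separation` parameter (default 0.25)
controlling how far, so the Group 3/Group 4 risk classes overlap while WNT
and SHH stay well separated; (c) per-sample scale U(0.9, 1.1) and additive
coefficient jitter U(0, 0.03); (d) Gaussian noise (default sd 0.02) and
clipping to [0, 1]; (e) an optional monotone S-shaped warp
x^g / (x^g + (1−x)^g) (g = 2) that pushes marginals toward the 0/1 peaks
seen in real beta distributions — warping a low-rank matrix rather than
sampling a mixture preserves the exact planted structure, so recovery tests
disable the warp and distribution tests enable it; (f) detection p-values
below 0.05 at observed entries and in (0.05, 0.5] at planted masked entries
(default rate 2%), so detection-p masking reproduces the planted
missingness exactly; (g) annotation categories (defaults scaled from the
removal proportions of a full 485,512-probe array) planted disjointly on
background probes so QC does not destroy the signal. Class proportions
default to the primary cohort's (33/409 WNT … 85/409 Group4-HighRisk),
apportioned by largest remainder.

What the generator does **not** emulate: probe-type chemistry differences,
batch effects, realistic genomic coordinates, age/sex covariates, and the
diffuse (non-block) loading patterns of real metagenes. Passing tests
therefore demonstrate the correctness and stability of the algorithms under
the stated generative assumptions, not clinical-grade accuracy on real
tumors.

## Problem sizes and numerical choices

Tests run the heavy factorization checks at 2,000 probes × 350 samples with
30 restarts (the scale at which the consensus diagnostics are
well-behaved), and the end-to-end classification check on the same cohort
with the top 1,000 variance probes, 5 consensus restarts and 10 tuning
candidates — enough restarts for a stable basis while keeping the default
suite fast. The pipeline defaults (rank 6, 30 restarts, 10,000 probes) are
the study-scale settings. Degenerate inputs fail loudly rather than
silently: empty post-filter matrices, all-missing probes, zero-variance
consensus matrices, all-zero basis columns, and single-class ROC inputs all
raise with specific messages.

## Known limitations

KL multiplicative updates converge slowly near the optimum; the relative
change criterion stops them at a practical point, but very flat objectives
at over-specified ranks take most of the 2,000-iteration budget. Consensus
clustering on strongly separated synthetic data saturates at cophenetic 1.0,
so the diagnostic's discriminating behavior between adjacent ranks is only
visible with noise or weaker separation. SVM probability estimates use the
underlying implementation's Platt-style calibration; they are deterministic
given the seed but not calibrated in the statistical sense. The CLI's
`full` command reuses the simulated cohort as its own validation cohort when
no independent validation paths are configured, which is a smoke-test
convenience, not an evaluation design.
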