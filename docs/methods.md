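# Methods

## The estimation problem

A bulk RNA-seq profile of a mixed tissue is, to first approximation, a
weighted sum of the expression profiles of its constituent cell types.
Expression deconvolution inverts that sum: given the bulk gene expression
profile (GEP) of a sample, estimate the fraction of each cell type in it.
`nnice` estimates the fractions of six immune lineages — B cells, CD4+ T
cells, CD8+ T cells, myeloid cells, NK cells, and other cells — together
with an uncertainty band for each estimate.

## Model

For each cell type *k* and each quantile *q* in {0.10, 0.25, 0.50, 0.75,
0.90}, an independent network maps the fixed gene panel (3,000 features by
default) through one densely connected layer of linear units (300 by
default) to a single linear output: ŷ = (x·W₁ + b₁)·w₂ + b₂. The output
bias b₂ is constrained non-negative (clamped after every optimiser step)
and the output weight kernel w₂ carries an L2 penalty with λ = 10⁻⁴
(configurable to include W₁). With 6 types × 5 quantiles the default model
holds 30 networks of 3000·300 + 300 + 300 + 1 = 900,601 parameters each.

Training each type independently, rather than one network with a K-output
softmax head, sidesteps the multicollinearity of marker expression across
related lineages (a gene such as *CD3D* tracks several T-cell subsets at
once); it also means per-type estimates are **not** renormalized to sum to
one by default (a `renormalize` flag is available).

Because every activation is linear, the forward map, its gradients, and the
optimiser (Adam, lr 10⁻³, batch 64, up to 30 epochs with early-stopping
patience 5) are implemented directly in numpy with closed-form gradients;
the gradients of every objective are verified against central finite
differences in the test suite, and training is bit-reproducible given the
config seed.

### Objectives

The composite regression loss is Loss = α(1−R) + (1−α)·RMSE, where R is
the batch Pearson correlation and α defaults to 0.8 (configurable; when a
batch vector is constant R is undefined and the loss falls back to RMSE,
logged). The tilted (pinball) loss is TiltedLoss(q, ξ) = max(q·ξ, (q−1)·ξ).

Two ways of nesting these are implemented:

* **signed** (default): mean over the minibatch of TiltedLoss(q, yᵢ−ŷᵢ)
  plus α(1−R) as a correlation regulariser. The pinball term's minimiser is
  the conditional q-quantile (under-prediction by the q=0.9 network costs
  9× more than over-prediction), so the five networks genuinely bracket the
  estimate; the shift-invariant R term sharpens correlation without moving
  the quantile anchor. Held-out coverage below each quantile network's
  prediction is checked to land within ±0.1 of q in the test suite.
* **literal**: TiltedLoss(q, Loss) applied to the non-negative composite
  batch loss. Since Loss ≥ 0 always, this reduces identically to q·Loss —
  all five quantile networks then optimise proportional objectives and the
  quantile interpretation collapses. It is retained, and its degeneracy
  asserted exactly, for fidelity experiments.

### Input normalization and prediction

Profiles are normalized as log1p of counts-per-million, then standardized
per feature with statistics fitted on the training split only. Raw network
outputs are clipped to [0, 1]. The point estimate is the unweighted mean of
the five quantile outputs; the reported band is the (q10, q90) pair.
Quantile crossing is reported as-is by default; an optional per-(sample,
type) sort is available behind `sort_quantiles`.

## Feature selection

A gene enters the fixed input panel iff it (1) appears in the supplied
immune-related gene list, (2) is present in every dataset in play, and
(3) ranks among the top n (default 3,000) by variability. Criteria are
intersected **first** and the top-n taken afterwards, so the panel always
has exactly n genes or the shortfall is reported.

The variability score is the variance of depth-adjusted Pearson residuals
under a fixed-dispersion negative-binomial null: μ_gc = depth_c·p_g with
p_g the gene's pooled count proportion, residual (x−μ)/√(μ+μ²/θ) with
θ = 100, clipped at ±√n_cells; this analytic form approximates
regularized-NB (SCTransform-style) highly-variable-gene ranking without the
per-gene regression machinery, and its fixed θ and clip are configurable.
Ties break lexicographically on gene ID, making the ranking a total order;
shrinking n yields a prefix of the larger panel. Variability is computed on
QC-filtered cells, on the split of the reference reserved for selection.

## QC and pooling

Cells are kept when they express between 200 and 3,000 features with
positive counts (inclusive bounds) and have a mitochondrial count
percentage strictly under 5% — boundaries are read inclusively/"under"
strictly from their plain-language statement and all are configurable.
Mitochondrial genes are recognised by case-insensitive `MT-` prefix or an
explicit set. Zero-total columns get pct_mito = 0, are flagged, and fall to
the min-genes rule anyway. Filtering is pure column selection (idempotent,
never rewrites values).

Two pooling maps ship as data: the ten FACS-sorted PBMC populations →
six lineages (CD34+ cells map to Other; the four CD4 subsets pool to CD4
T cell, the two CD8 subsets to CD8 T cell), and a 14-population
flow-cytometry panel (naïve/exhausted/non-switched/switched B cells and
plasmablasts → B cell; classical/intermediate/non-classical monocytes,
mDCs, pDCs → Myeloid; basophils → Other). The plasmablast and basophil
assignments follow the standard lineage reading but are not uniquely
dictated by convention, so every assignment is overridable via a two-column
TSV.

## Pseudo-bulk simulation

Fractions for K pooled types are drawn from a symmetric Dirichlet(α), with
α = 1 by default — uniform on the simplex, the least-informative choice.
Each fraction vector becomes integer cell counts summing to C (default 500)
by largest-remainder rounding (deterministic, ties by type order); the
stored ground truth stays the continuous Dirichlet draw, from which the
realised proportions deviate by at most K/(2C) per type. Cells are
subsampled uniformly without replacement per type (falling back to
with-replacement, logged, only when a pool is exhausted) and their count
vectors summed gene-wise, so each profile's total exactly equals the summed
totals of the cells used — an invariant asserted throughout the tests.
Profiles are raw count sums; normalization is the model's concern. The
reference is split (stratified by type) into disjoint selection and
simulation cells so feature selection cannot leak into evaluation data.
No sequencing noise is layered on top of the sums; real bulk RNA-seq is not
a simple sum of single-cell profiles, and that platform gap is a known
limitation of pseudo-bulk training in general, not something this simulator
models.

## Synthetic single-cell generator

The generator produces what the estimator assumes: a labeled reference of
~10 immune cell types that pool into the six lineages. Per (type, gene)
expected rates start from a shared long-tailed lognormal(0, 1) baseline;
each type then multiplies a random 30% of gene rates by lognormal(0, 0.6)
differential-expression factors (the splatter-style mechanism that makes
types globally distinct, as sorted populations are); finally a
round-robin-assigned 15% of genes are exclusive markers whose owner's rate
is pinned at marker_fold (default 5) times the maximum over all other
types, so the fold-change invariant holds by construction. Counts are
negative-binomial (gamma-Poisson, dispersion θ = 2) with mean =
depth × rate, a per-cell uniform depth multiplier on [0.5, 2] (so QC has
realistic library-size variation to act on), and independent dropout
(default 0.2). Mitochondrial genes are ordinary genes flagged by `MT-`
prefix (2% of genes by default) whose rates can be boosted to manufacture
cells that fail the 5% mito filter. Default scale is 10 types × 300 cells ×
1,000 genes.

At these defaults a nearest-centroid classifier on log-normalized cells
recovers ≥ 95% of held-out labels, i.e. the types are cleanly separable.
What the generator does **not** emulate: ambient RNA, doublets, batch
effects, UMI-vs-read distinctions, or the empirical count distribution of
any particular platform — passing tests demonstrate the pipeline's
correctness and its behaviour under a clean overdispersed-count law, not
performance on real tissue. One measured consequence of the generative law:
because every gene's true dispersion (θ=2) exceeds the ranking null
(θ=100), the variability score grows with expression for all genes, and
marker dominance in the ranking holds in the expression-matched sense (a
marker outranks ≥ 90% of non-markers of similar abundance) rather than
unconditionally.

## Evaluation

Pearson R uses the centered cross-moment form; RMSE is the root mean
squared difference; the composite loss in reports reuses the training α
(echoed in metadata). Reports cover three granularities: per (type ×
quantile), per type on the quantile-averaged estimate, and overall — where
"overall" is the metric on the concatenation of all (sample, type) pairs,
not the mean of per-type values (the suite includes a fixture where the two
differ). A constant truth column leaves R missing, never zero. Scatter
panels annotate the least-squares slope and intercept alongside R, since a
high correlation with slope far from 1 overstates accuracy.

k-fold cross-validation (default k = 10) shuffles with a seeded permutation
and chunks contiguously, so fold sizes differ by at most one (468 samples →
folds of 46/47); folds are unstratified. Each fold's model is trained on
the complement and predicts the fold once; out-of-fold estimates are pooled
in original sample order. True-fraction tables with missing entries are
zero-filled and row-renormalized; all-zero rows and negative entries are
errors that name the offending samples.

## Benchmark problem sizes

The package's standard simulated-data benchmark
(`nnice.benchmark.run_headline_benchmark`, recomputed by
`scripts/acceptance.py`) runs the whole pipeline at desk scale: 1,000
genes, 300 cells/type, marker fold 5, dropout 0.2; 300 selected features;
2,000 training and 500 held-out mixtures of C = 500 cells with Dirichlet(1)
fractions; 64 hidden units, signed objective, up to 30 epochs. These sizes
keep a full run around ten seconds on one CPU while leaving the pooled
held-out correlation stable across seeds.

## Numerical choices and degenerate inputs

Softmax is computed max-shifted (kept only for the legacy multi-output
head). Standardisation floors the per-feature s.d. at 10⁻⁸; CPM guards
zero-total profiles. The pinball subgradient at ξ = 0 is taken as 0.
Batches of fewer than two samples are skipped (batch metrics are undefined
there). A non-finite training loss aborts with a diagnostic rather than
continuing. Training with 0 epochs returns the model unchanged with empty
history; early stopping restores the best-validation-loss parameters.
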