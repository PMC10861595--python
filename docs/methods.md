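# Methods

## Problem setting

Given a labeled *source* domain `D_S = {(x_i, y_i)}`, `x ∈ R^d`, `y ∈ {1, …, C}`
and an unlabeled *target* domain `D_T = {u_i}` drawn from a different
distribution, the task is to predict target labels without ever seeing any.
The motivating application is wearable-sensor health prognosis: two cohorts
(e.g. community-dwelling older adults vs. osteoporosis patients) walk the
same 10-m test and yield the same gait features, but their feature
distributions differ, so a classifier carried naively across cohorts
degrades. Sample sizes are small (tens to low hundreds) and classes are
imbalanced, which rules out data-hungry neural approaches and motivates a
shallow, linear-algebraic pipeline.

## The pipeline

The combined method chains two classical alignments and a 1-nearest-neighbor
classifier:

1. **Covariance (CORAL) alignment.** With regularized covariances
   `Cs = cov(Xs) + r·I` and `Ct = cov(Xt) + r·I`, the re-coloring matrix is

       A_coral = Cs^{-1/2} · Ct^{1/2}

   using symmetric principal (inverse) square roots. By construction
   `A'·Cs·A = Ct` exactly — the transform whitens the source correlation and
   re-colors it with the target's. The pipeline applies it to *centered*
   source features and shifts onto the target mean,
   `(Xs − μs)·A + μt`. The whiten/re-color derivation concerns centered
   second moments; multiplying uncentered features by `A` drags the source
   mean to `μs·A`, an uncontrolled side effect that badly corrupts the
   initial pseudo-labels whenever the domains differ in location (the usual
   per-domain standardization in correlation-alignment practice removes the
   means the same way). `coral_align(..., center_means=False)` and the
   `coral_center` config flag recover the strictly second-order variant.

2. **Initial pseudo-labels.** A 1NN classifier trained on the aligned source
   labels the target. This replaces the weaker raw-source bootstrap of plain
   joint distribution adaptation, which is the main point of the combination:
   the quality of the *first* round of pseudo-labels controls how well the
   conditional alignment below can work.

3. **Iterative joint distribution adaptation.** Stack the aligned source and
   the target as columns of `X` (d × n, source block first). The empirical
   maximum mean discrepancy between blocks is `tr(A' X M0 X' A)` with the
   rank-one marginal matrix

       (M0)_ij = 1/ns²  (both source), 1/nt²  (both target), −1/(ns·nt)  otherwise,

   and one conditional matrix `Mc` per class built the same way from the
   class-c sub-blocks (source: true labels; target: current pseudo-labels),
   zero where a class is missing from either block. Minimizing the summed
   discrepancy under the variance constraint `A' X H X' A = I`
   (`H = I − 11'/n`) gives the generalized eigenproblem

       (X (M0 + Σc Mc) X' + λI) A = X H X' A Φ,

   solved for the `k` eigenvectors of smallest eigenvalue. Each iteration
   re-embeds (`Z = A'X`), retrains the 1NN on the source block, re-labels
   the target block, and rebuilds the conditional matrices; the loop stops
   when the pseudo-labels are unchanged between consecutive iterations or
   after `max_iters` rounds. Final target predictions are the last
   pseudo-labels — the "adaptive classifier" is the 1NN in the final
   embedding.

### Parameters

| name | default | meaning |
|---|---|---|
| `k` | 2 | embedding dimension (number of subspace bases); must satisfy `k ≤ d` |
| `lam` | 1.0 | ridge term of the eigenproblem; large values push the solution toward the leading principal axes |
| `max_iters` | 10 | refinement rounds; 0 skips refinement (covariance alignment + 1NN only) |
| `normalize` | on | pooled z-scoring of the stacked source+target features (per feature), so no single feature's scale dominates the discrepancy |
| `coral_reg` | 1.0 | diagonal loading `r` on both covariances; keeps them invertible when `n < d` (the fall-risk shape: d=50, as few as 14 samples per class) |
| `coral_center` | on | mean alignment inside the covariance step (see above) |

All quantities are unitless (features are z-scored by default).

### Numerical choices

* Matrix square roots by eigendecomposition with negative eigenvalues
  clipped at zero; the inverse root requires a strictly positive spectrum
  and fails loudly otherwise.
* Both sides of the eigenproblem are symmetrized (`(B+B')/2`) before the
  Hermitian generalized solve (`scipy.linalg.eigh`); the constraint side is
  computed as `Xc Xc'` with column-centered `Xc` (H is idempotent).
* Eigenvalues ascend; each eigenvector's sign is fixed by making its
  largest-magnitude component positive, so runs are bit-reproducible.
* 1NN ties break to the lowest training-point index (deterministic).
* Pooled z-scoring drops zero-variance features with a warning; classes that
  vanish from the pseudo-labels contribute a zero conditional matrix with a
  warning rather than aborting.
* A degenerate special case worth knowing: when `k = d` the constraint
  makes the embedding a full-rank whitening of the stacked data, and the
  solution subspace no longer depends on `λ` or the MMD matrices — the
  refinement reduces to 1NN in the whitened space. This is unavoidable for
  the 2-D simulation designs, where `k = 2` is the only admissible choice.

## Preprocessing paths

Two reduction paths for grouped gait-feature tables (28 "linear" + 22
"nonlinear" features in the motivating shape):

* **Group-wise PCA** — an independent PCA per feature group, fitted on the
  pooled source+target features (unsupervised; labels untouched) so both
  domains share one component space; 10 components from the linear group and
  12 from the nonlinear group combine into 22. Pooling is the only fit that
  gives both domains identical axes without touching target labels.
  Components are variance-ordered with orthonormal loadings; rank-deficient
  groups truncate with a warning.
* **Mutual-information filtering** — each feature is discretized into 10
  equal-frequency (quantile) bins and scored by the plug-in estimate of
  I(feature; label) in nats; the top 10 of 50 are kept, ties to the lower
  index. The plug-in estimator on ~10×2 tables has positive bias of order
  (bins−1)(C−1)/(2n), negligible at the sample sizes used; quantile binning
  makes scores invariant to strictly monotone feature rescaling.

## Synthetic data

The generators reproduce three two-class Gaussian domain-shift designs
(scenarios a–d each) plus a two-cohort fixture:

* **overlap** — fixed 2-D parameters, 100 samples per class. Source:
  μ1=[2.5, 7.5], Σ1=diag(3,1); μ2=[7, 4], Σ2=diag(2,1). Target scenarios
  walk class 2 toward class 1: (a) μ2=[13,0], Σ2=diag(6,1); (b) μ2=[8,1],
  Σ2=diag(6,1); (c) μ2=[8,2], Σ2=diag(6,2); each with μ1=[3,6],
  Σ1=diag(8,2); (d) μ1=[2.5,6], μ2=[7,4], Σ2=diag(6,2). The target Bayes
  error rises from (a) to (c) (verified numerically in the tests). Note the
  *shift* between domains is largest in (a): intrinsic difficulty and
  transfer difficulty move in opposite directions across these scenarios,
  so only methods that actually remove the shift track the Bayes ordering.
* **sample_size** — randomized designs at 50/100/200/500 samples per class.
  Each domain independently draws per-dimension class means (class 1 from
  U[2,5], class 2 from U[4,9]), and a covariance `Q·diag(u)·Q'` with
  uniform diagonals (source U[1,3], target U[4,6]) and a random orthogonal
  `Q`; the dimension is shared, drawn from U{2..20}. Independent draws per
  domain are what make these *domain-shift* experiments: with shared
  parameters there is nothing to adapt. All ranges are configurable
  (`SampleSizeRanges`).
* **noise** — the randomized design at 100 per class plus i.i.d. additive
  uniform noise per cell, half-width 1/2/3/4 for scenarios a–d, applied to
  both domains (configurable to target-only).
* **synth_fall_cohort** — a stand-in with the *shape* of the two-cohort gait
  study: 171×50 source, 49×50 target, two correlated feature blocks (28+22;
  within-block correlation 0.5, between 0.05, identical across domains),
  imbalanced binary labels (minority fraction 0.2, label 2 = faller), a
  0.8 mean shift on 15 features for the faller class, and a target-domain
  mean shift (U[−0.5, 0.5] per feature) with covariance scaled ×1.3. It
  emulates block correlation, imbalance and cohort shift — not the marginal
  distributions, feature semantics or label noise of real gait data, so
  results on it say nothing quantitative about clinical performance; it
  exercises the pipeline's shape and ranking behavior only.

Labels use {1, 2} everywhere (generators that conceptually produce {0, 1}
remap at the interface). All generators are deterministic functions of an
integer seed via named `numpy` generators; there is no global random state.

## Evaluation harness

Because target labels exist only inside simulations, hyperparameter
"tuning" is transparent grid reporting, not cross-validation: every cell of
k ∈ [2..10] × λ ∈ {0.01, 0.1, 1, 10, 100} (45 cells) is run and reported
with mean ± sd over seeded repeats; the covariance-only and no-adaptation
baselines are parameter-free (one cell). Suite benchmarks regenerate each
scenario's data per repeat (seed = base + repeat index) and compare methods
at the matched default cell (k=2, λ=1) — the only admissible k for the 2-D
designs. The standalone `coral` baseline is the published second-order-only
algorithm (no mean alignment); the pipeline's internal step centers, as
motivated above. F1 uses the source's minority class as the positive class.
A balanced sub-sampling flag draws equal per-class source samples per
repeat for the imbalanced cohort suite.

## Known limitations

* Linear (primal) formulation only: no kernelized variant, no manifold or
  geodesic-flow features, no probability outputs (1NN cannot produce them,
  so no AUC).
* With `k = d` the refinement degenerates to whitening (above), and with
  very small source classes the covariance estimates that drive the
  alignment are noisy — the smallest-sample scenarios are where the
  combined method is least reliable.
* The conditional alignment trusts pseudo-labels; when the initial labeling
  is badly wrong the iteration can converge to a self-consistent but wrong
  labeling. Initializing from the covariance-aligned source is precisely
  the mitigation, but not a guarantee.
* Multi-class inputs are supported by construction (one conditional matrix
  per class), but all shipped simulation designs are binary.
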