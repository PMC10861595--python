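# ceda — correlation-enhanced distribution adaptation

Unsupervised domain adaptation for tabular feature data, built for the
small-sample, imbalanced datasets typical of wearable-sensor health
prognosis (the motivating case: predicting fall risk for a new patient
cohort from gait features, when diagnostic labels exist only for a
different, related cohort).

Classifiers assume train and test data share a distribution. When a model
trained on one cohort (the labeled **source** domain `D_S = {(x_i, y_i)}`,
`y ∈ {1,…,C}`) is applied to another (the unlabeled **target** `D_T`),
that assumption fails and accuracy drops. This package implements CEDA
(Correlation Enhanced Distribution Adaptation), a shallow pipeline that
aligns the two domains before classifying:

1. **CORAL** (correlation alignment): re-color the source features with
   `A = Cs^{-1/2} Ct^{1/2}` so the source covariance matches the target's;
   a 1-nearest-neighbor classifier on the aligned source produces initial
   target pseudo-labels `ŷ_T`.
2. **Iterative JDA** (joint distribution adaptation): find a linear
   embedding `Z = AᵀX` minimizing the marginal *and* per-class conditional
   maximum mean discrepancy between domains by solving the generalized
   eigenproblem `(X Σc Mc Xᵀ + λI) A = X H Xᵀ A Φ` for the k smallest
   eigenvalues, then re-label the target with 1NN in the embedding and
   iterate until the pseudo-labels stabilize.

The CORAL bootstrap is the point of the combination: plain JDA starts from
pseudo-labels produced on unaligned data, and bad first-round labels poison
the conditional alignment. See `docs/methods.md` for the full model,
defaults, and numerical conventions.

Also included, mirroring the full study pipeline:

* `simulate` — three seeded Gaussian domain-shift experiment suites
  (sample size, class overlap, additive noise; scenarios a–d each) and a
  synthetic two-cohort gait-study stand-in (171×50 / 49×50, correlated
  feature blocks, imbalanced labels),
* `preprocess` — group-wise PCA (28+22 features → 10+12 → 22 components)
  and mutual-information top-k feature filtering,
* `bench` — accuracy/F1 evaluation, transparent (k, λ) grid reporting and
  repeated seeded method comparisons,
* a `ceda` command-line interface over all of it.

## Worked example

```python
import numpy as np
import ceda

# the fixed class-overlap design, scenario (b): 100 samples/class per domain
source, target = ceda.make_experiment("overlap", "b", seed=7)

model = ceda.CEDA(source, target, k=2, lam=1.0)   # target labels held back
res = model.fit()
print(res.summary())

acc, f1 = ceda.evaluate(res.predictions, target.labels, positive_class=2)
print(f"accuracy={acc:.3f}  F1={f1:.3f}")
plain = ceda.run_method("no_adaptation_1nn", source, target)
print(f"no-adaptation 1NN accuracy={np.mean(plain == target.labels):.3f}")
```

prints

```
      Correlation Enhanced Distribution Adaptation
==========================================================
Source samples:          200    Features: 2
Target samples:          200    Classes:  2
Subspace bases (k):        2    lambda:   1
Max iterations:           10    Run:      2
Normalize (z-score):    True    CORAL reg: 1
CORAL condition no.:       1.089
----------------------------------------------------------
iter   pseudo-label changes   marginal MMD in embedding
   1                      3   1.31414e-34
   2                      0   1.31414e-34
eigenvalues (ascending): 0.001441, 0.008246
predicted target class counts: {1: 100, 2: 100}
==========================================================
accuracy=0.980  F1=0.980
no-adaptation 1NN accuracy=0.890
```

The refinement converged in two rounds (iteration 2 changed no
pseudo-labels); the marginal discrepancy between the embedded domains is
numerically zero; and adaptation recovers 9 accuracy points over carrying
the raw source classifier across the shift. `res.plot_embedding()` draws
the shared 2-D embedding.

The same run from the shell:

```sh
ceda simulate --experiment overlap --scenario b --seed 7 --out-dir data/
ceda adapt data/source.csv data/target.csv --method ceda --k 2 --lam 1.0 --out-dir run/
ceda benchmark --suite overlap --repeats 20 --seed 0 --out report.csv
```

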