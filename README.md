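# orthomoments

Orthogonal image moments for biological image classification: discrete
**Krawtchouk moments** on rectangular pixel grids and **generalized
pseudo-Zernike moments** on the unit disk, wired into a complete
feature-extraction and classification pipeline.

The package is aimed at researchers who want to judge whether
moment-derived image features carry enough signal for a classification
problem — e.g. identifying insect species from binary wing-venation
images, or separating benign from malignant masses in mammographic
regions of interest — before investing in heavier machinery.  It
provides:

* `preprocess` — PNG I/O, min–max normalization, resizing, histogram
  equalization, binarization, centered crop/pad, CSV manifests;
* `krawtchouk` — weighted Krawtchouk polynomial bases
  `k̄_n(x; p, N−1)`, moment matrices `Q = K₁ A K₂ᵀ`, exact inverse
  transform `A = K₁ᵀ Q K₂`, and translation/rotation/scale-robust
  invariant features via pose normalization;
* `pseudozernike` — generalized radial polynomials `R^α_nm(r)`,
  weighted orthonormal disk polynomials
  `V̄^α_nm(r, θ) = R̄^α_nm(r) e^{imθ}`, moments
  `Z̄^α_nm = ∬ [V̄^α_nm]* f r dr dθ`, inverse transform, and
  rotation-invariant magnitude features `|Z̄_nm|`;
* `order_selection` — reconstruction-MSE curves over moment orders and
  two order-selection rules (arg-min of the mean MSE; rounded mean of
  per-image arg-mins);
* `features` — Z-score scaling, top-|t| feature selection, Q-mode PCA
  for p ≫ n matrices, Fisher LDA, and the train-mean-centered test
  projection `V_test = X_centered Wᵀ`, `D_test = V_test,k A`;
* `kde_classifier` — per-class product-Gaussian kernel density
  discriminant with Scott bandwidths and prior-weighted posteriors,
  yielding the predicted probability of malignancy P(mal);
* `bayes` — beta-posterior accuracy estimation: after `ΣX` correct of
  `N`, the posterior is `Beta(ΣX+1, N−ΣX+1)` with mean `(ΣX+1)/(N+2)`
  and equal-tailed credible intervals;
* `synthetic` — generators for multi-class wing-like binary images
  (with paired 19-point landmarks) and two-class mass-like grayscale
  images with five correlated categorical expert features;
* `pipeline` — the two end-to-end study designs plus
  accuracy/sensitivity/specificity reporting as mean ± sd/√repeats;
* a `orthomoments` command-line interface over all of the above.

## Worked example

Train the wing study on synthetic data (5 classes × 5 images,
128 × 352 px, class effect 4 px, jitter 1 px), with a held-out batch
from the same population:

```python
from orthomoments import synthetic, pipeline

spec = synthetic.WingSpec(n_classes=5, n_per_class=5, height=128, width=352,
                          delta=4.0, jitter=1.0, seed=7)
cfg = pipeline.WingStudyConfig(wing_spec=spec, km_order=60,
                               n_components=20, heldout=True)
report = pipeline.run_wing_study(cfg)

print("training accuracy:", report.train_posterior.format_percent())
print("landmark arm:     ", report.landmark_posterior.format_percent())
print("held-out accuracy:", report.test_posterior.format_percent())
```

prints

```
training accuracy: 96.3% [86.8%, 99.9%]
landmark arm:      96.3% [86.8%, 99.9%]
held-out accuracy: 77.8% [60.6%, 91.0%]
```

All 25 training wings are classified correctly; the posterior mean of
96.3% (not 100%) and the credible interval reflect that 25 samples
cannot pin the accuracy down further — the posterior mean
`(25+1)/(25+2)` shrinks the raw estimate toward the uniform-prior
mean.  The held-out batch shows the generalization gap at this effect
size.

The same estimator from the shell:

```bash
$ orthomoments bayes-acc --correct 71 --total 74
94.7% [88.8%, 98.5%]
```

## Layout

```
src/orthomoments/   library modules
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance script
docs/methods.md     models, assumptions, numerical choices
```
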