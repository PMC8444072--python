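# Methods

## Krawtchouk moments

The Krawtchouk polynomial of order `n` on the grid `x = 0..N−1` is
`k_n(x; p, N−1) = 2F1(−n, −x; −(N−1); 1/p)` with `0 < p < 1`.  The
weighted form `k̄_n(x) = k_n(x) √(ω(x)/ρ(n))`, with `ω` the binomial
pmf `Bin(N−1, p)` and `ρ(n) = ((1−p)/p)ⁿ n! (N−1−n)! / (N−1)!` the
squared norm, is orthonormal: the `l × N` matrix `K` of weighted values
satisfies `K Kᵀ = I`.  Moments of an `N × M` image are `Q = K₁ A K₂ᵀ`
and the inverse transform `A = K₁ᵀ Q K₂` is exact at full order
(`l = N = M`), since it is then just an orthogonal change of basis.

**Numerical evaluation.**  Neither the hypergeometric sum nor the
three-term recurrence in `n` is usable here: the former cancels, and
the latter loses orthogonality catastrophically once `n` exceeds
roughly `N/2` (at `l = N = 256` the Gram error reaches 10⁴⁴).  The
package instead computes the basis as the eigenvectors of the
symmetric tridiagonal Jacobi operator obtained by symmetrizing the
recurrence in `x` (diagonal `p(N−1−x) + x(1−p)`, off-diagonal
`−√(p(1−p)(x+1)(N−1−x))`), whose eigenvalues are exactly `0..N−1` with
the weighted Krawtchouk vectors as eigenvectors.  Orthonormality is
then inherited from the symmetric eigensolver at machine precision for
every `l ≤ N`.  Each eigenvector is determined up to sign; anchoring
the sign at `x = 0` (where `k_n(0) = 1 > 0`) fails for large `N`
because `k̄_n(0)` carries a √-binomial factor far below eigenvector
noise, so each row's sign is instead anchored at its largest-magnitude
entry, with the polynomial's sign there computed from the terminating
series in exact rational arithmetic.  Sampled entries agree with exact
evaluation to ~10⁻¹⁴ relative error at `N = 724, l = 200` and
`N = 256, l = 256`.

**Invariant features.**  Transform-robust features are produced by
explicit pose normalization rather than by moment-algebra identities:
the intensity centroid is translated to the frame center, the
principal axis of the second-moment tensor is rotated onto the column
direction, and the image is scaled isotropically so its total mass
equals a fixed fraction (default 0.25) of the frame area; the
remaining 180° ambiguity is resolved by requiring the third-order
central moment along the principal axis to be non-negative.  The
Krawtchouk moment matrix of the canonical image, flattened row-major,
gives `order²` features (40,000 at order 200).  On binary ellipses the
features of translated/rotated/×1.2-scaled copies agree within 5%
relative distance; the residual is interpolation and re-rasterization
error, so near-degenerate shapes (tiny masses, near-circular shapes
with ill-defined principal axes) will be less stable.

`p = 0.5` is used for both axes throughout; it centers the binomial
weight on the image and is the natural default when no prior reason
exists to emphasize one side of the frame.

## Generalized pseudo-Zernike moments

The radial polynomials are

    R^α_nm(r) = (n+|m|+1)!/(α+1)_{n+|m|+1} ·
                Σ_j (−1)^j (α+1)_{2n+1−j} / (j!(n−|m|−j)!(n+|m|+1−j)!) r^{n−j}

with `α > −1` and `R⁰_nm` the classic pseudo-Zernike polynomials
(e.g. `R₁₀(r) = 3r − 2`, `R_nn(r) = rⁿ`).  The alternating factorial
sum cancels catastrophically at high order even in log space, so the
package evaluates through the exact identity

    R^α_nm(r) = (−1)^{n−|m|} r^{|m|} P^{(2|m|+1, α)}_{n−|m|}(1 − 2r)

where `P` is a Jacobi polynomial computed by its stable three-term
recurrence.  The identity was derived by reindexing the defining sum
into hypergeometric form and is verified in the tests against exact
rational arithmetic for all `n ≤ 8` and both α values used.  The
weighted polynomial multiplies by `(1−r)^{α/2}` and the normalization
`√((2n+α+2)(α+1+n−|m|)_{2|m|+1} / (2π (n−|m|+1)_{2|m|+1}))`
(log-gamma arithmetic), making `V̄^α_nm = R̄^α_nm e^{imθ}` orthonormal
on the unit disk; radial orthonormality is checked by Gauss–Legendre
quadrature to 10⁻⁴.

Moments map the square image onto the *inscribed* disk of the frame
(origin at the image center, θ counter-clockwise from the +column
axis, pixel centers with `r > 1` ignored) and approximate the integral
by a midpoint Riemann sum with pixel area `(2/S)²` in disk units.  At
`S = 300` the constant-image moment `Z̄₀₀` matches the closed form
`√π` to 0.003%.  Only `m ≥ 0` is stored; negative repetitions follow
from the conjugate symmetry `Z[n,−m] = conj(Z[n,m])`, exact for real
images by construction.  Features are the magnitudes `|Z̄_nm|`,
`m ≥ 0`, in `(n, m)` lexicographic order — magnitudes are exactly
invariant under image rotation up to quadrature error, which is why
they are preferred over real/imaginary parts; the count is
`(n_max+1)(n_max+2)/2` (8,128 at order 126).  `α = 0` is the default:
the weight `(1−r)^{α/2}` with larger α suppresses the disk boundary,
which empirically raises reconstruction error on low-noise images.

## Order selection

Reconstruction error is the mean squared pixel difference (divided by
`N·M`).  Krawtchouk MSE curves are non-increasing in the order because
truncated reconstructions are nested orthonormal projections; disk
moments are computed with discrete quadrature, so their curves may
wiggle but trend downward on smooth images.  Two selection rules are
provided: `argmin_mean_mse` (order minimizing the across-image mean
MSE; ties to the smallest order) and `mean_of_argmins` (mean of
per-image best orders, rounded half away from zero).  The first is the
natural rule for the rectangular (Krawtchouk) family, the second for
the disk family whose per-image optima spread widely; both are exposed.

## Feature space

Z-scoring uses the sample (n−1) standard deviation; constant features
map to exact zeros rather than being dropped, preserving index
alignment.  Two-class feature selection ranks pooled-variance
two-sample t statistics and keeps the `⌈fraction·p⌉` largest
magnitudes (default fraction 0.01); zero-variance features get t = 0,
and |t| ties break toward the smaller index for determinism.  PCA is
computed from the thin SVD of the centered matrix (Q-mode: scores at
most `n × n`), with component signs fixed by making the
largest-magnitude loading positive; truncation is either the smallest
`k` whose cumulative explained-variance ratio reaches β (default
0.95) or a fixed component count (the wing study uses a fixed 60).
Fisher LDA solves `S_b a = λ S_w a` in the retained component space;
the within-class scatter is ridge-regularized with `1e−8·tr(S_w)/k`
when singular — routine after aggressive PCA truncation with few
samples per class — and the `s−1` leading directions are kept.  Test
samples are centered with *training* means, projected on the retained
loadings, and multiplied by the discriminant weights; the
dimensionally consistent product `V_test,k A` (with `A` of size
`k × (s−1)`) is used.

## Kernel discriminant

Each class receives a product-Gaussian kernel density with
per-dimension Scott bandwidths `h_j = σ̂_j n_c^{−1/(d+4)}`; degenerate
bandwidths (single point or zero spread) fall back to a global fixed
bandwidth with a warning.  Posteriors are prior-weighted normalized
densities computed in log space; priors default to empirical class
proportions (needed for a calibrated P(mal)), with a uniform-prior
flag recovering a pure maximum-likelihood rule.  Ties break by class
order; queries whose density underflows in every class are assigned to
the nearest class centroid with a warning.  This is a single-node
kernel discriminant: recursive partitioning around it (tree growing,
pruning, variable-importance scoring) is out of scope, as are random
forests.

## Bayesian accuracy estimator

Assuming one shared accuracy π across classes and a uniform prior,
`ΣX` correct of `N` gives the posterior `Beta(ΣX+1, N−ΣX+1)`, mean
`(ΣX+1)/(N+2)`, and equal-tailed credible intervals from the inverse
regularized incomplete beta (a bisection inversion is kept as the test
oracle).  The exact frequentist coverage of the 95% interval at
π = 0.8, N = 74 is 94.3%, and a 10,000-replicate simulation reproduces
it within Monte-Carlo error.  The shared-π assumption is deliberate:
per-class posteriors are not estimated.

## Synthetic data

**Wings.**  Each class is a fixed 19-point venation skeleton (six
polylines inside a half-elliptic outline) displaced by a
class-specific random direction of fixed magnitude δ (px); each sample
adds Gaussian jitter σ_w to the control points before rasterization at
3 px vein thickness with a 5·10⁻⁴ speckle rate.  Defaults mirror the
emulated study: 724 × 254 px frames and the 74-sample design (14
classes of five plus one of four); δ = 3 px with σ_w = 1 px gives a
strong but not trivial class separation at that resolution.  The
jittered control points double as paired landmarks.  Per-image
substreams are derived from the seed by counter, so samples are
independent of batch order, and a `sample_offset` yields fresh
held-out batches from the same class geometry.

**Masses.**  Both classes share an elliptical core
`r(θ) = r₀(1 + e·cos 2(θ−φ))`; malignant masses multiply it by the
spiculation profile `1 + a·|sin(kθ/2)|^γ` (defaults a = 0.35, k = 12,
γ = 1.5) and use a wide sigmoidal margin (0.35·r₀ versus 0.06·r₀ for
benign), embedded in correlated Gaussian background noise.  Setting
a = 0 and equal margins makes the class generators coincide exactly —
the null case.  Default prevalence is 48 benign / 52 malignant per
100, mirroring the emulated cohort.  Five categorical expert features
(BI-RADS-style assessment 0–5, mass shape, mass margin, breast density
1–4, subtlety 1–5) are drawn from class-conditional tables chosen so
that assessment is the most class-informative feature and density the
least (the exact mutual-information ordering is a tested property);
they are conditionally independent of the image given the class.

**What passing tests do and do not show.**  The generators reproduce
the *statistical structure* the pipeline assumes — class-specific
geometry with within-class jitter, margin/spiculation contrasts,
correlated categorical covariates — not the appearance of real slides
or film mammograms (no staining/lighting artefacts, no film grain or
scanner response, no anatomic background tissue, no annotation noise).
Pipeline recovery on these images demonstrates correctness of the
machinery and sensible effect-size behavior, not clinical or
taxonomic performance.

## Study designs and problem sizes

The wing study extracts pose-normalized Krawtchouk features (order
200 at the native 724 × 254 frame), Z-scores, takes 60 principal
components, fits LDA and the kernel discriminant, and reports the
training confusion matrix with its beta-posterior accuracy — training
performance is the designed readout at ~5 samples per class — plus a
landmark arm (alignment-standardized coordinates, 15 components).  The
mass study runs repeated stratified 70/30 splits (default 10); per
split, Krawtchouk and disk-moment feature blocks are each Z-scored and
top-1% |t|-selected on the training rows, concatenated, reduced by
Q-mode PCA (β = 0.95) and LDA, and classified by the kernel
discriminant.  P(mal) for *training* rows of the fusion models comes
from 5-fold out-of-fold prediction (in-sample probabilities would
leak); test rows use the split model directly.  Fusion models: I =
expert features + P(mal); II = expert features; III = expert features
with assessment replaced by P(mal); IV = expert features without
assessment.  Categorical features are one-hot encoded for the kernel
discriminant.  Metrics are reported as mean ± sd/√repeats.

Tests and the acceptance script run the studies at reduced problem
sizes chosen as the package's own desk-scale conditions: wings at
128 × 352 px, order 60, 40 components, the 74-sample design; masses at
96 × 96 px, orders 24 (Krawtchouk) and 12 (disk), n = 100 (n = 204 for
the null case, where dataset-level chance associations shrink with n),
10 repeats.  The full-scale wing configuration (724 × 254, order 200)
is exercised directly for feature extraction and basis stability.

## Known limitations

* Pose normalization assumes a well-defined principal axis and
  non-trivial mass; rotation-symmetric shapes fall back to an
  arbitrary axis.
* Disk moments use midpoint quadrature; moment error decays only
  linearly in grid resolution, so very high orders on small grids are
  quadrature-limited.
* The kernel discriminant treats one-hot categorical coordinates as
  continuous with diagonal bandwidths — a pragmatic stand-in for a
  learner with native categorical splits.
* Simple stratified splitting is used instead of plain random 70/30
  splits; this stabilizes small-class runs and is flagged in config.
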