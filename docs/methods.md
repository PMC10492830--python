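# Methods

This note documents the models implemented in `kerneltransfer`, the
assumptions behind them, the synthetic worlds they are validated on, and the
numerical choices that matter.

## Kernel machines

A fitted kernel regressor is `f(x) = alpha K(X, x)` with coefficients
`alpha` (one row per output) obtained from the training Gram matrix `K_n`:
ridge regression solves `(K_n + lambda I) alpha^T = Y`, and `lambda = 0`
takes the minimum-norm interpolant `alpha^T = K_n^+ Y`. The ridge is added
to the Gram diagonal unscaled by the sample count, so printed coefficient
magnitudes are comparable across set sizes.

Two kernels are provided:

* **Laplace kernel** `K(x, z) = exp(-||x - z||_2 / L)`, default bandwidth
  `L = 10` (in input-distance units). Two forms of this kernel circulate —
  bandwidth multiplying or dividing the distance; this package divides,
  matching the convention under which `L = 10` is a standard
  cross-validated choice for image-scale inputs.
* **Fully connected ReLU NTK** of an infinitely wide network with
  `depth` hidden layers, computed by the arc-cosine recursion
  (`kernels.py` docstring). An optional `offset` appends a constant bias
  feature (`Sigma^0 = x.z + 1`), the variant used for drug screening with
  `depth = 1`.

The recursion convention is pinned by an independent oracle: the exact
parameter-gradient inner products of finite-width ReLU networks (width
2^14 at depth 1, 2048 at depth 2, standard-normal parameters, computed by
backpropagation) are averaged over initializations and compared entrywise
with the recursion within three standard errors. Correlations are clamped
to [-1, 1] before `arccos`, and zero-norm inputs take the continuous limit
`lambda = 0`.

## Transfer operators

Given a frozen source predictor `f_s` and target data `(X_t, Y_t)`:

* **Projection** fits a head on source outputs: predict `f_p(f_s(x))` where
  `f_p` minimizes `||Y_t - f_p(f_s(X_t))||`. Effective when the source
  outputs already expose the target concept (e.g. target classes are unions
  of source classes).
* **Translation** adds a correction fit on residuals: predict
  `f_s(x) + f_c(x)` with `f_c` fit on `Y_t - f_s(X_t)`. Requires matching
  label dimensions; for linear models it is exactly fine-tuning started
  from the source weights (validated against a gradient-descent oracle to
  1e-6).
* **Combined** fits a head on the concatenation `[f_s(x) | x]`, subsuming
  both: an additive head recovers translation, dropping the feature block
  recovers projection (both identities are tested to 1e-8). The two blocks
  are concatenated without rescaling; in the drug-screening application
  both are in expression-comparable units.

Whenever a head fit is under-determined at ridge 0, the minimum-norm
solution is taken (pseudoinverse solves). Source models are never refit
during transfer. Classification decodes by argmax over one-hot outputs,
ties to the lowest class index. Source outputs are not standardized before
a kernel projection head (a documented switch point; the default follows
the raw-concatenation convention).

## Exact linear risk theory

In the linear world, source and target maps are `omega_s` (c_s x d) and
`omega_t` (c_t x d), inputs are isotropic on R^d (standard Gaussian here),
labels are noiseless, and every estimator is the minimum-norm least-squares
fit `w = y X^+` with columns-as-samples. The risk of an estimate `w` is
`E||omega_t x - w x||^2`, which under unit covariance equals
`E||omega_t - w||_F^2`; the Monte-Carlo oracle (`mc_risk`) uses that
identity per trial for variance reduction and draws fresh `X_s, X_t` each
trial. The closed forms implemented (and the regime `n_s, n_t <= d` they
are asserted in) are stated in `theory.py`; the task-similarity
`eps = ||omega_t (I - omega_s^+ omega_s)||_F^2` measures the part of the
target map unreachable from source outputs.

Validation status, established by the simulation oracle at 20000 trials
per cell over the grid d=16, n_s in {4,8,12,16}, n_t in {2,4,8},
c_s in {2,4,8}, eps in {0, 0.25}:

* the **baseline law** `(1 - n_t/d)||omega_t||^2` is exact (all cells
  within 3 SE, exact zero at n_t = d);
* the **translated risk** — a weighted average, with weight `n_s/d`, of the
  baseline risk and `(||omega_s - omega_t||^2 / ||omega_t||^2)` times it —
  is exact across the grid, including both endpoints (zero risk at
  `omega_s = omega_t, n_s = d`; baseline equality at `n_s = 0`);
* the **projected risk formula is an approximation, not an exact risk**.
  Its constants satisfy `E[P_s B P_s] = C1 I + C2 B`, where `P_s` is the
  projection onto the span of the source samples and `B = omega_s^+
  omega_s`; the formula is precisely the risk of the baseline estimate
  composed with the operator `P_s B P_s` *treated as an exact projection*
  (second moments replaced by first). That step is exact at `n_s = d`,
  where the formula matches direct simulation of the row-space-projected
  baseline (`mc_risk(..., "projected_rowspace")`) within 3 SE. Away from
  that boundary it matches no simulatable estimator we tested: the composed
  estimator `y_t (w_s X_t)^+ w_s` itself recovers `omega_t` exactly (risk
  0) whenever `n_s = d`, `eps = 0` and `n_t >= c_s`, a case in which the
  formula reports a strictly positive value, and in other cells the
  deviation reaches ~0.1 absolute at d=16 — orders of magnitude beyond
  Monte-Carlo error. The formula's qualitative structure (monotone benefit
  of source samples when tasks align; the class-count reversal when
  `2S - 1 - ST > 0`; the `(1-T)^2` vs `(1-T)` baseline comparison) is still
  informative and is what the asymptotic helpers expose.

The large-d limits at fixed `S = n_s/d, T = n_t/d, C = c_s/d` follow from
the constants' limits (`C1 -> SC(1-S)`, `C2 -> S^2`, `K1 -> 1 - T(1-C)`,
`K2 -> T(2-T)`); finite-d evaluation at d=2000 agrees with the S=1 limit
to 0.02% relative. The S-monotonicity predicate is exposed both as printed
(`eps < (1-C)||omega_t||_F`, which compares a squared norm with an
unsquared one) and in a homogeneous squared form, since the intended
homogeneity is ambiguous. For equal-norm `omega_s, omega_t`, solving
translated risk = baseline risk numerically locates the crossover at angle
pi/3 for any `n_s > 0` (`translated_crossover_angle`); a pi/4 threshold
sometimes quoted for this comparison does not follow from the implemented
closed form.

Monte-Carlo reproducibility: one root seed per experiment; trials are
drawn in fixed-size chunks from a single generator, so results are
bitwise reproducible for a given seed and trial count.

## Synthetic worlds

All benchmarks run on generated data; every generator is a pure function
of its seed and configuration.

**Linear tasks.** `gen_weights_with_epsilon` draws `omega_s` with
orthonormal rows (Haar via QR) and splits `omega_t` into in-row-space and
orthogonal components rescaled so the similarity `eps` and `||omega_t||^2`
are exact to 1e-8. Inputs are standard normal columns; labels noiseless.
Gaussian sampling is one convenient representative of the isotropic laws
the theory assumes.

**Clustered classification** emulates transfer from a fine-grained to a
coarse-grained recognition task: 20 source classes as Gaussian blobs
around unit-sphere centers in d=30 (spread controlled solely by
`cluster_sd = 0.35`), 5 target classes each the union of 4 source blobs,
n_s = 2000 source samples vs. n_t = 50 target samples, balanced classes.
Laplace models (L=10) with ridge 1e-4 for numerical stability of the
interpolating solves. Projected transfer wins against the direct target
fit in 20/20 seeds with a mean gain around 20 accuracy points.

**Drug screen** emulates expression imputation for held-out cell lines.
Latent cell vectors `u_c` and drug vectors `v_p` (dimension `rank = 6`)
generate control expression `G0 u_c` (50 genes), perturbed expression
`control + G(u_c * v_p) + noise` (sd 0.1), and 128-bit fingerprints by
sign-thresholding a random projection of `v_p` — a structural stand-in for
circular chemical fingerprints, not chemistry. The bilinear interaction
makes drug responses share structure across cell lines (what transfer can
exploit) while remaining cell-specific (what the correction must fix).
Feature rows are `[control | fingerprint]`. 12 cell lines x 80 drugs; 2
held-out cells; 15 held-out drugs form the unseen stratum; 25 training
drugs per held-out cell (nested prefixes of a per-seed permutation, so
learning curves vary only through the sample count). Models use the
depth-1 NTK with offset. Ridge coefficients are selected per seed by
cross-validated grid search over {1, 10, 100, 1000, 10000} — the selection
protocol itself, rather than any dataset-specific selected value, since
the appropriate magnitude scales with the Gram spectrum. The combined
projected+translated model beats both the direct NTK baseline and
mean-over-cell-line imputation on all three metrics (seen stratum) in 5/5
seeds, and the seen-drug gain exceeds the unseen-drug gain on average.

What these generators do **not** emulate: class imbalance, label noise,
non-Gaussian cluster geometry, batch effects, dose-response structure,
relatedness between fingerprint bits and mechanism, or the difficulty
heterogeneity of real images (see scaling laws below). Passing benchmarks
here demonstrates that the operators exploit shared structure when it is
present by construction — not performance on any real dataset.

## Screening metrics

For prediction/truth tables (rows samples, columns genes): Pearson r on
the flattened matrices without centering (hence scale-invariant); mean
per-sample R^2 against the sample's own mean over genes (constant truth
rows are excluded with a warning; negative values are averaged raw); and
mean per-sample cosine similarity after subtracting each group's (cell
line's) truth-mean vector from both matrices — centering on the truth mean
is the default, with a switch to center each matrix on its own mean, since
either reading is defensible. Zero-norm centered samples are excluded with
a warning. All three metrics equal 1 at pred = truth and are validated
against naive per-row loops to 1e-12.

## Scaling laws

Learning curves are summarized by ordinary least squares of score on
`log2 n` (`fit_log_law`), reporting slope, intercept and R^2 (defined as 1
when both residual and variance vanish). The committed curve protocols
average each point over 3 seeds and confine the grid to the rising,
pre-plateau regime of the corresponding benchmark, because a logarithmic
law can only describe a curve that has not saturated: classification uses
50 evenly spaced points n_t = 10..206 (the projected accuracy plateaus
near 0.75 beyond ~250) with a 2000-sample test set; the drug screen uses 8
log-spaced points n = 3..21 (plateau ~0.94 from ~28), scored by mean R^2
on the fixed unseen-drug stratum.

Measured on the committed configurations: classification curve R^2 0.93 -
0.99 across replicates (first replicate 0.956); drug-screen transfer and
baseline curves R^2 0.92 - 0.95. Extrapolating a fit of the smallest five
points to the final point, however, overshoots by 7 - 19 accuracy points
in most replicates: these synthetic curves are concave in log n (the
per-octave slope decays roughly twofold across the sampled range), so a
head fit systematically overpredicts. Near-perfect log-linearity over
decades — which makes such extrapolation accurate on large-scale image
benchmarks — appears to be a property of heterogeneous real data that
Gaussian-blob tasks at desk scale do not reproduce; widening the
within-task difficulty spectrum flattens but does not eliminate the slope
decay. The extrapolation helper is therefore exact on log-linear inputs
(unit-tested) while its accuracy on these synthetic curves is reported as
measured.

## Numerical choices

* Pseudoinverse rank cutoff: singular values below
  `max(rows, cols) * eps * sigma_max` are zero, everywhere.
* Ridge solves use Cholesky on `K + lambda I`, falling back to the
  pseudoinverse with a warning if the factorization fails.
* Square Gram matrices are symmetrized exactly; PSD is asserted in tests
  up to `-1e-8 * lambda_max`.
* Monte-Carlo risk grids use batched pseudoinverses over trial stacks
  (chunks of 2048) for speed; chunking does not affect the stream.
* Problem sizes throughout (d=16 grids, 20000 trials, n_s = 2000/3000,
  650-row drug tables) are chosen so the full validation suite runs in a
  few minutes on a single CPU while keeping Monte-Carlo error well below
  the effect sizes of interest.

## Known limitations

* The projected-risk closed form is approximate away from `n_s = d` (see
  above); its Monte-Carlo companion reports the true risk of the composed
  estimator, and both are exposed so the gap is visible rather than
  hidden.
* Convolutional NTKs, iterative large-scale solvers, and real datasets are
  out of scope; exact dense solves bound problem sizes to a few thousand
  samples.
* The drug-screen generator's bilinear response model is a deliberately
  simple mechanism for shared structure; its fingerprints carry no
  chemistry.
* Heads are fit by exact solves only; no stochastic training, data
  augmentation, or cross-entropy objectives.
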