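# Methods

## Model and estimator

Two data blocks `X1` (n × p) and `X2` (n × q) share their n samples.
After column standardization (mean 0, unit sample standard deviation
with divisor n−1; constant columns are rejected), a canonical component
is a pair of weight vectors (α, β) whose latent variables γ = X1α and
ζ = X2β are maximally correlated. Components are estimated one at a
time by an alternating least-squares (NIPALS) loop in which each
regression update is replaced — under the working approximation that
the within-block Gram matrices are identity, which is what makes the
update a plain cross-product — by a soft-thresholded cross-product:

1. γ ← X1α, scaled to unit norm;
2. β ← S(X2'γ, qβ); ζ ← X2β, unit norm;
3. α ← S(X1'ζ, pα); γ ← X1α, unit norm;
4. ρ ← cor(γ, ζ); stop when |ρ(t) − ρ(t−1)| ≤ tol.

`S(v, keep)` is rank-based soft-thresholding: with λ the (keep+1)-th
largest |v_i|, the top-`keep` entries by magnitude are shrunk to
sign(v_i)(|v_i| − λ) and the rest zeroed. It returns *exactly* `keep`
nonzeros except in two announced situations: fewer than `keep` entries
are nonzero to begin with, or entries are tied in magnitude exactly at
the boundary — ties are admitted in ascending index order and a tied
survivor shrinks to exactly zero (a `ThresholdTieWarning` is emitted;
with continuous data ties have probability zero). The absolute value in
the stopping rule terminates the tiny terminal oscillations that
thresholding can cause; the recorded ρ trajectory is otherwise
non-decreasing.

Later components are fitted after deflating each block by its own
latent variable in sample space, `X(k+1) = (I_n − γγ'/γ'γ) X(k)`
(equally ζ for X2). This projector makes successive fitted latent
variables exactly orthogonal; sparsity only breaks orthogonality of
the *weight vectors*, i.e. of latents recomputed on the original data.
Degenerate components (a weight vector thresholded to zero — no signal
at the requested sparsity) truncate the sequence with a warning rather
than raising. Each finished component is sign-normalized so its
largest-|α| entry is positive.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_alpha`, `q_beta` | — | exact nonzero counts per weight vector (1 ≤ pα ≤ p) |
| `k` | 1 | number of components; capped at min(p, q) |
| `tol` | 1e-6 | convergence threshold on the change of the in-sample correlation (dimensionless) |
| `max_iter` | 500 | iteration cap; exceeded fits are returned with `converged=False` |
| `init_mode` | `uniform_random` (fit), `decomposition` (path) | start vector for α: seeded i.i.d. uniform(−1, 1); constant 1/√p; or the leading right singular vector of the current (deflated) X1 |
| `folds` | 5 | cross-validation folds for the out-of-sample correlation |
| `b` | 100 | permutation count (minimum 19) |
| `alpha` | 0.05 | significance level for the max-statistic rule |

### Initialization and multiple attractors

The soft-thresholded iteration is not a contraction: it has multiple
exact fixed points, including mixtures of two underlying components
(verified numerically — a mixed support can be bit-stable under further
iteration at any tolerance). Under random initialization different runs,
and different sparsity levels of one path, can land in different basins,
which permutes or mixes the order of recovered components while still
recovering each signal. `fit_toscca` defaults to seeded uniform random
initialization, reproducible by seed; `fit_sparsity_path` defaults to
the decomposition start so that every level begins in the basin of the
same dominant component — without a common, data-driven start,
cross-level support comparisons (and the nestedness property below)
conflate basin choice with selection instability. The replicated
experiments in the acceptance script use the decomposition start for
the same reason: the significance pattern and plateau checks presuppose
that component k of the fit is the k-th strongest signal.

## Explained variance

CPEV after k components is tr(G_k'G_k)/tr(X'X) where G_k stacks the
first k latent variables. The latents in the numerator are the
*un-normalized* γ = X(original)·α with unit-norm weights: with
unit-norm latents the ratio would degenerate to k/tr(X'X) regardless of
the fit (that literal convention is still available via
`cpev(..., unit_norm_latents=True)` for comparability). The denominator
uses the original, not deflated, matrix, so the curve is non-decreasing
and the entries are fractions of total variance.

The adjusted CPEV multiplies CPEV(γk) by ∏_{i<k}(1 − |cor(γi, γk)|).
The correlations are taken between the components' *fitted* latent
variables (each from its own deflated matrix): deflation makes those
essentially orthogonal here, so for this estimator the adjustment is
typically negligible — which is precisely the diagnostic value of the
measure, since components produced without such a deflation scheme
(e.g. external weight tables fed to `cpev_adjusted`) are penalized in
proportion to the information they repeat. A perfectly duplicated
latent contributes nothing.

## Out-of-sample correlation and permutation testing

Sparse in-sample canonical correlations grow with the number of noise
variables admitted, so model assessment uses the out-of-sample
correlation: seeded K-fold cross-validation (default 5; a fold scheme
needs at least 2 held-out and 3 training samples), training-fold
standardization statistics applied to the held-out rows, fold weights
sign-aligned to the full-data fit before averaging. Folds whose
training fit is degenerate are recorded as missing and excluded from
the mean.

Component k is tested against the null of no cross-block association in
the matrices deflated by the observed components 1..k−1 (reusing the
observed deflation keeps one refit per permutation and matches the
sequential logic of the analysis). Each of the B permutations shuffles
the rows of the deflated X2 and refits a single component **at the
identical (pα, qβ)** — the property that makes permuted statistics
comparable; the equality is asserted at runtime. Observed statistic and
null draws are computed by the same deterministic function (one init
vector and one fold partition per component, both derived from the
seed), so under the null they are exchangeable and
p = (1 + #{null ≥ observed})/(B + 1) is valid (one-sided: the
alternative is positive by construction; the floor is 1/(B+1)).
Permutations are independent given their derived seeds and may run
concurrently with identical results. Multiplicity across the K
components is handled by Bonferroni (min(1, K·p)) or by the
max-statistic rule (compare every observed statistic to the
(1−α)-quantile of the null draws of the component with the largest
observed statistic).

## Synthetic data

The generator follows a sparse probabilistic-CCA factor model: per
component k a latent score z_k ~ N(0, sd_k²) per sample, blocks
X = Σ_k z_k w_k' + E with i.i.d. N(0, noise_sd²) residuals, loading
vectors nonzero on pairwise-disjoint supports with magnitudes uniform
on (0.5, 1.5) and random signs. Defaults — n=100, p=2500, q=500, three
components with support sizes (80, 50, 30) and (60, 40, 20), latent
scales (3, 2, 1.5), unit noise — put each planted signal well above the
noise floor while leaving component 4 of a K=4 fit pure noise. Latent
scales decrease strictly so the component order is identifiable;
`k_true=0` yields independent noise blocks for type-I experiments.

What the generator does *not* emulate: within-block correlation
structure beyond the factors (real omics blocks have correlated
features even under the null), overlapping or hierarchical supports,
heavy-tailed or discrete measurements, and batch structure. Passing
tests therefore demonstrate correctness of the machinery and
calibration under exchangeable rows, not robustness to those real-data
features — though the permutation test's validity argument only needs
row exchangeability of one block.

Recovery scoring matches estimated to true components greedily by
absolute latent correlation and reports support precision/recall/F1,
sign-agnostic cosine similarity of weights, and contamination (overlap
with *other* components' supports). Note that with the requested
support (100) larger than a true support s, F1 is capped at
2s/(100+s) by construction — recall is the informative recovery metric
in that regime, and the surplus weights sit near zero.

## Problem sizes in the validation runs

The replicated study uses 10 replicates at the full design with B=100
permutations and the out-of-sample statistic; the type-I experiment
uses 200 independent-noise replicates at n=50, p=200, q=100 with B=99
and sparsity (20, 10) (10% of each block); nestedness uses 10 seeds
over pα ∈ {25, 50, 100, 200} at fixed qβ=100; the dense-limit check
compares 25 instances at n=50, p=20, q=15 against the SVD at tolerance
1e-14. Together these run in roughly 15 minutes on one CPU.

## Known limitations

- Component order under random initialization is not guaranteed to
  follow signal strength (see the attractor discussion); the
  decomposition start removes this in practice but ties the result to
  the leading singular directions of X1.
- The identity-Gram approximation ignores within-block collinearity;
  strongly collinear blocks can spread a signal over correlated
  surrogates.
- The adjusted CPEV is a descriptive diagnostic; no automatic choice of
  K is made.
- p-values are permutation-exact only marginally per component; the
  sequential deflation makes later tests conditional on the earlier
  estimates.
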