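# Methods

## Profile representation

A protein of length R is represented by its R×20 position-specific
scoring matrix (PSSM). The package reads the PSI-BLAST ASCII dialect
(`-out_ascii_pssm`): header comment, a 20- or 40-letter column header,
one row per position, trailing K/λ statistics. Only the first 20
numeric columns — the log-odds block — are used; the percentage block
is ignored. This is a convention choice: nothing downstream depends on
which block is taken, but the log-odds scores are the conventional
profile representation. The column order A R N D C Q E G H I L K M F P
S T W Y V (PSI-BLAST order) is declared once in `ppilm.residues` and
shared by every matrix in the package.

Profiles can also be built from a row-stochastic frequency matrix and a
20×20 mutation matrix as d(u,v) = Σ_k p(u,k)·w(v,k). The default
mutation matrix is PAM250 from Biopython's curated collection;
"Dayhoff's matrix" is a family, not a single object, so the builder
accepts any 20×20 matrix and PAM250 is configuration, not behaviour.
Non-canonical residues (B, Z, X, U, …) are tolerated in sequences with
a warning and map to zero-score rows. No scaling or sigmoid is applied
to profile entries.

## Legendre-moment descriptor

The profile is treated as a piecewise-constant image f on [−1,1]²: rows
(sequence positions) on the x axis, the 20 amino-acid columns on the y
axis, cell-centered with Δx = 2/P, Δy = 2/Q (cell i has center
−1 + (i+½)Δx). The moment of order (m,n) is

    L_mn = μ_mn ∫∫ V_m(x)V_n(y) f(x,y) dx dy,  μ_mn = (2m+1)(2n+1)/4.

Because f is constant on cells, the integral is computed exactly from
the antiderivative identity ∫V_m = (V_{m+1} − V_{m−1})/(2m+1): per-cell
integral tables of shape (P, K) and (Q, K) with K = max_order+1 give
L = μ ∘ (Idxᵀ f Idy) at cost O(PQK²). Polynomials are evaluated by the
three-term recurrence (stable for the orders used here); V_{−1} ≡ 1 by
convention — it only ever appears inside differences of definite
integrals, where any constant cancels. An independent oracle
(`legendre_moments_naive`) integrates the same quantity by per-cell
Gauss–Legendre quadrature built on `scipy.special.eval_legendre`; the
two agree to better than 1e-8 on random profiles, which is the
package's defence against index-convention mistakes.

Choices worth stating:

- **max_order = 20** per axis, so the descriptor has 21² = 441 values;
  configurable. Flattening is row-major in (m,n) and identical at
  training and prediction time.
- **Axis orientation is fixed** (x ↔ positions). Moments are not
  symmetric in (m,n), so swapping axes changes the descriptor.
- **No padding/truncation**: the mapping to [−1,1]² makes the
  descriptor length-independent, so any R ≥ 1 is accepted as-is.
- **No pre-normalization** of the profile before moments; an optional
  min–max flag exists but defaults off.

## Pair vectors and PCA

A pair (a, b) is the concatenation [f_a ‖ f_b] (882 values), reduced to
100 principal components. The projection is **fitted on the training
fold only** and applied to the test fold; a `pca_global` escape hatch
exists to mimic the leaky variant but is off by default. Centering
only — no standardization — since all 882 coordinates are on the same
moment scale. Component signs are fixed deterministically (largest
|loading| positive). The concatenation is order-dependent; an optional
`swap_augment` flag adds the swapped copy of each training pair.

## PCVM classifier

Model: P(y=+1|x) = Ω(Σ_i w_i K_θ(x,x_i) + b) with K_θ(x,z) =
exp(−‖x−z‖²/θ²) and Ω the standard normal CDF. Each weight has a
truncated Gaussian prior 2N(w_i|0,α_i⁻¹) restricted to y_i w_i ≥ 0; the
bias has N(0, β⁻¹); the precisions have Gamma hyperpriors (shape/rate
defaults 1e-12, i.e. scale-free).

Fitting uses probit data augmentation. The E-step posterior mean of the
latent response is the truncated-normal mean z + y·N(z;0,1)/Ω(yz),
evaluated in log space so deep tails stay finite; the M-step is an
exact regularized least-squares solve for (w, b). Precisions are
adapted for `adapt_iter` (default 50) iterations with the fast ARD
update α_i ← (2c+γ_i)/(2d+w_i²), γ_i = 1 − α_iS_ii, where S is the
Gaussian posterior covariance from the solve; basis vectors whose
precision exceeds 1e6 are pruned. After the adaptation stage the
precisions are frozen and the EM runs to convergence (relative (w,b)
change < 1e-5, cap 500 total iterations); with fixed precisions the
penalized log posterior is strictly concave and provably non-decreasing
per iteration, which is the monotonicity property the tests assert.
After every solve, weights violating y_i w_i > 0 are dropped and the
reduced system re-solved until the constraint holds, so the
truncated-prior support condition is maintained at every iteration.

Why the two-stage design: the naive conditional expectation
α_i = 1/w_i² is aggressively self-reinforcing — when kernel columns are
correlated the weights spread thinly, every precision diverges at once
and the model collapses to an empty basis; conversely the fully
marginal update 1/(w_i²+S_ii) sparsifies far too slowly to prune
anything in a bounded run. The evidence-weighted γ factor
discriminates: well-supported weights keep finite precision, redundant
ones diverge and are pruned. Freezing the surviving precisions then
gives a concave final problem with a clean convergence guarantee.

Weights are initialized class-signed (w_i = y_i·0.01) so the sign
constraint holds at iteration 0; the first solve uses unit precisions
(seeding α from the deliberately tiny initial weights would prune
everything before the data are consulted).

The only free parameter is θ. Default: the median pairwise distance of
the training rows (median heuristic). Because EM converges to local
optima, the package also implements the multi-start selection protocol:
nine candidate widths (log-spaced over [1e-2, 1e2] by default — a
choice, since no canonical grid exists) are trained on each of five CV
training folds; each fold keeps its best-accuracy candidate (ties to
the smaller width) and the median of the five winners is returned.
Degenerate widths collapse to chance accuracy and are discarded by the
protocol itself.

## Evaluation

Acc = (TP+TN)/n, **Sn = TP/(TP+FN)**, Pe = TP/(TP+FP), MCC =
(TP·TN−FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). A zero denominator
yields NaN with a warning, never a silent 0, so averages are not
quietly inflated. AUC is the midrank Mann–Whitney statistic (verified
exactly against an exhaustive pair-count oracle). Cross-validation is
stratified (balanced classes per fold stabilize MCC) and shuffled with
a caller-supplied seed; the per-fold table plus mean ± SD is emitted in
the conventional layout. The decision threshold is 0.5 on the PCVM
probability; ROC uses the raw probabilities. The SVM comparison runs
`sklearn.svm.SVC` with c = 0.02, g = 0.03 on the identical reduced
features.

## Synthetic data generator

The generator emulates the geometry the descriptor consumes, not
protein evolution. Each protein's R×20 matrix is a sum of low-order
Legendre modes (orders ≤ 3 per axis, 16 coefficients) evaluated on the
descriptor's own cell-centered grid, plus N(0, σ²) white noise.
Proteins come in groups of 3 sharing a latent coefficient matrix drawn
with scale δ; members perturb it by σ. Positive pairs are sampled
within groups, negative pairs across groups, balanced 50/50, without
replacement over unordered pairs. Defaults: 1500 proteins, lengths
50–150, 2000 pairs, δ = 1.0, σ = 0.1 — an order of magnitude between
signal and noise, which is what "separable" means here; δ = 0 makes
the two classes identically distributed by construction.

Expressing the latent structure in the Legendre basis is deliberate:
the continuous moment of mode (m,n) with coefficient c is exactly c, so
the descriptor is provably sufficient for the synthetic task and a
classifier failure cannot be blamed on the features. What the generator
does **not** emulate: realistic amino-acid background frequencies,
alignment-depth-dependent profile noise, homology between proteins, or
the heavy-tailed degree distribution of real interaction networks.
Passing tests therefore demonstrate the pipeline's correctness and its
capacity to recover a planted similarity signal — not field performance
on real interactomes, which additionally depends on PSI-BLAST profiles
and curated gold standards.

Note on learnability: the pair signal ("the two halves of the
concatenation are correlated") is sample-hungry — positives lie near a
16-dimensional diagonal manifold of the latent space, and held-out
accuracy ≥ 0.9 emerges at roughly a thousand training pairs. Tests and
the acceptance script use 1000–2000 pairs for accuracy statements and
smaller sizes (120–500 pairs, shorter proteins) for structural and
determinism checks; those sizes are stated at each use.

## Numerical choices and degenerate inputs

- Kernel widths ≤ 0, single-class labels, non-finite features, empty
  pair lists, and PCA with n_components > n_samples are rejected with
  explicit errors.
- If EM fails to converge within the cap it warns with the iteration
  count and returns the current model (the width-selection protocol
  then discards such widths by accuracy).
- If every basis vector would be pruned, the least-violating one is
  retained at weight 0 with the bias set to the mean augmented
  response, so prediction degrades to the prior rather than crashing.
- All fits are deterministic given the configuration; the recorded seed
  only feeds fold shuffling and the median-heuristic subsample.

## Known limitations

- The blob and synthetic benchmarks are favourable geometry by design;
  no claim is made about DIP-style curated interactomes.
- The PCVM scales as O(N³) per adaptation iteration in the training-set
  size; beyond ~5000 pairs a basis-subset strategy would be needed.
- θ selection optimizes fold accuracy only; it does not trade off
  sparsity.
- The truncated-prior sign constraint is enforced by prune-and-resolve
  rather than a constrained quadratic program; the two coincide except
  in marginal cases where a weight sits exactly at zero.
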