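# Methods

## Model family

All factorizations minimize variants of

    f(A, Y) = 1/2 ||X − A Y||_F² + penalties,    X ∈ R^{m×n}, A ∈ R^{m×k}, Y ∈ R^{k×n},

with samples in columns and features (genes) in rows.  The Gaussian-error
reading of the Frobenius objective is what justifies least-squares fitting;
non-negativity encodes the additive-parts assumption appropriate for
expression data.  The unified sparse model (VSMF) adds
Σᵢ(α₂/2‖aᵢ‖₂² + α₁‖aᵢ‖₁) + Σᵢ(λ₂/2‖yᵢ‖₂² + λ₁‖yᵢ‖₁) with boolean switches
t₁, t₂ for the non-negativity of A and Y; standard NMF (α = λ = 0,
t₁ = t₂ = 1), semi-NMF (t₁ = 0), and sparse NMF (λ₁ > 0) are special cases.
The classic sparse-NMF objective with η/2‖A‖_F² and squared-ℓ1 column
penalties is kept as a separate variant (`variant="kim_park"`); the squared
form is implemented as published, with `squared_l1=False` switching to a
plain ℓ1 sum, since the two appear interchangeably in the literature.

## Optimization

Two engines per model where meaningful:

* **Multiplicative rules** — monotone (objective non-increasing), cheap per
  iteration, zeros approached only asymptotically.  Denominators are guarded
  by `max(·, 1e-9)` rather than an additive ε so that exact fixed points
  (X = AY) remain exact.
* **Exact alternating steps** — every block subproblem is solved to
  optimality by an active-set non-negative QP solver (Lawson–Hanson style,
  warm-started across columns, ridge 1e-12·tr(H)/p on rank-deficient
  Hessians, per-column iteration cap 3p, one step of iterative refinement on
  the final passive-set solve).  Sign-free ℓ1 blocks use the u − v split to
  an NNQP of doubled size.  Zeros are exact and each returned column carries
  a KKT certificate (dual feasibility and complementarity within 1e-8).

Initialization is A, Y ~ U(0,1)·√(mean|X|/k) from a seeded generator;
`FitOptions` also accepts user-provided factors and, for semi-NMF, a k-means
cluster-indicator start (see *Identifiability*).  Convergence is declared at
relative objective change < 1e-6 (default) or 500 iterations; optional
multi-restart keeps the best objective.  A basis column that collapses to
zero is re-seeded from the largest-norm residual column so the effective
rank stays k.

Order of block updates: the Y-step precedes the A-step in the alternating
NNLS variants.  This makes the λ = 0 sparse model traverse the same iterate
sequence as plain alternating NNLS up to a per-column rescaling of A (the
unit-norm constraint commutes with the NNLS refit), which is also the basis
of the reduction checks in the test suite.

Orthogonal NMF uses the square-rooted tri-factor rules; the factors start
from column-normalized (A) and row-normalized (Y) uniform draws with
S = AᵀXYᵀ, which keeps the rules numerically monotone — from unnormalized
starts the first iterations can overshoot.  Orthogonality is soft: the
deviations ‖AᵀA − I‖_F and ‖YYᵀ − I‖_F are reported, not enforced.

Convex NMF is initialized from a seeded k-means partition (indicator + 0.2
smoothing, per the original recipe) and its W columns are renormalized to
sum one each iteration with the scale pushed into Y, so the product — and
hence the objective trace — is unaffected by the normalization.

## Kernelization

Semi-NMF's updates need X only through AᵀA = (Y‡)ᵀ XᵀX Y‡ and
AᵀX = (Y‡)ᵀ XᵀX with Y‡ = Yᵀ(YYᵀ)⁻¹, so XᵀX can be replaced by any kernel
matrix; the basis lives implicitly in feature space and is never formed.
YYᵀ inversions add ridge 1e-10·tr when near-singular.  Kernel matrices must
be symmetric within 1e-8; eigenvalues in (−1e-8·λmax, 0) are clipped to
zero, more negative ones are an error.  The RBF width σ defaults to the
median pairwise distance of the data it is first applied to.  The
linear-kernel equivalence (K = XᵀX reproduces the linear algorithm iterate
by iterate) is the correctness argument for the kernel rules and is asserted
in the tests rather than taken on faith.

## Identifiability and the recovery checks

Separable planted structure (factor-exclusive rows in A and columns in Y)
makes standard NMF identifiable up to permutation and scaling, and the
planted factors are recovered to correlation > 0.99 at zero residual.
Semi-NMF is different: for any non-negative invertible T, (A T⁻¹, T Y) is an
equally good solution, so no optimizer can be expected to recover planted
factors from a random start — measured correlations scatter over 0.5–0.98 at
numerically zero residual.  The package therefore follows the semi-NMF
literature and offers a k-means cluster-indicator initialization
(`init="kmeans"`); started there, and with planted coefficients that have
disjoint cluster support, the sparse cluster-structured optimum is reached
and recovery is exact.  This is a statement about the optimization
landscape, not a flaw of the implementation; real-data use of semi-NMF
should likewise start from a clustering.

## Mining layer

* **Clustering**: label = argmax row of each coefficient column (ties to the
  lowest index); invariant to positive per-column rescaling.
* **Rank selection**: consensus matrix C over seeded restarts (hard argmax
  co-clustering), scored by the dispersion ρ = (1/n²)ΣΣ4(C−½)².  Ties in ρ
  go to the **larger** k: merging well-separated clusters is always stable,
  so k = 2 would otherwise win degenerately on clean data.  The selection
  study condition is separation ≈ 5 noise-sd (signal amplitude ~2.5, noise
  variance 0.25), where the true rank uniquely maximizes ρ.
* **Biclustering**: factor q pairs its argmax samples with features whose
  basis weight exceeds mean + z·sd of column q (default z = 1).  Exact block
  recovery holds when loaded rows are a minority of the column (unexpressed
  features present) — with an exact 50/50 split the mean + sd threshold sits
  on the block value and membership is boundary-dependent.
* **Feature extraction**: Eq. X ≈ A Y_tr on training data; unknowns are
  projected by NNLS (kernel path: through K(X, S) only).
* **Entropy selection**: row weights p(i,q) = A_iq/Σ_q A_iq, score
  1 + (1/log₂k)Σ p log₂ p ∈ [0,1] (1 = one-hot, 0 = uniform), threshold
  mean + z·sd (default z = 2).  The threshold presumes markers are a small
  minority of features; all-zero rows are excluded and reported.

## Classifier

Training samples are the basis; prediction solves
min_{y≥0} ½‖s − X_tr y‖² + λ‖y‖₁ per unknown, from inner products only.
Decision rules: minimum class-restricted reconstruction residual (default,
the sparse-representation convention) or maximum class coefficient sum; λ
defaults to 0.  Missing values are never imputed: each pairwise inner
product is taken over the features observed in both samples after rescaling
both restrictions to unit ℓ2 norm.  The resulting "Gram" matrix need not be
PSD (each entry lives on a different subspace), so it is projected onto the
PSD cone by eigenvalue clipping before the QP — without this the active-set
method has no convergence guarantee.  A pair of samples with disjoint
observed features is a hard error; the probability of such a pair decays
like (1 − (1−r)²)^m, so high missingness rates r require high-dimensional
data (the robustness protocols use m = 100–200 features for r up to 0.7).
Cross-validation is stratified k-fold (scikit-learn splitters), repeated with
per-run derived seeds, degrading to plain k-fold with a warning when a class
is smaller than the fold count.  Robustness protocols: additive Gaussian
noise of variance 0–4 (step 0.5) with a 1-nearest-neighbour baseline, and
uniform random masking of exactly round(r·m·n) entries for r ∈ [0.1, 0.7],
comparing the ignore strategy with zero imputation.

## Comparison statistics

* **Minimum significant size**: for each candidate n, mean held-out accuracy
  over `reps` random training subsets (each containing every class) is
  compared with a label-permutation null (default 200 permutations, add-one
  p-value).  The smallest n with p < α is returned.
* **Learning curve**: e(n) = a·n^(−α) + b fitted by bounded least squares
  (a ≥ 0, α ∈ (0, 3], b ∈ [0, 1)), initialized from a log-log regression of
  errors − min + ε; exact on noiseless data.
* **Friedman test**: per-dataset ranks (ties averaged),
  χ²_F = 12N/(k(k+1))[ΣR_j² − k(k+1)²/4] against chi-square with k − 1 df;
  the Iman–Davenport F refinement is reported alongside.  The chi-square
  form's null rejection rate at k = 4, N = 10 measures ≈ 0.04–0.05, inside
  the nominal band.
* **Nemenyi CD**: q_α = studentized-range quantile at df = ∞ over √2
  (scipy's `studentized_range`; q_.05(2)/√2 = 1.960, q_.05(8)/√2 = 3.031,
  matching published tables and an independent numerical integration of the
  range distribution in the tests).  The CD diagram connects maximal groups
  whose mean-rank span is within one CD.

## Synthetic data

The generator plants: a basis with `factor_specific_features` one-hot rows
per factor (amplitude ~ U(1, 3)) over a weak uniform background (0.1),
cluster-indicator coefficients with the same background, optional Gaussian
noise (variance 0–4 is the meaningful range for the classifier protocol;
negatives clipped in non-negative mode), and exactly round(rate·m·n) NaN
cells.  It emulates the block structure of subtype-labelled expression data;
it does not emulate heavy-tailed count noise, batch effects, or correlated
gene modules, so passing recovery tests shows algorithmic correctness on
identifiable inputs, not robustness to those real-data phenomena.  Defaults
(m = 50, n = 30, k = 3, 10 specific features per factor, no noise or
missingness) give a clean identifiable instance; the experiment scripts set
sizes per protocol, chosen at desk scale (tens of features/samples, 20
seeds/restarts) so the full suite and the acceptance script each run in
minutes on one CPU.

## Known limitations

* Multiplicative rules converge slowly near zeros and can stall in local
  minima (e.g. factorizing a diagonal matrix needs restarts); the
  alternating-NNLS engines are the recommended default.
* Semi-NMF and convex NMF factors are identifiable only up to non-negative
  mixing; interpret single-run factors with care (see *Identifiability*).
* The dispersion tie-break toward larger k assumes candidate ranks are
  scanned over a modest range; very large k with tiny clusters can still be
  spuriously stable on noiseless data.
* The missing-value inner products assume values are missing at random;
  informative missingness biases the normalized products.
* Kernel NNLS classification requires complete data — the common-support
  trick is specific to the linear inner product.
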