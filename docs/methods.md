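# Methods

## Model

`prenetfa` fits the oblique common-factor model for a centred p-vector X,

    X = Λ F + ε,    Cov(F) = Φ,   Cov(ε) = Ψ = diag(ψ_1, …, ψ_p),

so the implied covariance is Σ(θ) = ΛΦΛᵀ + Ψ with θ = (Λ, Φ, Ψ).  Λ is the
p×m loading matrix, Φ an m×m factor correlation matrix (fixed to I for
orthogonal models), and the ψ_i > 0 are unique variances.  Estimation
minimizes the maximum-likelihood discrepancy

    ℓ_DF(θ) = ½ { tr(Σ⁻¹S) − log|Σ⁻¹S| − p },

which is nonnegative and zero exactly when Σ = S, plus a penalty ρ·P(Λ).

## The prenet penalty

The prenet (product-based elastic net) penalty acts on within-row *pairs*
of loadings:

    P(Λ) = Σ_i Σ_{j<k} { γ |λ_ij λ_ik| + ½(1−γ)(λ_ij λ_ik)² },  γ ∈ (0, 1].

Because each term involves a product, P vanishes on any loading matrix with
at most one nonzero per row (a *perfect simple structure*, PSS).  Two limits
characterize its behaviour:

* ρ → ∞: the fit collapses onto the PSS manifold rather than onto Λ = 0,
  yielding a hard clustering of variables (variable i belongs to the cluster
  of its single surviving column).  Under Ψ = αI and orthonormal Λ this is a
  generalization of k-means clustering of the *columns* of the data matrix,
  whose objective has an exact covariance-only form that the package verifies
  numerically on every evaluation.
* γ → 0: P(Λ) → ½·quartimin(Λ) = ½ Σ_i Σ_{j<k} (λ_ij λ_ik)², so small-γ,
  small-ρ fits approach the quartimin-rotated maximum-likelihood solution
  (the factor ½ does not move minimizers).

Element-wise penalties are provided for comparison: lasso (Σ|λ|), elastic
net (γΣ|λ| + ½(1−γ)Σλ²) and MCP with concavity γ > 1, whose ρ-scaled form is
returned as a single object (the generic objective must not multiply it by ρ
again).

An optional stabilizer −ζ·log|Φ| (default ζ = 0, conventionally 0.01 when
used) is added to the reported objective for oblique element-wise fits,
whose factor correlations can otherwise diverge toward |Φ| → 0; the sign is
chosen so that near-singular Φ is penalized, which is the stabilizing
direction in a minimized objective.  ζ does not enter the Φ update.

## Algorithm

Fitting uses a generalized EM algorithm with the factors as missing data.
The E-step computes, with M = ΦΛᵀΣ⁻¹,

    B = S Mᵀ  (p×m),    A = M S Mᵀ + Φ − M Λ Φ  (m×m),

after which the expected complete-data loss separates over the rows λ_i of
Λ: row i contributes (s_ii − 2λ_iᵀb_i + λ_iᵀAλ_i)/(2ψ_i) + ρP_i(λ_i).  The
M-step runs one cyclic coordinate-descent sweep per row.  For the prenet,

    λ_ij ← Soft(b_ij − Σ_{k≠j} a_jk λ_ik,  ρ ψ_i γ Σ_{k≠j}|λ_ik|)
           / (a_jj + ρ ψ_i (1−γ) Σ_{k≠j} λ_ik²),

the exact minimizer of the (convex) coordinate problem.  Lasso and elastic
net use the corresponding soft-thresholding forms; MCP uses firm
thresholding when the coordinate problem is convex (a_jj > ψ_i/γ) and an
exact piecewise-quadratic candidate search otherwise (the minimum of a
piecewise quadratic lies at a stationary point of a piece or at a kink, so
no grid is needed).  A key property of the prenet update is that a row
whose other entries are zero receives the *unshrunk* value b_ij/a_jj — the
mechanism by which one large loading per row survives arbitrary ρ.

Unique variances update as ψ_i = max(s_ii − 2λ_iᵀb_i + λ_iᵀAλ_i, 10⁻³);
the floor guards against Heywood collapse and hits are logged and counted.
For oblique fits the correlation update candidate is Φ = D^{−1/2} A D^{−1/2}
(D = diag A), accepted only when it does not increase the EM surrogate
½(log|Φ| + tr(Φ⁻¹A)) − ζ log|Φ| — a generalized-EM acceptance rule that
preserves the monotone-descent guarantee the plain rescaling lacks.  Every
step weakly decreases the penalized discrepancy; the objective trace is
checked to be non-increasing (10⁻⁹ slack) in the test suite.

Convergence: relative objective change < 10⁻⁷, at most 1000 iterations,
one coordinate sweep per M-step.  Non-convergence returns the last iterate
flagged, never an exception.  Cold starts draw Λ entries iid U(−1,1) scaled
by √(s_ii/m), with Ψ = diag(S)/2 and Φ = I.

### Large-ρ (PSS) solver

As ρ → ∞ the penalty forces P(Λ) = 0, and the M-step row problem has a
closed form: place the single nonzero of row i at j = argmax_k b_ik²/a_kk
(smallest index on ties) with value b_ij/a_jj, all other entries exactly
zero.  Because the large-ρ problem is multimodal (like k-means), `fit_pss`
runs from 10 random starts by default and keeps the lowest-discrepancy fit.
Its output satisfies the one-nonzero-per-row property with *exact* zeros.

## Regularization path and model selection

From the PSS fit, the smallest pattern-preserving weight has a closed form
derived from the coordinate-descent threshold condition:

    ρ_max = max_i max_{k≠j} |b_ik − a_kj λ̂_ij| / (γ ψ_i |λ̂_ij|),

over rows i loaded on column j (all-zero rows impose no constraint and are
skipped; if every cross statistic vanishes — e.g. a PSS fit that collapsed
onto fewer columns — ρ_max is 0, and the path anchors instead at the
threshold scale max|b_ij|/(γψ_i), the only remaining scale in the problem).
The grid holds K = 30 log-equispaced values from ρ_max down to
ρ_max·Δ·√γ with Δ = 0.001; the √γ factor keeps the low end useful for
small γ.  Warm starts march down the grid, reusing each solution as the
next initial value, with the PSS fit itself serving as the top-of-grid
prenet solution (at ρ ≥ ρ_max the penalized and PSS problems coincide).
Cold starts refit every grid point from fresh random initials — slower, and
occasionally better at multimodal small-ρ points, which is why the
warm-vs-cold comparison in the tests is a majority check, not a uniform one.
Element-wise families have no finite PSS point and the null model Λ = 0 is
an EM fixed point (B = 0 there), so their paths reuse the prenet anchor as
a comparably strong shrinkage level and fit the top point by multi-start.

ρ is selected by AIC = 2n·ℓ_DF(θ̂) + 2p₀ or BIC = 2n·ℓ_DF(θ̂) + p₀·log n,
where p₀ counts nonzero loadings (|λ| > 10⁻¹⁰; coordinate descent produces
exact zeros) plus the p unique variances plus m(m−1)/2 correlations for
oblique fits.  These differ from −2·loglik + penalty only by the
saturated-model constant, so rankings are identical — the form used here
makes the loss term explicitly nonnegative.  Ties break toward the largest
ρ (the sparsest fit).  Columns shrunk entirely to zero reduce the effective
number of factors, reported alongside the selection.

K-fold cross-validation scores each ρ by the held-out Gaussian loss
½(log|Σ̂| + tr(Σ̂⁻¹ S_test)) on a grid shared across folds (anchored at the
full-data ρ_max).  This equals the held-out discrepancy up to a
ρ-independent constant and, unlike the discrepancy itself, is defined when
the held-out covariance is singular (n_test ≤ p, the common case for
ten-fold splits of moderate samples).

## Synthetic designs

The generators reproduce the package's four study conditions exactly:

* **A-ORT** — p = 100, m = 4; Λ = blockdiag(0.8, 0.7, 0.6, 0.5) ⊗ 1₂₅
  (each value repeated for 25 variables), Φ = I.  A perfect simple
  structure, so the true variable partition is the 4×25 block split and the
  true nonzero rate is exactly 0.25.
* **A-OBL** — same Λ, all Φ off-diagonals 0.4.  With one nonzero per row,
  diag(ΛΦΛᵀ) is unchanged, so A-ORT and A-OBL share identical Ψ.
* **B** — A's zeros replaced by iid U(−0.3, 0.3) draws, redrawn per
  replicate: the cross loadings are treated as part of the generating model,
  not a fixed unknown.  Close to, but not exactly, a PSS.
* **C** — a fixed, sparse 26×3 matrix (a rotated centroid solution of the
  classical box problem, rescaled by 0.83 with entries below 0.1 zeroed),
  sparse but more complex than a PSS.

All designs set Ψ = diag(I − ΛΦΛᵀ), so the population covariance is a
correlation matrix; data are iid N(0, Σ).  What the generators deliberately
do **not** emulate: non-Gaussian or ordinal responses, missing data,
model-misspecified uniqueness structure, and n ≪ p regimes.  Passing tests
therefore demonstrate correctness of the estimator and its selection
machinery under the stated Gaussian designs, not robustness to survey-style
data pathologies.

## Monte-Carlo harness and metrics

Each replicate draws a sample, fits a path (or the PSS fit), selects ρ,
aligns the estimate to the truth over all m!·2^m signed column permutations
(exact for m ≤ 8), and scores: squared error ‖Λ − Λ̂‖²_F/(pm), nonzero
rate, TPR/FPR over the true zero pattern, exact-pattern recovery, and the
adjusted Rand index between the estimated and true variable partitions
(all-zero rows are excluded pairwise from the ARI and counted).  The
aggregated RMSE follows the convention (1/T)·(Σ_s ‖Λ − Λ̂⁽ˢ⁾‖²_F/(pm))^{1/2}
— sum inside the root, then divided by T — with 5th/95th percentile bands
of the per-replicate root errors.  Dense ρ → +0 fits are hard-thresholded
at 0.1 before zero/nonzero counts (they never produce exact zeros); the
threshold is caller-controlled and off by default for penalized fits.
Desk-scale runs use T = 20 replicates; the harness accepts T = 1000.

## Numerical choices and limitations

* Zero tolerance 10⁻¹⁰ for "nonzero" decisions; coordinate descent and the
  PSS M-step produce exact zeros, so this only guards floating-point noise.
* ψ floor 10⁻³; Φ candidate rejected if A is not positive definite.
* Ties: argmax-based cluster assignment and the PSS column choice both take
  the smallest index; model selection takes the largest ρ.
* The EM attains local minima only; multimodality is handled by multi-start
  (PSS, cold paths), not guaranteed global optimization.
* Exhaustive alignment is limited to m ≤ 8 factors by design.
* The quartimin-limit checks compare against a gradient-projection rotation
  of the population maximum-likelihood loadings; agreement is asserted
  element-wise to 0.05 on the near-simple population design, and the
  penalty-level comparison at γ = 0.01 uses design-scale (40×4) standard
  normal matrices, where the pairwise product sums are concentrated enough
  for the 2% relative band to be meaningful.
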