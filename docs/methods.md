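# Methods

## Model

We estimate a shared coefficient matrix W ∈ R^{p×t} over t temporally
ordered tasks by minimizing

L(W) + λ₁‖WR‖₁ + λ₂‖WR‖₁,₂ + λ₃‖(WRH)ᵀ‖₁,

where R = R(α) is the temporal structure matrix and H the t×(t−1)
consecutive-difference operator (H[j,j] = +1, H[j+1,j] = −1; this is the
only orientation consistent with a t×(t−1) shape and with right-
multiplication forming column differences). The model's core assumption is
that the state at each time point depends on *all* previous time points
with geometrically decaying influence, not only on the adjacent one:
column i of WR mixes task i with history through the recursion
w̄ᵢ = α·w̄ᵢ₋₁ + (1−α)·wᵢ. Columns of R therefore sum to one and are
non-decreasing over their support — each temporal task is a convex
combination of raw tasks, with nearer time points weighted more heavily.
The cap α ≤ ½ encodes that the current time point always carries at least
as much weight as all history combined. R is upper triangular with
determinant (1−α)^{t−1}, hence invertible for every admissible α; the
inverse is computed once per fit by triangular back-substitution and
cached.

An optional Laplacian-type smoothness penalty ‖WRH‖_F² can be formed from
the same operators for ablation, but the fused (L1) form is the default:
it yields piecewise-constant coefficient profiles, which matches how
feature relevance switches on and off across disease stages.

## Loss conventions

Two conventions matter when comparing λ values with other software:

* squared loss carries a global ½: L(W) = ½·Σᵢ‖X_i w_i − y_i‖²;
* logistic loss and gradient are both normalized by 1/n_i per task:
  L(W) = Σᵢ (1/nᵢ)·Σⱼ log(1 + exp(−y_ij·x_ijᵀw_i)), computed via
  `logaddexp` so extreme margins neither overflow nor lose precision.

These choices make the two solvers minimize the identical function (so
their solutions are directly comparable) and keep λ's meaning stable
across task sizes in classification.

## Proximal operators

The reparameterization Q = WR makes the penalty separable across rows of
Q. The per-row prox of λ₁‖·‖₁ + λ₂‖·‖₂ + λ₃·TV decomposes exactly as
group-shrinkage ∘ soft-threshold ∘ TV-prox, *in that order*; the reverse
composition is not a prox and the test suite exhibits a witness where it
differs. The 1-D total-variation prox uses a direct single-pass
taut-string-style algorithm — exact and non-iterative, O(t) in the typical
case — chosen over iterative TV solvers because t (number of time points)
is small and exactness keeps the decomposition identity testable to
floating-point accuracy. The zero vector is mapped to zero by group
shrinkage (the subdifferential-consistent choice).

## Accelerated proximal-gradient solver (`agm`)

Standard two-sequence accelerated scheme with momentum
t₀ = 1, tᵢ = ½(1 + √(4tᵢ₋₁² + 1)), αᵢ = (tᵢ₋₁ − 1)/tᵢ. The smooth part in
Q-space is Q ↦ L(QR⁻¹) with gradient (∇_W L)·R⁻ᵀ. The initial step uses
the Lipschitz bound σ_X²·σ_max(R⁻¹)², where σ_X is the largest per-task
top singular value (σ_X²/(4nᵢ) per task for logistic loss); backtracking
(doubling L until the quadratic upper bound holds) remains on by default
because the bound, though valid, can be loose.

Plain acceleration is not monotone, so the solver uses the objective-
safeguarded (monotone) variant: the prox output drives the momentum
sequence, but the reported iterate keeps the previous point whenever the
objective would rise. When no safeguard triggers — the common case — the
iteration is exactly the plain accelerated scheme. A safeguarded step
leaves the monitored objective unchanged, so convergence (relative
objective change < `tol`, default 1e-4; an absolute criterion is available
via `criterion="absolute"`) is only certified on improving steps.
Initialization is Q₀ = 0, the conventional sparse-regression start. The
solver is fully deterministic.

## ADMM solver (`admm`)

Splitting A = WR, B = WRH with scaled duals C, D and penalty ρ (default 1;
0.01–5 is the useful range — ρ affects the iteration count, not the fixed
point, and the test suite checks this). The W-update linearizes the
column coupling M = RRᵀ + NNᵀ (N = RH) Jacobi-style: off-diagonal terms
are evaluated at the previous iterate, leaving t independent systems
V_i w_i = q_i with V_i = X_iᵀX_i + ρ(1 + M_ii)I, factorized by Cholesky
once per fit. The ρI inside V_i is a proximal damping term, so q_i
carries the matching center + ρ·w_i^k; without it the update's fixed
point is not a stationary point of the augmented Lagrangian (the solver
then stalls ~0.4% above the optimum on small test instances — this was
verified numerically before fixing the right-hand side). A-updates use
the row-wise sparse-group prox at weights λ₁/ρ, λ₂/ρ; B-updates are
elementwise soft-thresholds at λ₃/ρ. Stopping requires both the primal
residual ‖WR−A‖_F + ‖WRH−B‖_F and the dual residual
‖ρΔA + ρΔB·Hᵀ‖_F below `tol` (default 1e-4 absolute). For classification
the W-block is minimized by L-BFGS (inner tolerance 1e-6, ≤ 50
iterations) with the analytic logistic-plus-quadratic gradient.

## Metrics and cross-validation

nMSE divides each task's squared test error by the *population* variance
(divide by nᵢ) of the true test targets and pools over all samples. The
population convention is chosen so the per-task-mean predictor scores
exactly 1 — an identity the tests assert. Classification uses pooled
accuracy on ±1 labels; a decision score of exactly 0 predicts +1
(arbitrary, documented).

Cross-validation splits each task independently into k shuffled folds
(seeded), so unequal nᵢ are handled naturally and no model is ever scored
on samples it saw during fitting. The full grid spans 10⁻³…10⁴ by decades
for each λ with α ∈ {0.01, 0.02, 0.05, 0.1, 0.15, …, 0.5}; because that
4-D search is expensive, the default `coarse` preset keeps λ ∈ {0.1, 1, 10}
and α ∈ {0.1, 0.3, 0.5} — mid-decade coverage matched to the loss scale of
standardized features at n ≈ 10²).

## Synthetic generator

The generator emulates the longitudinal regime the model targets: i.i.d.
standard-normal designs over p shared features; per-time-point sample
counts that decline with follow-up (default (120, 110, 100, 90, 60, 50),
mimicking cohort attrition); a small set of rows active at every time
point whose values follow a seeded random walk with step `smooth_step`
(so column drift scales linearly with it — asserted); optional rows
active at a single time point; Gaussian target noise for regression; and
labels drawn from the logistic model at the true scores for
classification, matching the loss the solvers optimize (rather than
sign-plus-flip noise). What it does *not* emulate: correlated or
non-Gaussian features, missing data, within-subject dependence across
visits, and covariate shift over time — so passing recovery tests show
algorithmic correctness under the model's own assumptions, not robustness
to real cohort messiness.

## Recovery study

The end-to-end experiment (p = 30, t = 5, nᵢ = 100, 6 shared rows, drift
0.1, noise 0.5, 10 seeds) tunes (λ₁, λ₂, λ₃, α) by coarse 5-fold CV,
fits, and compares ‖Ŵ−W*‖_F against independent per-task ridge tuned by
its own per-task 5-fold CV over λ ∈ {0.01, …, 100}. Support recovery
counts a feature row as selected when its largest entry exceeds twice the
per-coefficient estimation noise floor, 2·σ/√n̄ (0.1 under the study
conditions): at the prediction-optimal λ the L1 stage shrinks null rows
to magnitudes at or below that floor rather than to exact zeros, and
entries indistinguishable from estimation noise are not meaningfully
"selected". Problem sizes throughout the suite (p ≤ 30, t ≤ 6, nᵢ ≤ 120)
were chosen to exercise every code path at desk scale.

## Numerical choices and limitations

* R inversion rejects numerically singular input (zero diagonal); α < 1
  always holds in-range so this only guards malformed matrices.
* AGM aborts with a diagnostic if the objective becomes non-finite or the
  backtracked L exceeds 10¹⁸; ADMM aborts on non-finite iterates.
* Ties at zero in soft-thresholding produce exact zeros, so reported
  supports are exact at the Q level; row supports of W equal those of Q
  because R is invertible and triangular.
* The ADMM dual residual follows the plain form ‖ρΔA + ρΔB·Hᵀ‖_F (no Rᵀ
  weighting on the A-term); with tight tolerances this only changes when
  stopping occurs, not the fixed point.
* Known limitations: no intercept handling (center targets or include a
  constant column), no missing-data support, no per-gap αᵢ (a single α
  governs all gaps), and the Laplacian smoothness variant is exposed only
  through the penalty components, not as a CLI option.
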