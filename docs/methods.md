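# Methods

## Model

Given M views of the same N samples, each represented as a symmetric
weighted adjacency A_m with combinatorial Laplacian L_m = D_m − A_m, the
method minimises

f(X) = Tr(Xᵀ L X),  L = blockdiag(L_1,…,L_M) − β_couple (J − I) ⊗ I_N,

over per-view orthonormal blocks X_m ∈ R^{N×K} (XmᵀXm = I_K), where J is
the all-ones M×M matrix.  The block-diagonal part is the usual spectral
relaxation of per-view ratio cut; the off-diagonal coupling
−β_couple Σ_{m≠h} Tr(XmᵀXh) rewards alignment of the view embeddings.
Minimising over a product of Stiefel manifolds (one constraint per view,
not one for the stacked X) is what preserves per-view cluster structure:
the relaxation to a single stacked constraint would discard exactly the
view-specific information the method is designed to keep.

The coupled matrix is never assembled; `apply_block_operator` computes
(LX)_m = L_mX_m − β_couple (ΣX_h − X_m) with one pass over the blocks, so
views enter as dense arrays or scipy sparse matrices interchangeably.

β_couple defaults to 1 and is deliberately distinct from the quadratic
penalty weight β_pen below — the two play unrelated roles (model coupling
vs constraint enforcement) even though both are conventionally written β.

## Penalty solver

The orthogonality constraints are enforced by the smooth exact-penalty
(merit) function

h(X) = f(X) − ½ Σ_m ⟨ψ(G_mᵀX_m), XmᵀXm − I⟩ + (β_pen/4) Σ_m ‖XmᵀXm − I‖²_F,

with G = LX and ψ(A) = (A + Aᵀ)/2, minimised over per-block Frobenius
balls of radius r = radius_factor·√K.  Each iteration takes a gradient
step along

D_m = G_m − X_m ψ(G_mᵀX_m) + β_pen X_m (XmᵀXm − I),

rescales any block with ‖X_m‖_F > r back onto the sphere, and chooses the
stepsize by the alternating Barzilai–Borwein rule (BB1 = ⟨S,S⟩/⟨S,Y⟩ on
odd iterations, BB2 = ⟨S,Y⟩/⟨Y,Y⟩ on even ones, from the stacked iterate
and gradient differences).  Iterations stop when
max_m‖D_m‖_F / max(1, ‖X‖_F) ≤ tol.

Two sign/convention notes:

* The gradient is taken as G = LX rather than the true Euclidean gradient
  2LX; the constant is absorbed by the scale-adaptive BB stepsizes.  The
  finite-difference tests therefore check 2LX against the directional
  derivative while the solver consumes LX.
* The multiplier term is *subtracted* (Riemannian-correction form).  With
  the sign flipped, D = 2G ≠ 0 at feasible stationary points, i.e. the
  direction is not a descent direction; the `printed_multiplier_sign` switch exposes
  that variant for auditability and is exercised in the tests.

### Numerical choices and safeguards

* **Initialisation**: per-view QR of a seeded Gaussian N×K matrix
  (default) or the bottom-K eigenvectors of each L_m (`init="spectral"`).
* **Stepsize safeguards**: the merit function is nonconvex, so ⟨S,Y⟩ may
  be negative; the raw BB ratio is taken in absolute value and clamped to
  [1e−10, 1e2].  A zero denominator falls back to μ_init = 1e−3.  An
  earlier fallback-to-μ_max variant was rejected: a 1e2 step at iteration
  2 reliably threw the iterate onto the ball boundary with collapsed
  singular values.
* **Penalty weight**: β_pen = 0.01·|f(X₀)| by default ("auto").  Small
  penalties converge fastest, but the merit function's stationary points
  are guaranteed feasible only for β_pen above a problem-dependent bound
  of the order of the K-th smallest Laplacian eigenvalue.  Below that
  bound the merit admits attracting rank-deficient minimisers (e.g.
  X = v₁aᵀ with Lv₁ = 0, ‖a‖ = 1, where f = 0 and only the penalty term
  remains).  The coupled multiview operator is self-stabilising — its
  bottom eigenvalues are negative, so the feasible optimum beats any
  collapsed point — but single-view/uncoupled problems are not.
* **Feasibility restoration**: therefore, whenever
  max_m‖XmᵀXm − I‖_F exceeds `feas_restore_tol` (default 1e−2) the
  iterate is projected back onto the Stiefel manifold by a polar
  decomposition and the BB history is cleared.  The safeguard never
  triggers on the coupled simulation problems (residuals stay ≲1e−7) and
  fires a handful of times on decoupled ones, where it is what makes the
  solver provably land on the bottom eigenspace (verified against dense
  eigendecompositions to ~1e−12 relative).
* **Termination**: tol = 1e−6, max_iter = 1000; hitting max_iter returns
  `converged=False` rather than raising.  Non-finite iterates raise a
  divergence error naming the iteration.
* **Polishing**: the returned blocks are the polar factors UVᵀ of the
  final iterate, making them exactly orthonormal; the pre-polish residual
  is kept in `SolverState.pre_polar_feasibility`.  k-means downstream
  assumes comparable row scales, which the polish guarantees.

## From embedding to labels

All N·M rows of the stacked X are clustered jointly by k-means
(squared-Euclidean, k-means++ seeding, 20 restarts, best inertia kept).
Because one centroid set is fitted for all views, labels are comparable
across views with no permutation matching.  Integrative labels: samples
concordant across all views keep their label; discordant samples take the
majority label across views; ties are voted by the k_nn = 5 nearest
concordant samples in the view-averaged embedding; if no sample is
concordant the integrative labels fall back to k-means on the
view-averaged embedding (logged).  k-means and silhouettes are delegated
to scikit-learn, the log-rank test to lifelines.

## Synthetic data

The generator draws each view independently from a stochastic block
model: nodes are assigned to K clusters in contiguous blocks of the
configured sizes, and each unordered pair is connected independently with
probability prob_matrix[l, s] (unweighted edges, no self-loops).  The
four canonical probability matrices P1–P4 share the diagonal
(16, 18, 17)/n and add increasing between-cluster noise; the divisor n is
the node count of the view (150 or 600), which holds the expected
within-cluster degree near 5 at both scales.  Views use independent
child streams of one master seed, so adding a view leaves earlier views
bit-identical.

What this emulates — and does not: SBM graphs have Bernoulli edges,
homogeneous within-block degrees and exactly block-constant connection
probabilities.  Real patient-similarity networks are weighted, have
hub/degree heterogeneity and continuous similarity decay.  Passing the
simulation study therefore demonstrates correct recovery of planted
partitions under the stated noise model, not performance on real omics
cohorts; the feature-matrix generator (Gaussian mixture per view with
configurable separation/noise) exercises the real-data code path
end-to-end but is likewise an idealisation.

## Evaluation

Simulation accuracy is the Rand index R = (TP+TN)/C(N,2) of each view's
labels against that view's ground truth, averaged over views (the
aggregation is a package decision, recorded in run metadata).  The
replication driver repeats generate→solve→cluster→score with independent
spawned seeds and reports mean and SD over replicates (50 by default).
Silhouette scores use Euclidean distance on embedding rows and come in a
triple: integrative labels on the view-averaged embedding ("common"),
per-view labels on each X_m averaged over views ("average"), and
integrative labels on the stacked rows ("integrative").  Survival
separation is the K-group log-rank test p-value.

## Problem sizes used in the shipped checks

The replication suite runs the two N = 150, M = 3 settings and the
N = 600, M = 5 differential setting at 50 replicates, and the N = 600,
M = 5 equal-size setting at 20 replicates; the solver-robustness grid
uses a single N = 1000, K = 30 sparse random instance.  These sizes match
the study design while keeping the default test run in the minutes range
on one CPU.

## Known limitations

* K is a config value; no eigengap or stability selection is provided.
* Combinatorial Laplacians only; no normalised variants.
* No missing-value handling in the feature front end (zero-variance
  features are dropped, everything else must be numeric).
* The penalty solver is first-order; convergence to the global optimum
  of the coupled nonconvex objective is generic, not guaranteed.
* On the differential-size five-view simulation the pipeline recovers
  per-view partitions with mean Rand ≈ 0.95–0.98 — the accuracy is
  controlled almost entirely by the coupling-to-Laplacian balance
  (raising β_couple forces more consensus and lowers per-view accuracy),
  so results in that regime should be read jointly with the chosen
  β_couple.
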