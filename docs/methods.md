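# Methods

## Model

The package models the conditional distribution of gene expression **y** ∈ ℝ^q
and clinical traits **z** ∈ ℝʳ given genotypes **x** ∈ ℝᵖ as a Gaussian chain
graph assembled from two sparse conditional Gaussian graphical models
(sCGGMs):

    p(y, z | x) = p(y | x) p(z | y),
    p(y | x) ∝ exp(−½ yᵀΛ_y y − xᵀΘ_xy y),
    p(z | y) ∝ exp(−½ zᵀΛ_z z − yᵀΘ_yz z).

Nonzero off-diagonals of Λ_y, Λ_z are network edges; nonzero entries of Θ_xy,
Θ_yz are direct perturbations.  Equivalently p(y|x) = N(B_xyᵀx, Λ_y⁻¹) with
B_xy = −Θ_xy Λ_y⁻¹, so a SNP's direct effects propagate along network paths:
B_xy is generically dense where Θ_xy is sparse.  Genotypes are accepted as
real dosages; mean-centering makes the {0,1,2} coding immaterial.

Assumptions: rows (samples) are independent; expression and traits are
jointly Gaussian given genotypes (equivalently, every conditional mean is
linear); missingness occurs only as whole expression rows; traits are few
relative to genes (r ≪ q) where the low-rank EM machinery matters.

## Estimation

The penalized maximum-likelihood problem decouples into the two layers.  Per
layer (dropping subscripts), with mean-centered 1/n-scaled cross-products
S_xx, S_xy, S_yy,

    min_{Λ≻0, Θ}  −log|Λ| + tr(S_yy Λ + 2 S_xyᵀΘ + Λ⁻¹ΘᵀS_xx Θ)
                  + λ_Λ‖Λ‖₁,off + λ_Θ‖Θ‖₁.

The diagonal of Λ is not penalized.  The problem is jointly convex; the
solver alternates:

1. **Θ step.**  With Λ fixed the problem is a Lasso; coordinate descent with
   exact scalar soft-threshold updates, restricted to an active set
   {(i,j): |∇g| > λ_Θ or Θ_ij ≠ 0}, caching M = S_xx Θ (one O(p) column
   update per changed coordinate).
2. **Λ step.**  A generalized Newton direction minimizes the L1-regularized
   quadratic model with gradient S_yy − Σ − Ψ and Hessian Σ⊗(Σ+2Ψ), where
   Σ = Λ⁻¹ and Ψ = ΣΘᵀS_xxΘΣ, by coordinate descent over symmetric pairs
   (cache U = ΔΣ, rows i and j refreshed per update).  A backtracking line
   search (β = 0.5, Armijo σ = 1e−4) guards positive definiteness —
   verified by Cholesky — and sufficient decrease.

Defaults: one coordinate sweep per outer iteration, lexicographic visitation
(deterministic; a seeded shuffled order is available), convergence when the
relative objective change falls below 1e−6 or after 100 outer iterations,
initialization Λ = diag(1/diag(S_yy)) clipped below at 1e−3 and Θ = 0, warm
starts everywhere, soft-threshold ties resolved to exact zero.  The line
search and Armijo constants are package choices; they only affect the path,
not the optimum of the convex problem.

An independent monotone-FISTA solver (`perturbnet.reference`) minimizes the
same objective by accelerated proximal gradients with backtracking and
restart.  It shares no code with the Newton path and serves as the
cross-check oracle in the tests and acceptance script.

### Memory-budgeted fitting

The block-wise solver solves the identical problem while keeping its large
caches under a byte budget: columns of Σ and Ψ are produced on demand by
Cholesky solves against Λ, rows of S_xx are recomputed from the centered data
per input block, and the Λ Newton direction is accumulated as a sparse
coordinate set using only cached Σ/Ψ rows for the current block pair (cost
O(nnz(Δ)) per coordinate instead of a dense U cache).  A deterministic block
plan keeps the estimated peak within the budget or reports the minimal
feasible budget.  Budget accounting covers the large caches (Σ/Ψ/S_yy
blocks, S_xx/S_xy row blocks, the ΘΣ block cache, and data-sized
transients); parameter storage and factorization workspace are exempt.  When
the budget covers the dense working set, the plan collapses to one block and
the in-memory code path runs unchanged.  Block-grouped coordinate order
differs from the in-memory lexicographic order, so agreement with the
in-memory fit is asserted at the solver-tolerance level (relative objective
1e−5; support up to coordinates at the soft-threshold boundary) rather than
bitwise.

### Model selection

λ's are chosen per layer (the objective decouples) to maximize
BIC = loglik − (k/2)·log n, with k = nnz(Θ) + number of nonzero off-diagonal
pairs of Λ + dim(Λ) and loglik the exact Gaussian log-likelihood.  This
penalized-count form is a package definition (AIC is available); grids are
traversed from sparse to dense with warm starts.

### Semi-supervised EM

With expression observed for a subset of samples, EM maximizes the penalized
expected log-likelihood.  The E-step is the exact Gaussian posterior

    Σ_y|x,z = (Λ_y + Θ_yz Λ_z⁻¹ Θ_yzᵀ)⁻¹,
    μ_y|x,z = −Σ_y|x,z (Θ_yz z + Θ_xyᵀ x),

shared covariance across hidden samples.  (The quadratic-form direction
Λ_z⁻¹ follows from completing the square in p(z|y); the low-rank factor is
K = Θ_yz L_z⁻ᵀ with L_z L_zᵀ = Λ_z, so that KKᵀ = Θ_yz Λ_z⁻¹ Θ_yzᵀ.)  Hidden
rows contribute E[y] = μ and E[yyᵀ] = Σ + μμᵀ to the expected sufficient
statistics; the M-step re-runs the layer solvers warm-started.  Column means
are fixed once — Y over observed rows, X and Z over all rows — and all
computation is done in centered coordinates, which preserves the EM
monotonicity guarantee for the recorded observed-data objective (observed
rows: −2 log p(y,z|x); hidden rows: −2 log p(z|x) from the marginal).  With
no hidden rows the EM entry point calls the complete-data fitter directly.
For large q, columns of Σ_y|x,z are available individually via conjugate
gradients on Λ_y + KKᵀ (residual tolerance 1e−8) without forming any dense
q×q matrix.

## Inference

* B_xy = −Θ_xy Λ_y⁻¹ and B_yz = −Θ_yz Λ_z⁻¹ (computed by solves, never an
  explicit inverse).
* SNP→trait effects mediated by the gene network: B_xz = B_xy B_yz, with
  cov(z|x) = Λ_z⁻¹ + Λ_z⁻¹Θ_yzᵀΛ_y⁻¹Θ_yzΛ_z⁻¹.
* Module decomposition: B_xz^(M) = Σ_{j∈M} B_xy[:,j] B_yz[j,:] over disjoint
  modules covering all genes; the components sum to B_xz exactly.
* Posterior gene network after conditioning on traits:
  Λ_y|x,z = Λ_y + Θ_yz Λ_z⁻¹ Θ_yzᵀ.  Edges present there but absent from Λ_y
  are *moralized*: they join genes influencing the same trait or connected
  traits.
* Joint representation over (z, y): precision [[Λ_z, Θ_yzᵀ], [Θ_yz, Λ_y|x,z]]
  with perturbation (0_{p×r}, Θ_xy); its density factorizes into the two
  layers (verified numerically in tests).
* Group summaries use S(A[I,J]) = Σ|A_ij|; SNP rankings sort by S(B_xz[i,:])
  with identifier tie-break.  Effects below 1e−12 are truncated to exact zero
  in sparse outputs (numerical noise floor).
* Mediator categorization: gene j mediates SNP k → trait i when
  B_xy[k,j] ≠ 0 and B_yz[j,i] ≠ 0; the perturbation *received* is direct iff
  Θ_xy[k,j] ≠ 0 and the perturbation *passed* is direct iff Θ_yz[j,i] ≠ 0,
  giving four categories.

## Synthetic data

The generator emulates a module-organized transcriptome under genetic
perturbation; its defaults are the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| p, q, r | 10000, 5000, 100 | SNPs, genes, traits |
| module_size | 50 | nodes per network module (both layers) |
| avg_degree | 3 | mean node degree of each network |
| within_module_edge_frac | 0.9 | fraction of edges inside modules |
| edge weights | N(0.5, 0.1²) | network and perturbation magnitudes |
| min_eigenvalue | 0.3 | exact minimum eigenvalue after diagonal shift |
| perturbants_per_target | 3 | nonzeros per Θ column |
| sign_flip_prob | 0.5 | perturbation sign balance |
| n_snps_perturbing | 1000 | SNP pool eligible to perturb genes |
| gene modules unperturbed | 1/2 | fraction with all-zero Θ_xy columns |
| gene modules trait-silent | 1/5 | fraction with all-zero Θ_yz rows |
| trait wiring | 0.9 / 0.1 | primary vs other trait-module edge split |
| noise_variance | 0.5 | regression-family residual variance |

Scale-free topology comes from per-module preferential attachment with exact
edge quotas (total edges = round(dim·deg/2), split 90/10 within/between), so
mean degree and within-module fraction are met by construction and weights
are sampled i.i.d. Gaussian; the diagonal is set to c·I with c chosen from
the extremal eigenvalue so the minimum eigenvalue is exact.  Any generator
meeting the measurable targets (degree, module fraction, weight
distribution, eigenvalue floor) is equivalent for the package's purposes.
Sign flips are applied to perturbation entries; network-edge sign flips are
available but off by default.  Three families: the chain model itself
(ancestral sampling y|x then z|y), a two-layer linear regression with noise
variance 0.5 (mediators acting independently), and a two-layer GGM with
Θ_xy = 0 (no genetic perturbation).  Genotypes are independent
Binomial(2, MAF) counts with MAF ~ U(0.1, 0.5): real linkage disequilibrium,
allele-frequency spectra and population structure are *not* modeled, so
passing recovery tests here says nothing about confounding by LD in real
cohorts.  Tests and the acceptance script run reduced dimensions (hundreds
of SNPs/genes) with the same structural constants.

## Evaluation

Recovery of true structure is scored by sensitivity (TP/P) against false
discovery rate (FP/(TP+FP)) while sweeping a threshold down the |score|
ranking, ties grouped; replicate curves are averaged pointwise on a fixed
101-point FDR grid, and the headline operating point sensitivity-at-FDR-0.05
is reported.  For *network* recovery the operating points are the estimated
edge sets along a penalty path (area under the resulting
best-sensitivity-vs-FDR envelope): scoring a single penalized estimate by
coefficient magnitude conflates ranking quality with how many coefficients
survive the penalty — the genotype-blind fit is systematically denser at
matched λ because the marginal expression covariance is inflated by SNP
effects — whereas path operating points compare methods at matched sparsity.
The two-layer Lasso baseline regresses each gene on X and each trait on Y
independently and composes the coefficient matrices; "trait-perturbing SNP"
truth is the nonzero pattern of the true composed effect (B_xz for the chain
family, W_xy W_yz for the regression family).  The robustness harness refits
on subsampled (without replacement, stratified over expression-observed and
-unobserved rows) and noise-injected data and scores each parameter block's
|estimate| by ROC-AUC against the reference fit's support; the
full-data/no-noise cell is the reference itself, hence AUC exactly 1.

## Numerical choices and degenerate inputs

Symmetry violations of Λ above 1e−8 (relative) raise rather than being
silently symmetrized; positive definiteness is always established by
Cholesky (its failure *is* the test).  Inputs with zero variance cause their
Θ row to be skipped with a warning.  An infeasible memory budget raises a
capacity error naming the minimal feasible budget.  Empty score groups return
0 with a warning.  Trait z-scoring is a preprocessing option, off by default
for simulated data.  All randomness flows through seeded generators;
identical seeds give bitwise-identical simulations.

## Limitations

Continuous traits only (no discrete/CRF variant); no LD or population
structure in simulated genotypes; no cross-validated selection (BIC/AIC
only); the block-wise solver bounds cache memory in RAM but does not spill
to disk; single-threaded.
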