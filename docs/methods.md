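# Methods

This note documents the models, numerical choices, and design decisions
behind each analysis stage, what the synthetic-data generators emulate, and
what passing tests do and do not establish about real data.

## Local synchrony (ReHo)

Regional homogeneity is Kendall's coefficient of concordance W over the
temporal rank orders of a voxel and its spatial neighbors:

W = 12 Σ_t (R_t − m(T+1)/2)² / (m²(T³−T) − m Σ_i C_i),

where m is the neighborhood size, T the number of volumes, R_t the rank sum
at time t, and C_i = Σ_g (t_g³ − t_g) the tie correction of series i.
Ranks are mid-ranks; the tie correction keeps W ≤ 1 under ties, matching the
common neuroimaging implementation (the choice is not forced by the
definition; exact-rank alternatives exist).  Neighborhoods are the 27-voxel
cube by default (7 = faces, 19 = faces+edges also supported).  Boundary and
mask-edge voxels use their in-mask neighbors only; voxels with fewer than 4
in-mask neighbors are reported missing rather than scored on degenerate
neighborhoods.  This preserves cortex edges at desk-scale grids and is
configurable.

Maps are standardized (in-mask mean 0, SD 1, ddof = 1) before smoothing, in
that order.  Smoothing uses a Gaussian kernel with σ = FWHM / (2√(2 ln 2))
per axis in voxel units, truncated at 4σ (kernel-mass error < 1e-4), and is
NaN-aware: the map is renormalized by the smoothed valid-voxel indicator so
missing voxels neither bleed in nor attenuate edges.  Parcel values are
means of valid voxels per label; empty parcels are missing.

## Connectivity gradients

Per segment: Pearson correlation across parcels; row-wise sparsification
keeping each row's top (1 − sparsity) fraction of off-diagonal entries by
value (ties at the cutoff all kept; negatives among kept entries zeroed;
diagonal zeroed); cosine similarity between the sparsified rows with
negatives clipped; diffusion-map embedding with anisotropic normalization
W' = D^(−α) W D^(−α) at α = 0.5, Markov normalization P = D'^(−1) W', and
coordinates from the leading nontrivial right eigenvectors of P (normalized
against the trivial constant eigenvector) scaled by λ/(1−λ) (the diffusion
time 0 convention).  Row-wise sparsification, α, and the time-0 scaling are
declared defaults — the underlying methodology literature varies here — and
all are configurable.  Disconnected affinity graphs raise an error naming
the component sizes; repeated-eigenvalue embeddings are flagged degenerate
rather than silently rotated.

Templates are built by averaging connectivity matrices element-wise and
embedding the mean.  Alignment is orthogonal Procrustes (columns centered,
rotation/reflection only, re-estimated iteratively against the evolving
mean reference, 10 iterations).  Scaling is deliberately excluded: the
quantity of interest is dispersion (range and SD of G1), and an isotropic
scale fit would erase exactly the flattening effect being measured.  After
alignment each component is sign-flipped if needed so its correlation with
the template component is nonnegative.

## Geometric eigenmodes

The Laplace–Beltrami operator is discretised with cotangent stiffness
weights and a lumped (diagonal) mass matrix whose trace equals the surface
area.  The lumped mass makes the projection a closed-form mass-weighted
inner product, ω = ΨᵀMy, for M-orthonormal modes — the standard choice in
surface eigenmode work; a plain pseudoinverse projection and a restricted
(masked-vertex) weighted least-squares path are also provided.  The
generalized eigenproblem is solved by shift-invert Lanczos (σ = −1e−6,
since the stiffness matrix is singular at 0), falling back to a dense
solver for small meshes or near-complete bases.  Signs follow a fixed
convention (first entry above 1e−8 positive), making bases reproducible.

Power is |ω_k(t)|, energy |ω_k(t)|²λ_k²; the constant mode (λ ≈ 0) has
identically zero energy.  Segment summaries take the temporal mean and max
per mode and then apply log10 (log of the mean, not mean of logs — the
ordering is declared and switchable), with a floor of 1e−12 before the log.
Totals are per-time sums averaged over the segment.  Eigengroups default to
spherical-harmonic multiplicities (1, 3, 5, 7, …) since no canonical
partition exists for arbitrary meshes; custom partitions are accepted.

Validation anchors on the unit icosphere, where the analytic spectrum is
λ = l(l+1) with multiplicity 2l+1: a subdivisions-4 sphere reproduces
{2, 6, 12} within 0.4% and the exact multiplicities {3, 5, 7}.

## State trends

Each metric is modelled as y = Σ_d β_d P_d(state) + u_participant + ε with
centered orthonormal polynomial contrasts P_d up to degree 3 and a random
participant intercept.  Fitting is restricted maximum likelihood with the
variance ratio θ = σ_u²/σ_e² profiled out: for compound-symmetric
covariance every likelihood evaluation is closed form (block Woodbury),
leaving a 1-D bounded optimization in log θ.  This makes the calibration
simulations (tens of thousands of fits) tractable; the solver is
cross-checked against a general-purpose mixed-model implementation in the
test suite (fixed effects, standard errors, variance components agree).
Fixed-effect t tests use residual degrees of freedom
N_obs − N_participants − D; Satterthwaite-type corrections are deliberately
out of scope and the df rule is declared in the result metadata.

Model reduction removes only the single highest-degree term while it is
non-significant at α = 0.05 (coefficient p under REML), never dropping the
linear term; the un-reduced fit is retained for audit.  Condition
comparisons use a categorical-state model against the composite control
(counting/memory average, originals retained for the control-vs-control
contrast), estimated marginal means from the fixed effects (equal to raw
means in balanced designs), FDR within each model's eight contrasts and a
second FDR across metrics.  Trend FDR families run across metrics within a
modality.

## Brain–behavior coupling

PLSC z-scores both blocks and decomposes R = Y_zᵀX_z/(n−1) by SVD —
correlation-scale PLSC, required because behavioral domains mix 1–10
ratings with task scores of arbitrary units.  Covariance explained is
100·S_i²/ΣS²; the number of components defaults to the number of
behavioral variables, capped at rank(R).  Permutation inference permutes Y
rows (X fixed) and compares i-th sorted null singular values with the i-th
observed, p = (1 + #{S_perm ≥ S_obs})/(n_perm + 1) (minimum attainable p is
1/(n_perm+1)), with BH across latent variables.  Bootstrap resamples rows
with replacement, sign-aligns each resample's saliences to the original by
inner product, and reports percentile CIs and bootstrap ratios
(|ratio| ≥ 1.96 flags stability).  Kaiser retention keeps components whose
explained covariance strictly exceeds the mean.

Missing behavior entries are completed by chained equations with predictive
mean matching (k = 5 donors, 20 iterations, 5 chains averaged element-wise
before PLSC; observed cells are never altered).  Averaging multiple
imputations into one table before PLSC is a declared simplification — no
pooling rule for PLSC across imputations is established — and is the main
caveat on the imputation path.

## Decoding and robustness

Delta maps (state minus composite control, unthresholded) are decoded by
Pearson correlation against each map in a term library over jointly valid
locations, ranked descending, with top-10 positive and negative lists.
Subgroup robustness correlates two subgroups' state maps and builds the
null by permuting one map's locations (p two-sided on |r|).  Location
shuffling assumes spatial exchangeability; real cortical maps violate this
through spatial autocorrelation, so on real data these p-values are
anti-conservative — the synthetic parcel-level maps used in testing are
exchangeable by construction.  The similarity trend is an OLS slope of r on
state index 1–8.

## Synthetic data: what is emulated, and what is not

All generators are pure functions of (spec, seed); a single integer seed
drives a hierarchical stream tree (one child per participant × condition,
labelled by a stable CRC32 hash) so subsets reproduce independently.

* **ReHo substrate.** Voxel series are √w·(parcel-shared signal) +
  √(1−w)·(i.i.d. noise) with w = logistic(base + l·P1 + q·P2 + c·P3) over
  the eight states, so Kendall's W increases monotonically with w by
  construction.  Defaults plant anterior-negative / posterior-positive
  linear trends and a midline quadratic; region groups are thirds along the
  first grid axis (deterministic and resolution-independent).  Controls use
  the base weight only.
* **Hierarchy substrate.** Parcel series realize an Ornstein–Uhlenbeck
  correlation kernel over a latent coordinate g ∈ [−1, 1] (correlation
  decays exponentially with |g_i − g_j|, positive definite for any
  coordinate set).  Flattening is *topological*: the meditation-state
  correlation matrix is a·K + (1−a)·K_scrambled, mixing the hierarchy
  kernel with an order-scrambled copy of itself, and a is solved by
  bisection so that the noiseless matrix's embedded G1 range equals
  `gradient_compression` times the control range.  A uniform shrinkage of
  the coordinates would *not* work: rank-based sparsification and cosine
  normalization make the embedding nearly invariant to monotone rescaling
  of the correlation structure (measured ratio 0.93–1.0 for a 0.5
  shrinkage), so the parameter is defined by its contract — the recovered
  range ratio — and realized by reduced hierarchical differentiation, which
  is also the phenomenon the analysis is meant to detect.  Headline ratios
  are computed from condition-mean connectivity (averaging FC before
  embedding); per-segment embeddings at short T are biased toward extra
  flattening by sampling noise in the correlation matrix.
* **Eigenmode substrate.** y(t) = Σ_k a_k(state) z_k(t) ψ_k + ε with unit
  white z_k; the default amplitude schedule (2, 1.5, 1, 0.8, 0.7, 0.9, 1.3,
  1.8) is U-shaped, planting a positive quadratic trend in log mean power.
* **Behavior substrate.** The planted latent score is the brain matrix's
  leading principal component (making the perfect-coupling case exactly
  recoverable by the cross-covariance SVD); behavior columns are
  ρ·latent·uᵀ plus noise.  Phenomenology is affinely mapped to integer 1–10
  ratings (skippable for exact-identity checks); missingness is inserted
  completely at random (MCAR ⊂ MAR, the imputer's assumption) in
  phenomenology and traits.  Coupling is injected at the
  participant × condition level, mirroring how PLSC consumes parcel
  summaries.
* **Term library.** The planted map is r·z(target) + √(1−r²)·e with e
  orthogonalized against the target, so its sample correlation equals the
  target exactly; remaining maps are independent noise.

None of the generators model hemodynamics, physiological noise, head
motion, spatial autocorrelation of noise, or realistic rating
distributions.  Passing tests therefore establish that the implementations
compute the intended statistics and recover effects of the planted form at
the planted strength — not that those effect sizes, or the exchangeability
assumptions behind the permutation nulls, hold in real 7T data.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 6–12
participants, 10×10×10 grids with 27 block parcels, 60-volume segments
(240 for gradient-ratio checks, where correlation sampling noise matters
most), 60 gradient parcels, subdivisions-2/4 icospheres, 500-replicate
calibration nulls, and 500-permutation inference where 10,000 is the
analysis default.  All resampling defaults (10,000 permutations and
bootstraps) remain the library defaults for real use.

## Known limitations

* One participant-level random intercept only; no random slopes or
  heteroscedastic residuals.
* The Procrustes iteration is idempotent for a single source (the evolving
  reference matters only for multi-set alignment).
* Degenerate embeddings (repeated eigenvalues) are flagged, not resolved.
* The naive location-permutation null for map similarity is
  anti-conservative under spatial autocorrelation (see above).
* MICE chains are averaged rather than pooled by combining rules.
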