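# medstates

Multiscale analysis of sustained, ordered brain states in fMRI — built for
studies of advanced absorption meditation (eight ordered jhana-type states,
J1–J8, plus non-meditative control tasks), but generic over any ordered
condition factor.

The package implements, as a tested and reusable library, the full analysis
chain such studies need:

* **Local synchrony (ReHo).** Kendall's coefficient of concordance
  W ∈ [0, 1] over each voxel and its 7/19/27-voxel neighborhood time-course
  ranks (mid-ranks, tie-corrected), then standardization, NaN-aware Gaussian
  smoothing (2 mm FWHM default), and parcel averaging.
* **Connectivity gradients.** Pearson functional connectivity → row-wise
  sparsification at 90% → cosine affinity → diffusion-map embedding
  (α = 0.5, diffusion time 0) → iterative Procrustes alignment to a template
  (10 iterations, no scaling) → principal-gradient (G1) dispersion and
  network summaries.
* **Geometric eigenmodes.** Cotangent Laplace–Beltrami eigenmodes ψ_k with
  eigenvalues λ_k on a triangle mesh; projection ω = ΨᵀMy; per-mode power
  |ω_k(t)| and energy |ω_k(t)|²λ_k²; segment mean/max/total summaries on a
  log scale; eigengroup (2l+1 block) aggregation.
* **State trends.** Random-intercept linear mixed models across the ordered
  states with centered orthonormal polynomial contrasts up to the cubic,
  iterative reduction of non-significant highest-degree terms, estimated
  marginal means and state-vs-composite-control contrasts, and
  Benjamini–Hochberg FDR (two-level for contrasts).
* **Brain–behavior coupling (PLSC).** SVD of the cross-block correlation
  matrix R = YᵀX/(n−1); permutation inference on singular values, bootstrap
  salience CIs and bootstrap ratios, Kaiser retention, latent Pearson
  correlations; MICE with predictive mean matching for missing behavior
  entries; univariate factor correlations with FDR.
* **Decoding and robustness.** Correlation decoding of unthresholded
  state-minus-control delta maps against a term-map library (top-10
  rankings), and split-half subgroup spatial similarity with permutation
  inference plus its linear trend across states.
* **Synthetic data.** Seeded generators that plant every effect the
  analyses are meant to detect — region-wise polynomial ReHo trends,
  hierarchy flattening, U-shaped eigenmode power, latent brain–behavior
  coupling, planted decoder terms — and return the ground truth for
  recovery scoring.

## Worked example

`examples/07_end_to_end.py` generates a 6-participant synthetic cohort with
planted effects (anterior-negative / posterior-positive linear ReHo trends,
gradient compression 0.5 in meditation states, a U-shaped eigenmode power
schedule, latent behavioral coupling ρ = 0.7, a planted decoder term) and
runs every stage:

```
trend sign recovery: 1.00 (fraction of trend-bearing parcels with the planted sign)
G1 range ratio state/control: 0.543 (planted flattening 0.5)
PLSC LV1 latent r per domain: {'phenomenology': 0.71, 'traits': 0.72, 'cognition': 0.69} (planted coupling rho = 0.7)
decoded top term for the J8 delta map: planted_term
eigenmode quadratic trend: 0.42 (positive = planted U-shape)
```

Every planted effect is recovered: all trend-bearing parcels get the right
trend sign, the principal-gradient range is roughly halved in states
relative to controls, the latent brain–behavior correlation lands near the
planted 0.7, the planted term ranks first in the 123-term decoder, and the
U-shaped power trajectory shows up as a positive quadratic trend.  The other
scripts in `examples/` demonstrate each stage on its own, with one-line
explanations of the printed numbers.

A thin CLI wraps the file-based stages:

```bash
medstates simulate --out data/ --participants 20 --seed 0
medstates reho --input run.nii.gz --segments segments.csv --labels parcels.nii.gz --out reho.csv
medstates run --participants 12 --seed 0
```

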