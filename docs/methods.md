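# Methods

This note documents the statistical model, the default parameters and the
numerical choices behind `flens`, a toolkit for detecting batch effects,
bias and overfitting in learned image embeddings. It states only design
facts; every empirical number in the repository is computed by the test
suite or by `scripts/acceptance.py`.

## Problem setting

A feature extractor maps image tiles to vectors `x ∈ R^d`. Each tile
carries metadata: a prognostic variable we *want* the embedding to encode
(e.g. tumor stage) and nuisance variables we *hope* it ignores (e.g. the
tissue source site that contributed the slide). If a simple decoder can
predict a nuisance variable from the embeddings well above chance, the
representation carries batch structure that can leak into and confound
downstream models. `flens` quantifies this with three instruments:

1. a **linear probe** with bootstrap uncertainty (how decodable is the
   variable?),
2. **structure scores** on 2-D projections (is the variable visible as
   geometric cluster structure, and is that structure faithful to the
   high-dimensional space?),
3. **sampling utilities** that enforce the experimental design the above
   require (patient-disjoint, covariate-balanced, whitespace-filtered
   tile sets).

## Linear probe

The probe is a single affine layer `z = W x + b` trained with softmax
cross-entropy. Deliberately minimal capacity means any accuracy above
chance reflects information that is *linearly* accessible — the easiest
kind for a downstream model to exploit accidentally.

- **Standardization** (`standardize=True`): each feature dimension is
  centered and scaled using statistics of the *training* split only, so
  no test information leaks into preprocessing. Zero-variance dimensions
  get unit scale to avoid division by zero.
- **Optimizer**: mini-batch Adam, learning rate `1e-3`, betas
  `(0.9, 0.999)`, batch size 256, 20 epochs. These are conventional
  defaults for a convex-ish single-layer objective; the probe converges
  well within 20 epochs at the default problem sizes. All arithmetic is
  float64 for run-to-run bit stability.
- **Determinism**: weight init and epoch shuffling come from a seeded
  generator, so `fit` is bitwise reproducible for a fixed seed.
- **Classes** are ordered lexicographically so label order never depends
  on input order.

### Uncertainty

Test-set accuracy and Cohen's κ get 95% percentile-bootstrap intervals
from 100 resamples of the (true, predicted) pairs. Percentile bootstrap
is chosen over normal-approximation intervals because accuracy near 0 or
1 is strongly skewed. κ is computed per replicate from the resampled
confusion matrix and averaged; when the expected agreement is 1 (a
degenerate single-cell matrix) κ is undefined and reported as missing
rather than coerced to a number.

### Subsampling experiment

`subsample_experiment` retrains the probe on stratified fractions of the
training set (rounded per class, erroring if a class would vanish). For
fractions ≤ 0.25 the epoch count is raised to 60 so small-sample runs are
limited by data, not by optimization budget. This produces the
accuracy-vs-training-size curves used to diagnose whether a probe result
is data-limited.

## Structure scores

Given high-dimensional embeddings `X`, a 2-D projection `L`, and a label
vector, four scores are reported:

- **Silhouette** on `L` with Euclidean distance. Points whose label class
  is a singleton score 0 (the neutral value) instead of being dropped.
  Above 5000 points a seeded subsample caps the O(n²) cost.
- **k-means ARI**: Lloyd's algorithm with k = number of label classes,
  greedy farthest-first seeded initialization, 10 restarts, at most 300
  iterations, stopping when the largest center shift is below `1e-4`.
  The best-inertia clustering is compared to the labels with the
  pair-counting adjusted Rand index. ARI is used rather than raw Rand
  because it is 0 in expectation under independent partitions.
- **KNN-preservation**: mean fraction of each point's k nearest neighbors
  shared between `X` and `L`. Distance ties are broken deterministically
  by lower index (stable argsort) so the score is reproducible.
- **CPD** (correlation of pairwise distances): Spearman correlation of
  all pairwise distances in `X` vs `L`, computed on a seeded subsample of
  at most 1000 points to bound the O(n²) distance count.

Silhouette, ARI, KNN-preservation and CPD each have exhaustive
brute-force oracles in the test suite; the library implementations must
match them to 1e-8 on random instances.

A *projection that looks clustered by site* is only evidence of a batch
effect if the projection is faithful; KNN-preservation and CPD guard
against over-reading artifacts of the embedding method.

## 2-D projection

Two backends:

- **`neighbor_embedding`**: UMAP (via `umap-learn`, imported lazily),
  defaults `n_neighbors=15`, `min_dist=0.1`, seeded `random_state`.
  `project_grid` sweeps neighbor/min-dist grids because UMAP cluster
  appearance is sensitive to both.
- **`linear_fallback`**: 2-component PCA implemented by power iteration
  with deflation. This backend is fully deterministic (fixed start
  vector, sign fixed by making the largest-magnitude loading positive)
  and is the one used wherever bitwise reproducibility is asserted.

Power-iteration numerics: convergence when the iterate moves less than
`1e-12` (vector criterion) or the Rayleigh quotient moves less than
`1e-10`, up to 50 000 iterations. The generous iteration cap exists
because convergence is linear in the eigengap ratio and near-degenerate
top eigenvalues (ratio ≈ 0.99) legitimately need tens of thousands of
iterations to reach eigenvector error below 1e-9; the cost is still well
under a second at d ≤ 64. Each iterate is re-orthogonalized against
previously found components so rank-deficient inputs yield exact zero
trailing components instead of noise.

`draw_projection_sample` stratifies by a label with largest-remainder
rounding (ties broken by class name) so small classes are not silently
dropped from plots.

## Tiling and sampling

- **Tile grid**: stride `round(side · (1 − overlap))`; tiles that would
  cross the image edge are dropped rather than padded.
- **Whitespace**: a pixel is background when all RGB channels are ≥ 220;
  a tile is removed when its background fraction is strictly greater than
  the threshold (default 0.85), so exactly-at-threshold tiles are kept.
- **Top-N groups**: groups ranked by descending tile count, ties broken
  by ascending group id — a deterministic rule for choosing the largest
  contributing sites.
- **Covariate balancing**: restrict to covariate levels present in every
  group (dropping, e.g., a stage that only one site contributed), then
  subsample every (group, level) cell to the minimum cell size with a
  seeded draw, preserving original row order. If no level is shared the
  error names the offending groups.
- **Patient-disjoint split**: units (patients) are assigned greedily to
  the partition with the largest remaining shortfall, so no patient ever
  spans train and test. With `stratify_by`, the greedy assignment runs
  independently inside each stratum (e.g. site) so partition proportions
  match per stratum. Stratification matters for calibrated chance levels:
  an unstratified greedy split anti-correlates site frequencies between
  train and test, which pushes a no-signal probe *below* chance and would
  masquerade as negative information.

## Synthetic generator

Data are drawn as

```
x = class_sep · μ_class + delta · v_site + sigma · ε,   ε ~ N(0, I_d)
```

with `μ_class` and `v_site` orthonormal (distinct identity columns:
classes occupy the first `n_classes` dimensions, sites the next
`n_sites`). Site centroids are therefore mutually equidistant at
`delta·√2` and the class/site subspaces are exactly orthogonal, making
`delta/sigma` the single interpretable knob for batch-effect strength.
The hierarchy mirrors a pathology study: sites → patients → slides →
tiles (defaults 5 × 10 × 2 × 50 = 5000 tiles), with the prognostic stage
assigned at the *patient* level so patient-disjoint splitting is actually
load-bearing.

What this emulates: site-specific additive shifts (stain/scanner bias),
patient-level label granularity, multi-level sampling structure. What it
does **not** emulate: non-linear or multiplicative batch effects,
site-conditional class imbalance, correlated noise across dimensions,
spatial correlation between tiles of one slide, or realistic image
content. Conclusions about detector *calibration* transfer; absolute
effect sizes on real embeddings will differ.

`gen_tiles` produces grayscale-like RGB tiles with an exactly controlled
background fraction (round(frac·side²) pixels at 255, the rest at 50),
used to validate the whitespace filter against known truth.

## Storage

Embeddings round-trip through two dialects with a shared header
convention (`id`, `meta_*`, `f0…f{d−1}`): a text dialect (TSV/CSV,
floats printed with `%.9g`, which is lossless for float32) and a binary
dialect (a single Parquet file). Features are canonicalized to float32 on
load, so save→load equality is exact. Missing metadata is written as the
explicit string `NA`. Validation rejects duplicate ids and non-finite
values, naming the offending row and column.

## Hooks

Training-loop hooks run the full bias battery on a cadence
(`every_n=20` epochs by default): an internal patient-disjoint 70/30
split, a lighter in-loop probe configuration (5 epochs, 25 bootstrap
resamples) to keep per-check cost small, optional projection scoring, and
a stop rule (`variable`, direction, threshold) that can halt training
when, e.g., site decodability rises above a tolerance. History is
persisted as JSON lines, one record per check, with UTC timestamps.

## Limitations

- The probe is linear; a nuisance variable encoded only non-linearly will
  be under-reported. Pairing the probe with projection scores mitigates
  but does not remove this.
- Bootstrap intervals treat test tiles as exchangeable; tiles from the
  same slide are correlated, so real-data intervals are anti-conservative
  unless sampling is done at the slide or patient level first.
- The synthetic generator's additive orthogonal site shift is the easiest
  case for a linear probe; detection power on real embeddings is lower.
- k-means ARI inherits k-means' bias toward isotropic, equal-size
  clusters.
- UMAP projections are seeded but not guaranteed bitwise stable across
  library versions; the linear fallback is the reproducible reference.
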