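# Methods

## Problem and model

The package predicts a binary chemotherapy endpoint (pCR vs RD, pCR
positive) for a patient from the spatial organisation of histology classes
in an H&E biopsy. The model is deliberately feature-engineered: no
representation is learned from pixels. Two stages:

**Stage 1 — tiles to maps.** The slide is partitioned on a fixed grid of
224×224-px tiles anchored at the origin with stride equal to the tile size.
A tile is retained iff its exact polygon-intersection area with the
annotated tissue reaches 90 % of the tile area; its label is the class of
the region with the largest overlap (ties to the lower class id, for
determinism). Color is handled in optical density, OD = −log10((I+ε)/I₀)
with ε = 1e−6 and I₀ = 255, where stains mix linearly. The H&E stain
matrix is estimated per image by SVD over tissue pixels (OD norm > 0.15)
and the 1st/99th percentile angles in the leading plane; the vector with
the larger red-channel OD is labeled hematoxylin, robust maxima are the
99th concentration percentiles, and the standard published H&E vectors
(H ≈ (0.650, 0.704, 0.286), E ≈ (0.072, 0.990, 0.105)) are the fallback
and deconvolution default. Normalization unmixes against the source model,
rescales to the reference maxima and remixes with the reference matrix;
the off-span OD residual is carried through unchanged so normalizing a
tile against its own model is the identity. All texture features are
computed on the hematoxylin concentration channel, windowed to [0, 2] OD
and quantized to 8 bits (a luminance switch is not provided; the
hematoxylin channel is the one the deconvolution step isolates).

**Stage 2 — maps to outcome.** Per class pair (A, B), 4-connected
same-class cell clusters (8-connectivity by config) are reduced to
centroids at mean cell centers, cell (r, c) centering at (c+0.5, r+0.5) in
tile units. Nodes of both classes form a random geometric graph with an
edge whenever the Euclidean centroid distance is ≤ radius (default 8 tile
widths; a cross-class-only edge mode exists because the construction can
be read either way — the default links all pairs within radius). The
20-feature pair vector is: per-class means of hematoxylin GLCM contrast,
GLCM homogeneity and histogram entropy over cluster member tiles plus the
node-count ratio |A|/(|A|+|B|) (7); mean degree, degree variance, mean
clustering coefficient, adjacency spectral radius, Laplacian algebraic
connectivity (0 when disconnected), normalized-Laplacian energy
(mean |λᵢ−1| of the normalized Laplacian spectrum) and cross-class edge
fraction (7); Euclidean-MST total length over the map diagonal, mean, SD
and max MST edge length, connected-component fraction of the geometric
graph, and mean cross-class nearest-neighbor centroid distance (6). A pair
with either class absent yields a zero vector flagged invalid. Pairs are
unordered; slot A is the lower class id.

ReliefF (k = 10 neighbors capped at class size − 1, Manhattan distance on
min–max normalized features, all instances used so the default is
deterministic, neighbor ties by instance index) weights all pair features;
with a binary outcome the prior-weighted multi-class miss term reduces to
the plain miss mean. The top n = 8 by weight (ties to the lower index) are
kept. Both granularities — per-feature weights and per-pair maxima — are
emitted, since rankings can be read at either level.

## Classifiers and evaluation

Four classifiers are shared by both stages: 1NN, linear SVM (C = 1),
RBF SVM (C = 10, kernel width 1/(d·Var)), and RUSBoost — 100 depth-3
trees, learning rate 0.1, SAMME updates with every class randomly
undersampled to the minority count each round (implemented in-package as a
small sklearn-style estimator). Feature standardization is fit on training
folds only, asserted by instrumentation on every CV run. SVM probabilities
are Platt-calibrated. Tile evaluation uses stratified eightfold CV
(seeded per-class round-robin; per-class fold counts differ by ≤ 1; a
class smaller than k warns and is spread best-effort). Patient evaluation
uses leave-one-out CV; the call is the larger class probability, with an
exact 0.5 tie going to RD so a pCR call requires strict majority. Feature
selection defaults to `nested` (ReliefF re-run inside every training
fold — no selection leakage); a `global` mode (select once on all
patients) exists for replicating select-then-validate protocols, and both
are reported where relevant. Binary metrics come from the confusion matrix
with pCR positive; undefined ratios are NaN and flagged. AUC is the
all-pairs rank statistic with ties at ½, and the trapezoidal area under
the reported ROC curve equals it to 1e−9. 95 % CIs are patient-level
bootstrap percentiles (seeded; 500–1000 resamples). Attention maps
highlight the cells of every class participating in a selected pair,
i.e. the tissue whose clusters feed the discriminative graphs.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage has a no-download substrate with known
ground truth.

*Tiles* are rendered as stain mixtures: per-class hematoxylin/eosin
concentration fields are unit-variance Gaussian random fields (anisotropic
Gaussian smoothing of white noise at the class correlation length, 2:1
anisotropy when an angle is set), modulated ±35 % around the class OD
levels; nuclei are Poisson-placed anti-aliased disks adding 0.8 OD to
hematoxylin; OD mixes through the standard H&E matrix and exponentiates to
RGB. Class recipes differ in correlation length, nucleus density/size and
stain levels, giving distinct second-order statistics (e.g. a 2-px vs
16-px correlation length is separable by a single GLCM-contrast
threshold).

*Label maps* take the per-cell argmax over class fields w·exp(g), g a
smoothed standardized noise field (smoothness 3 cells), producing coherent
patches whose prevalence grows with the mixing weight; the lowest 5 % of a
coarser tissue field becomes background.

*Cohorts* default to the study conditions: n = 60 patients, pCR prevalence
0.6 (matching a 51/85 development cohort), 48×48 maps, six classes
(stroma, tumor, tumor-TIL, stroma-TIL, PGCC, microvessel; weights
1.5/1.2/0.8/0.8/0.5/0.6 chosen once as a plausible biopsy composition),
planted pair tumor–tumor-TIL. Outcomes are drawn i.i.d. first; then each
pCR patient's map is edited until the planted pair's interface density
(4-adjacent A–B cell pairs per map cell) exceeds its baseline by
effect_size cohort SDs. The edit is micro-infiltration: isolated interior
tumor cells become single-cell TIL clusters, spread round-robin over tumor
clusters (each adds 4 interface adjacencies and a TIL node inside a tumor
region), while equally small far-away TIL clusters are retired to conserve
the TIL cluster count; any shortfall is met by thickening existing contact
zones. This targeting makes the group shift essentially exact (the
per-patient target is baseline + effect·σ) and concentrates the signal in
the planted pair's graph features rather than in every pair sharing the
TIL class — simpler edits (boundary relabelling, cluster relocation) were
tried and leaked most of their signal into neighboring pairs. Per-cell
80-feature vectors are sampled from class-conditional means/SDs measured
on six rendered 96-px reference tiles per class, with undefined (NaN)
statistics mapped to zero variance, rather than rendering one tile per
cell — tying feature distributions to the renderer at tractable cost.

Passing tests on this substrate show the machinery recovers a planted
spatial interaction under realistic class geometry and feature noise. They
do not show robustness to what the generator omits: scanner and staining
variation across sites, annotation error, within-class texture
heterogeneity, correlated feature noise, tissue-section artifacts, or
class imbalance as extreme as real slides. Real-data performance claims
require real cohorts.

## Numerical choices and degenerate inputs

- GLCM: 32 levels, distance 1, offsets (0,1), (1,1), (1,0), (1,−1) scaled
  by distance (diagonal offsets keep both components equal to the
  distance); symmetric, normalized; correlation is NaN at zero marginal
  variance; energy is the sum of squared probabilities (1 for a flat
  tile).
- LBP: P = 16, R = 2, bilinear neighbor sampling with a 1e−6 tie tolerance
  so equal-valued neighborhoods code as all-ones; uniform mapping to P+2
  bins; only pixels with full in-image neighborhoods are coded.
- Tamura contrast is σ/kurtosis^¼ with the 0-at-zero-variance convention;
  directionality is the magnitude-weighted resultant length of doubled
  gradient angles (1 = single orientation, 0 = isotropic or gradient-free);
  coarseness is mean best window size over 2^k, k ≤ 5, interior-cropped.
- Histogram entropy uses 256 bins in bits; kurtosis is non-excess.
- Exclusion rule: a feature column is dropped if it contains any NaN, is
  identically zero, or exactly duplicates an earlier retained column
  (keep-first); "repetitive" is read strictly as exact duplication, with
  the retained count reported, not asserted — it is data-dependent.
- Stain estimation requires ≥ 50 tissue pixels, else an
  insufficient-tissue error; unmixing is least squares with concentrations
  clamped at 0 for rendering.
- Single-node graphs give zero MST features; empty node sets give zero
  spectral features flagged invalid; algebraic connectivity of a
  disconnected graph is 0 by the Laplacian spectrum itself.
- All randomness flows from explicit integer seeds (kept below 2³¹);
  generator outputs are pure functions of (config, seed).

## Problem sizes used in the checks

The shipped tests and demo run at sizes chosen to exercise every code
path at desk scale: 64–96-px renders where full 224-px tiles are not the
point, 24–48 map grids, cohorts of 12–60 patients, 3–20 replicates per
stochastic property. The README demo is the full default configuration
(n = 60, 48×48 maps).

## Known limitations

- The exact membership of the 80-feature catalog and the 20 pair features
  follows standard parameterizations of the named families at the stated
  totals; both catalogs are config-overridable, and data-dependent
  retained counts (e.g. 55 of 80 on a particular cohort) will differ on
  other data.
- The geometric-graph radius and the edge-scope question (all pairs vs
  cross-class only) are interpretation choices, exposed in config.
- ReliefF is the binary-outcome variant; RReliefF and iterative variants
  are out of scope, as are weighted/directed graphs, sub-tile cell graphs
  and Delaunay/Voronoi constructs.
- Real-mode ingestion expects pre-extracted tiles plus QuPath-style
  GeoJSON and an outcome CSV; pyramidal WSI reading is an optional adapter
  boundary, not implemented here.
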