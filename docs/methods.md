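# Methods

## Model and procedure

`spassoc` measures bivariate spatial association between expression
variables on a spot lattice. The pipeline is:

1. **QC** — remove genes detected (count > 0) in fewer than
   `min_spots_per_gene` spots (default 10) and spots with total UMI below
   `min_umi_per_spot` (default 150). Both masks are computed on the raw
   matrix and applied simultaneously; the filter is not iterated to a
   fixed point, so a joint application can in principle leave an entity
   below threshold afterwards — this is logged, and a second `qc_filter`
   call tightens it. Simultaneous application keeps the operation
   deterministic and order-free.
2. **Normalization** — log counts-per-million: `log(1 + 1e6·c/total)`,
   natural log with pseudocount 1 (`log1p` of CPM). The log base is
   configurable; the natural log is the scverse ecosystem convention.
   Raw counts are retained alongside the layer.
3. **Neighborhood** — symmetric k-nearest-neighbor weights over spot
   coordinates, union-symmetrized and row-standardized, default k = 6
   (the hexagonal Visium lattice has six immediate neighbors). Ties in
   neighbor distance break by (distance, spot index); for up to 2048
   spots an exact full distance matrix guarantees that order, beyond that
   a ball tree is used. Isolated spots (impossible for kNN, possible for
   user-supplied weights) keep zero rows and contribute local L = 0.
4. **SVG selection** — Moran's I, `I = (n/S0)·zᵀWz / zᵀz`, computed per
   gene on log-CPM (the pipeline order implies normalized input). For
   row-standardized W, S0 equals the number of non-isolated spots.
   Selection is top-K by I or a threshold, default I > 0.3 strict; an
   `inclusive` flag switches to ≥ for workflows that phrase the criterion
   inclusively (e.g. I ≥ 0.4). No significance test is attached to SVG
   selection; permutation testing belongs to the pairwise stage.
5. **L-index** — with population-sd z-scores and row-stochastic W,
   local `L_i = (Wz_x)_i (Wz_y)_i` and global `L = mean_i L_i`. This is
   the unique closed form under which "global L is the mean of local L"
   coincides with the classical bivariate spatial-association measure:
   row standardization makes `(1/n)(Wz_x)ᵀ(Wz_y)` exactly the
   neighbor-set-size-weighted form of that statistic, and Cauchy–Schwarz
   gives |L| ≤ √(L(x,x)L(y,y)) ≤ 1. With W = I the statistic degenerates
   to the Pearson correlation, which the tests use as a closed-form
   limit.
6. **Permutation test** — the null hypothesis is *no spatial
   arrangement*, not *no expression correlation*: one random permutation
   of spot labels per round is applied jointly to both variables,
   preserving the per-spot (x, y) coupling while destroying spatial
   structure. Two-sided add-one p: `p = (1 + #{|L_perm| ≥ |L_obs|}) /
   (n_perm + 1)`; the add-one keeps p off zero and at a floor of
   1/(n_perm+1). All pairs in one invocation share the same permutation
   sequence — deterministic and vectorizable, and statistically valid
   because each pair's test is marginal. An alternative `perm_mode=
   "single"` permutes only the second variable, additionally breaking the
   value coupling. BH-FDR is applied once across the full tested pair set
   per invocation. The seed is a mandatory API argument (the CLI defaults
   it and logs it); identical seeds give bit-identical p and q.
7. **Cell-type scores** — each marker list collapses to the mean of the
   z-scored log-CPM of its present markers (z-scoring stops one
   highly expressed marker from dominating; plain mean and sum are
   options). Absent markers are dropped with a warning, a type with no
   present markers is an error, and the same pairwise-L machinery then
   measures cell-type colocalization. The bundled immune dictionary
   (B cells, T cells, Macrophages, Neutrophils, NK) is a fallback set of
   canonical human markers shipped as editable JSON
   (`src/spassoc/data/immune_markers_default.json`); tissue-specific
   analyses should supply their own dictionary. When the CLI falls back
   to the bundled set it silently restricts it to cell types with at
   least one present marker, since a generic default cannot promise
   coverage of an arbitrary dataset.
8. **Gene modules** — genes are clustered on the symmetric global-L
   matrix (diagonal 1) via distance d = 1 − L clipped to [0, 2] and
   average linkage; for every candidate cluster count k in [k_min, k_max]
   (default [2, 10], k_max clamped to g−1) the tree is cut and the mean
   silhouette on the precomputed distance is recorded; the maximizing k
   wins, ties to the smallest k (parsimony). Module ids m0, m1, … order
   by descending size, ties by lexicographically first gene; genes are
   processed in sorted order so the labeling is invariant to input order.
   Clustering input is fixed to the global-L matrix (rather than local-L
   or expression correlation) because it is the quantity the pipeline
   estimates and tests.
9. **Visualization** — volcano (global L vs −log10 q, q floored at the
   permutation resolution before the log), local-L hotspot maps with a
   symmetric diverging scale centered at 0 (a constant-zero field renders
   at the midpoint), a clustered heat map of the L matrix using the same
   1 − L / average-linkage contract as module detection, and per-module
   pattern and pair-hotspot maps. The y axis is inverted so low array
   rows (tissue top) plot at the top. Every figure writes a companion CSV
   of exactly the values handed to the renderer; tests check data, never
   pixels.

## Input dialects

SpaceRanger directories are read from MatrixMarket triplets plus
barcodes/features companions (gzipped or plain, old `genes.tsv` accepted)
and a tissue-positions CSV (with or without header), joined by barcode
key — never by file order — and restricted to in-tissue spots. Array
indices are converted to hexagonal geometry, `x = array_col/2`,
`y = array_row·√3/2`, matching SpaceRanger's parity convention for
`array_col`; raw (row, col) used as Euclidean coordinates would distort
the six-neighbor topology. Pixel coordinates stay in `spot_meta` for
plotting. Either filtered or raw barcode matrices work, since the
in-tissue flag restricts the spot set in both cases. The CSV dialect is a
counts matrix (spots × genes; `transpose=True` for the other orientation)
plus metadata with literal `x` and `y` columns, joined by row key;
non-integer counts are rejected as not-raw input.

## Synthetic data generator

`spassoc.simulate` emulates a Visium capture area as a hexagonal-offset
lattice (odd rows shifted 0.5, row spacing √3/2) with negative-binomial
counts: gene g at spot i has mean `base_mean · intensity_g(i) · libsize_i`
and variance `μ + α μ²`. Defaults, fixed once as the study conditions for
every simulation in the tests and acceptance script:

| parameter | default | meaning |
|---|---|---|
| `base_mean` | 10 counts | per-gene baseline mean per spot |
| `dispersion` α | 0.5 | NB overdispersion (α → 0 is Poisson) |
| `libsize_range` | (0.7, 1.3) | uniform per-spot depth factors |
| bump `amplitude` | 10 | fold-elevation of the domain peak over base |
| bump `background` | 0.02 | relative mean outside the domain |
| bump `radius` | 4 lattice units (reference fixture) | Gaussian scale `exp(−(d/r)²)` |
| lattice | 20 × 20 (400 spots) | reference fixture size |
| noise genes | 18 (reference fixture) | unstructured library background |

The low bump background is deliberate: real regional markers are close to
dropout outside their tissue domain, and in log-CPM space it is this
domain-shaped presence/absence structure — not small smooth fold
changes — that carries detectable spatial autocorrelation at Visium-like
depths. Under these conditions the reference colocalized pair yields
global L ≈ 0.64 (every seed > 0.5) and the exclusive pair L ≈ −0.40,
while unstructured genes center at the Moran null −1/(n−1). Planted
module fixtures place pairwise-disjoint bumps on a coarse grid (radius
0.3 × grid cell).

What the generator does *not* emulate: segmented tissue morphology,
spatial autocorrelation of library size, zero inflation beyond NB,
platform artifacts (spot swapping, diffusion), or gene–gene correlation
that is not spatially mediated. Passing tests therefore demonstrate
correctness and calibration of the statistics under an idealized NB spot
model, not performance on any particular real tissue.

## Numerical choices and degeneracies

- z-scores use the population standard deviation (ddof 0); constant
  variables raise "zero variance" in the single-pair API and are skipped
  with a warning (and reported) in the pairwise API.
- Permutation rounds are processed in blocks capped at 2·10⁷ matrix
  elements so memory stays bounded at any pair count.
- The exceedance comparison is `|L_perm| ≥ |L_obs|` (ties count against
  rejection, conservative).
- Silhouette is undefined for a cut that fails to split (or splits to
  singletons everywhere); such cuts record NaN in the trace and cannot be
  selected unless forced (`k_min = k_max`).
- An all-equal pairwise-L matrix is rejected as a degenerate distance
  rather than clustered arbitrarily.
- `detect_modules` clamps `k_max` to g−1 with a warning instead of
  erroring, so the default range works on small gene sets.
- SVG selection with neither `topK` nor `i_threshold` uses the documented
  default threshold 0.3; supplying both is an error.

## Problem sizes

The test suite and acceptance script run on 400-spot lattices with
999 permutations for calibration (200 simulations) and significance
checks (20 seeds per layout), 19 permutations where only the observed L
feeds a downstream stage (module detection), and ≤ 60-spot random
geometries for oracle comparisons. These sizes give stable rates (the
binomial 95% half-width at 200 simulations is ±0.030 around 0.05) while
keeping a full run in tens of seconds.

## Known limitations

- The permutation null conditions on the observed weight matrix; edge
  effects on small lattices are absorbed by the empirical null rather
  than corrected analytically. No analytic (normal-approximation)
  p-values are provided.
- BH controls FDR per invocation; combining tables across invocations
  re-raises the multiplicity question for the user.
- Local L values are reported without per-spot significance; hotspot maps
  are descriptive.
- Cell-type scores are marker averages, not deconvolved proportions;
  strongly overlapping marker lists (warned on) blur the distinction
  between types.
- HDF5 SpaceRanger input, H&E image underlays, and multi-sample merging
  are out of scope.
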