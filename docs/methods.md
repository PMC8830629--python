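# Methods

This note records the models the package implements, the assumptions and
defaults behind them, and the choices made where the method family leaves
room for interpretation.

## Spatial data model

All surfaces are single-band rasters with square cells in a projected
metric CRS; NaN is nodata, and every grid in one analysis must share
geometry exactly. Cell centres sit at `(x0 + (col+0.5)·s, y0 − (row+0.5)·s)`
for cell size `s` and upper-left origin `(x0, y0)`; all distances are in
meters. On-disk formats are deliberately text-based: ESRI ASCII grids for
rasters (written at full float precision so round trips are bit-exact),
CSV for points, GeoJSON for polygons. Non-square-cell ASCII dialects are
rejected rather than resampled.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

- **Continuous predictors** are white noise convolved with a Gaussian
  kernel of scale `autocorr_range` (default 500 m on 100 m cells) and
  standardized; `autocorr_range = 0` yields iid noise. Spectral synthesis
  would allow more general covariances but is unnecessary for what the
  pipeline consumes.
- **Anthropogenic features** — roads (random polylines), settlements and
  dumpsites (points), croplands (rectangles) — are rasterized and turned
  into Euclidean-distance predictors, matching the distance-to-feature
  form of the real predictor set.
- **Occurrences** are cells sampled *without replacement* with probability
  proportional to a known logistic suitability; sampling at cell level
  avoids duplicate coordinates that would distort the Moran's I screen.
  The default sample is 188 points labelled 55 dens / 88 scats / 45
  sightings; source classes are treated identically downstream (no
  weighting information exists to do otherwise).
- **The default truth** is `2.5·env1 − 2.0·env2 − 1.0·dist_roads − 4.0`
  (standardized predictors). The intercept sets species prevalence near
  14% of the landscape: a carnivore occupying roughly a seventh of a
  semi-arid study region. Prevalence matters more than it looks — at
  intercept 0 the species occupies half the landscape and even the
  *generating* model cannot separate presences from background beyond
  AUC ≈ 0.72, so a realistic low prevalence is what makes "high
  predictive performance" achievable at all.
- **Conservation areas** are non-overlapping random rectangles, by default
  nine in a 2 wildlife-refuge / 2 protected-area / 5 non-hunting-area mix
  (largest-remainder apportionment for other counts).
- **Prey layers** are per-species (suitability, density) pairs with
  suitability in [0, 1] and piecewise-constant density over rectangular
  abundance zones, combined downstream as Σ suitability × density.

All randomness flows from the spec's single integer seed through named
`numpy` generators (fixed integer stream ids); identical specs are
bit-identical, different seeds differ. What the generator does *not*
emulate: terrain (no DEM, slope, roughness), NDVI-like seasonal layers,
scale-dependent species responses (the truth acts at the native cell
scale, so the best focal extent on synthetic data is typically the
smallest — the opposite of a species responding to broad-scale structure),
and observation bias (e.g. roadside sampling). Passing tests therefore
validate the machinery and its statistical behaviour, not any claim about
real landscapes.

## Screening

- **Collinearity**: greedy Pearson screen at |r| > 0.8. The worst pair is
  found and the member with the larger mean |r| against all other retained
  variables is dropped (ties to the later variable); the cut value is the
  method's convention, the drop rule is ours since only the cut is
  conventional. Zero-variance variables have undefined r; they are warned
  about and retained.
- **Spatial autocorrelation**: global Moran's I of occurrence counts over
  occupied square aggregation cells (default 1 km), inverse-distance
  weights w_ij = 1/d_ij, z-score under the normality assumption with
  E[I] = −1/(n−1). The value field, weighting, and band are documented
  stand-ins — point-pattern Moran's I has no single canonical recipe — and
  the implementation is validated against a brute-force double loop and a
  Monte-Carlo null calibration (≈95% of random patterns give |z| < 1.96).
  Constant counts make the statistic undefined; a `degenerate` status is
  returned instead of raising.

## Suitability ensemble

MaxEnt is replaced by a ridge-penalized presence-background logistic
regression on standardized linear + quadratic features — the same model
family at this feature complexity, fully specifiable without external
software. Hinge/product features are out of scope. Per replicate:
presences are split 75/25 into calibration/evaluation, the calibration
set is bootstrap-resampled, and `n_background` cells are drawn uniformly
over valid cells *with replacement* (presences not excluded, the
presence-background convention; replacement keeps the 10000 default
meaningful on small grids). Splitting before bootstrapping keeps the
evaluation set untouched by resampling. The solver is L-BFGS with the
iteration cap as configured (default 500); a replicate that hits the cap
is flagged, and the ensemble is valid while at least half converge.
Regularization defaults to 1 (unit ridge); as it grows, coefficients
shrink to 0 and predictions flatten to the prevalence constant.

Evaluation is the rank (Mann-Whitney) AUC with ties counted ½, of
held-out presences against the replicate's background sample. Variable
importance is permutation-based (mean AUC drop, clipped at 0, rescaled to
sum to 100): the path-dependent "percent contribution" of the original
software is not reproducible outside it. Response curves sweep one
variable over its observed range with the others at their means.

Thresholds: the 10th percentile (linear interpolation between order
statistics — no percentile convention is canonical, so the numpy default
is used and frozen in tests) of ensemble HS at the union of training
presences, or the mean HS at *all* occurrence points (whether the mean
rule should use training points only is ambiguous; all points is the
implemented reading). Binarization is threshold-inclusive (HS ≥ t).

## Connectivity

- **Resistance**: R_raw = 1000^(−HS) rescaled linearly onto [1, 10] over
  the transform's *analytic* codomain [0.001, 1], not the empirical range
  of the map — this makes R(HS) map-independent and pins R(1) = 1,
  R(0) = 10 exactly.
- **Cost distance**: Dijkstra on the 8-neighbour lattice, edge cost
  ((R_i + R_j)/2)·d with d = s orthogonally and s√2 diagonally (the
  standard cost-distance convention). One cost unit = one
  resistance-weighted meter, anchored by the 50000-cost-units ↔ 50 km
  correspondence at R = 1.
- **Resistant kernel**: linear decay K_s = max(0, 1 − c_s/D) per source,
  summed. Linear decay is the classic default of this kernel family; the
  kernel function is an assumption, and a Gaussian alternative would only
  change the within-threshold weighting, not the support.
- **Least-cost paths**: one Dijkstra tree per source; paths are recovered
  by a deterministic backward walk choosing the neighbour that minimizes
  `dist[n] + edge(n, cur)`, ties to the lower flat cell index, so reruns
  are bit-identical. Factorial corridor strength counts unordered source
  pairs whose buffered path (default buffer 200 m = 2 cells; the buffer
  width is conventional, configurable, and logged) covers a cell; one
  path is kept per pair even under cost ties. No dispersal threshold is
  applied to corridors.

## Cores, metrics, prioritization

- **Cores**: kernel cells strictly above the 70th percentile of the
  *positive* kernel support, 8-connected. Taking the percentile over all
  cells is available by config but defaults off — on large landscapes
  zeros dominate and an all-cells percentile would make cores
  near-everything. Strict ">" means a constant positive kernel yields an
  empty set; that is reported as a `degenerate_uniform` status rather than
  an error. Core delineation is invariant under any strictly monotone
  rescaling of the kernel.
- **Pattern metrics**: PLAND, NP (8-connected), LPI, and correlation
  length = area-weighted mean radius of gyration, with the radius of
  gyration as the mean (not RMS) distance of patch cells to the patch
  centroid, the FRAGSTATS GYRATE convention.
- **PC/dPC**: nodes carry area (km²) or kernel strength; A_L is the
  non-nodata landscape area (km²) for area attributes and total kernel
  mass for strength — dPC is a ratio, so the attribute unit cancels and
  rankings are invariant under uniform attribute scaling. Inter-patch
  distance is the minimum cell-centre distance (edge-to-edge);
  p_ij = exp(−k·d_ij) with k calibrated by p(d_med) = 0.5 at the median
  dispersal distance (the common calibration of this index family;
  configurable). p*_ij maximizes the path product, computed as a shortest
  path on −ln p edge weights; the connector fraction is the residual
  dPC − intra − flux, which equals its direct definition by the
  decomposition identity (asserted to 1e-9 in tests). In the pipeline,
  d_med is tied to the dispersal scenario as half the optimal-habitat
  reach (D/2 meters).
- **Gap analysis**: a target cell is covered iff its centre lies inside a
  conservation-area polygon (bit-exact, no partial-cell areas).
  Conservation-area prioritization treats each CA as a patch with the
  suitable-habitat area inside it as attribute; CAs with zero suitable
  habitat violate the positive-attribute invariant and are excluded with
  a warning. CA-to-CA distances are polygon boundary distances.

## Pipeline

The best focal extent is selected by mean test AUC across replicates,
ties toward the larger extent. The manifest records the config, package
version, per-stage wall times, and SHA-256 of every artifact; a rerun
with the same seed reproduces identical hashes.

## Numerical and testing choices

- Percentiles everywhere use linear interpolation between order
  statistics.
- Focal windows include cells whose centre lies within the radius; edge
  windows shrink to the available cells (no nodata padding), so constant
  fields are preserved exactly; a radius below half a cell is an identity
  with a warning.
- Oracle tests pair each core numeric (cost distance, least-cost paths,
  Moran's I, AUC, correlation length, PC/dPC) with an independent
  brute-force implementation — Bellman-Ford-style relaxation, double
  loops, exhaustive simple-path enumeration — at 1e-9 relative tolerance
  on fixtures up to 15×15 cells / 7 nodes.
- Statistical suites run at desk scale: 64×64 landscapes, 188 presences,
  dispersal thresholds 5–25 km, 10–100 seeds per suite, chosen so the
  whole test run stays around a minute while keeping each check's power
  (e.g. parameter recovery passes 20/20 seeds with minimum ensemble AUC
  0.834 under the defaults).
- "Monotone trend" suites (pattern metrics vs focal extent, dPC vs
  dispersal distance) use the sign of the Spearman rank correlation per
  seed rather than stepwise inequalities: single-cell labeling noise can
  produce one-cell dips in correlation length that a trend test correctly
  ignores.

## Known limitations

- The suitability model is linear + quadratic only; strongly non-monotone
  or interaction-driven truths will be underfit.
- Cost distances are lattice geodesics; they overestimate true Euclidean
  shortest paths by up to ~8% in direction-dependent error (the usual
  8-neighbour anisotropy), which is inherited by kernels and corridors.
- The kernel-percentile core rule makes core extent sensitive to the
  source configuration near the threshold.
- dPC comparisons across attribute types (area vs strength) are rank-wise
  meaningful but not numerically commensurable.
- Synthetic landscapes carry no scale-dependent species response, so
  multi-extent model selection on them favors the native resolution.
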