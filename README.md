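# landconnect

Multi-extent habitat suitability modeling, resistant-kernel landscape
connectivity, corridor mapping, graph-theoretic patch prioritization, and
conservation-area gap analysis on raster landscapes.

The package is aimed at landscape ecologists and conservation planners who
need to go from species occurrence points and raster predictors to a ranked
set of core habitats and corridors, and to an assessment of how well an
existing conservation-area network covers them. A first-class synthetic
landscape generator makes the whole chain testable end-to-end without any
external geodata.

## The method

1. **Multi-extent niche modeling.** Predictors are smoothed with circular
   moving windows at several focal radii (defaults 0.1, 0.5, 1, 2, 4 km).
   At each extent a presence-background suitability model — a
   ridge-penalized logistic regression with linear + quadratic features,
   the transparent analogue of a MaxEnt model — is fitted as a bootstrap
   ensemble (10 replicates, 10000 background points, 75%/25%
   calibration/evaluation split, 500-iteration cap) and scored by the
   rank AUC of held-out presences against background. Continuous
   suitability maps HS ∈ [0, 1] are binarized with the 10th-percentile
   training-presence and the mean-occurrence-suitability thresholds, and
   each binary map is summarized with PLAND, NP, LPI, and correlation
   length (area-weighted mean radius of gyration).
2. **Resistance.** The best-extent HS map (highest mean test AUC) becomes a
   resistance surface via R_raw = 1000^(−HS), linearly rescaled onto
   [1, 10] so that R = 1 at HS = 1 and R = 10 at HS = 0.
3. **Resistant kernels and corridors.** Movement is modelled on the
   8-neighbour lattice with edge cost ((R_i + R_j)/2)·d_ij; one cost unit
   is one resistance-weighted meter, so a dispersal threshold of 50000
   cost units is 50 km of movement through optimal habitat. Around every
   occurrence point a dispersal kernel decays linearly from 1 to 0 at the
   threshold in accumulated (Dijkstra) cost; kernels are summed into a
   movement-rate surface, repeated for five thresholds (50–250 km at
   full scale). Factorial least-cost paths between all pairs of sources,
   buffered and summed, map corridor strength.
4. **Cores and prioritization.** Core habitats are 8-connected components
   above the 70th percentile of the positive kernel support. Each core
   network becomes a graph whose nodes carry an attribute a_i (area or
   kernel strength) and dispersal probabilities p_ij = exp(−k·d_ij)
   calibrated by p(d_med) = 0.5. The probability of connectivity
   PC = Σ_ij a_i a_j p*_ij / A_L² (p*_ij the maximum-probability path)
   yields each patch's importance dPC_k = 100·(PC − PC_without_k)/PC,
   decomposed exactly into intra, flux, and connector fractions.
5. **Gap analysis.** Percent of core-habitat cells whose centres fall
   inside conservation-area polygons, per category (wildlife refuge,
   protected area, non-hunting area) and in total; conservation areas are
   themselves ranked by dPC using the suitable habitat they contain.

## Worked example

A complete synthetic run (100×100 cells of 100 m, 188 occurrences from a
known logistic truth, nine conservation areas) with dispersal thresholds
scaled to the 10×10 km landscape:

```python
import landconnect as lc

cfg = lc.PipelineConfig(
    synthetic=lc.LandscapeSpec(seed=1),
    dispersal_thresholds=(5000.0, 10000.0, 15000.0, 20000.0, 25000.0),
    seed=1,
    outdir="demo_run",
)
lc.run_full(cfg)
```

The log prints the screening and model-selection trail:

```
Moran's I on occurrences: I=-0.0010 z=0.933 (ok)
extent 100 m: mean test AUC 0.862
extent 500 m: mean test AUC 0.861
extent 1000 m: mean test AUC 0.842
extent 2000 m: mean test AUC 0.748
extent 4000 m: mean test AUC 0.710
best extent: 100 m
```

The occurrence pattern is spatially uncorrelated (|z| < 1.96), all extents
clear AUC 0.8 except the two broadest, and the native 100 m extent wins —
on this synthetic landscape the true suitability acts at the native cell
scale, so smoothing can only blur it. Variable importance recovers the
generating model (`variable_importance.csv`: env1 50.8%, env2 37.6%,
dist_roads 7.1%, all noise predictors < 3%). The run directory then holds,
per dispersal threshold, the kernel surface, the core-patch table, and the
dPC rankings, e.g. `dpc_area_D25000.csv`:

```
rank  id  attribute    dpc
   1   1      24.70  96.94
   2   2       2.93  17.61
   3   3       2.37  13.72
```

and `gap_coverage.csv` reports that the nine-area conservation network
covers between 5.6% (5 km dispersal) and 19.8% (25 km) of the predicted
core habitat — the number of cores drops and their extent grows as
dispersal ability increases, so coverage of the merged southern cores
improves.

The same stages are available as shell commands: `landconnect synth`,
`fit`, `kernel`, `flcp`, `cores`, `metrics`, `rank`, `gap`, and
`run-all` (see `landconnect --help`).

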