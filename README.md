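# llecorridor

Do the linear landscape elements (LLE) of agricultural landscapes — field
margins, road verges, ditches — act as dispersal corridors for vascular
plants?  `llecorridor` implements a complete analysis chain for that
question, built around two isolation measures for pairs of vegetation
plots:

- **Euclidean distance** — plain spatial separation (the distance-decay
  baseline), and
- **resistance distance** — the effective electrical resistance of the LLE
  network between the plots, computed by circuit theory over a resistance
  raster (LLE cells 0.01 Ω, a 5-m halo at 0.02 Ω that closes sub-10-m gaps
  at a penalty, impassable matrix).  Resistance falls with every additional
  connecting path, so it measures network connectivity, not just length.

Floristic similarity of two relevés is the unweighted Jaccard index
*J = c / S* (shared species over union), computed for all species and for
subsets by phytosociological group and dispersal-distance class.  Each
similarity column is regressed on each isolation measure with a
binomial-logit GLMM (proportion or binary coding; crossed random
intercepts for study area and both plots; observation-level intercept when
overdispersed), and the two measures are compared by the slope contrast

    Z = (b_resistance − b_euclidean) / sqrt(se₁² + se₂²).

A more negative resistance slope — in the field data, found for
margin-margin pairs and for species of traditional grasslands with short
or medium dispersal distances — is the corridor signal.  Predicted Jaccard
gains from maximum to minimum isolation are translated into species counts
via Δc = ΔJ × S̄.

The package includes a seeded synthetic-landscape and community generator
(random field mosaics with LLE networks, plots, and colonisation dynamics
with corridor- vs matrix-channel species), so the full pipeline is
reproducible and testable without survey data.

## Worked example

```python
from llecorridor import pipeline, similarity

run = pipeline.run_synthetic_analysis(
    seed=1, species_sets=("short_dispersal", "long_dispersal")
)
r, p = similarity.correlation_check(run.pair_table)
print(f"resistance vs Euclidean correlation: r = {r:.2f}")
print(run.table1[["species_set", "lle_combo", "b_euclid", "b_resist",
                  "delta", "p_delta"]].to_string(index=False))
```

Output from the run above:

```
resistance vs Euclidean correlation: r = 0.50
    species_set     lle_combo  b_euclid  b_resist  delta  p_delta
short_dispersal margin-margin    -0.568    -1.042 -0.475    0.045
short_dispersal  margin-ditch    -0.563    -1.021 -0.458    0.104
short_dispersal   ditch-ditch    -1.668    44.682 46.350    0.999
 long_dispersal margin-margin    -0.822    -0.747  0.075    0.674
 long_dispersal  margin-ditch    -1.163    -0.911  0.252    0.213
 long_dispersal   ditch-ditch    -0.482    -0.794 -0.312    0.478
```

Reading it: for short-dispersal (corridor-channel) species the resistance
slope `b_resist` is more negative than the Euclidean slope `b_euclid`
(negative `delta`, significant for margin-margin) — their similarity
tracks network connectivity beyond plain proximity.  For long-dispersal
(matrix-channel) species the two slopes are statistically
indistinguishable (`p_delta` large).  The wild ditch-ditch resistance
slope comes from a stratum with very few pairs in this draw; sparse strata
and species sets produce exactly this kind of unstable estimate in real
survey data too, which is why the headline inference rests on the
margin-margin simple slopes and their contrast.  `b_*` are slopes per SD
of the isolation measure on the logit scale; `p_euclid`/`p_resist`
(omitted above) are conservative t-tests at the minimum degrees of
freedom; `p_delta` is the two-tailed Z-contrast.

The same chain is scriptable from the shell:

```bash
llecorridor simulate  --seed 1 --out-prefix scratch/demo
llecorridor rasterize --geometry scratch/demo_geometry.csv --area A1 --out scratch/A1.asc
llecorridor resistance --raster scratch/A1.asc --plots scratch/demo_plots.csv --out scratch/A1_res.csv
llecorridor pairs --releves scratch/demo_releves.csv --classification scratch/demo_classification.csv \
                  --plots scratch/demo_plots.csv --resistance scratch/demo_resistance.csv --out scratch/pairs.csv
```

## Library layout

| module | contents |
| --- | --- |
| `synth` | landscape/community generators, `LandscapeConfig`, `CommunityConfig` |
| `rasterize` | resistance rasters, gap-closing halo, ESRI ASCII I/O |
| `circuit` | conductance graphs, effective-resistance solver, plot-pair resistances |
| `similarity` | Jaccard pair table, response coding, z-transform, correlation check |
| `glmm` | Laplace binomial GLMM with crossed random intercepts, overdispersion/OLRE, parametric-bootstrap LRT, cumulative-residual linearity check |
| `models` | `IsolationModel` / `IsolationResults` (fit, simple slopes, bootstrap test, predictions, plots) |
| `inference` | slope SEs, bracketing-df t-tests, slope contrasts, report table |
| `predict` | predictions at isolation extremes, ΔJ → Δ species translation |
| `pipeline` | end-to-end runs; `cli` exposes them as subcommands |

See `docs/methods.md` for the model details, generator assumptions, and
numerical choices.

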