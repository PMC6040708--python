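# Methods

`llecorridor` tests whether open linear landscape elements (LLE — field
margins, road verges, ditches) act as dispersal corridors for vascular
plants in intensive agricultural landscapes.  The underlying logic: if LLE
carry multi-generational plant migration, then the floristic similarity of
two vegetation plots should respond more strongly to the *connectivity of
the LLE network between them* (measured as circuit-theory resistance
distance) than to plain spatial proximity (Euclidean distance).  The
package implements the complete analysis chain plus a synthetic-data
generator that reproduces the statistical structure of such a field study,
so every stage is testable without survey data.

## Resistance rasters

LLE geometry (centreline segments with widths) is rasterised to a 1-m grid.
Cells on an element get resistance 0.01; all matrix cells within 5 m of an
LLE cell get doubled resistance 0.02 (this closes gaps shorter than 10 m at
a penalty, reflecting that small interruptions are occasionally bridged);
all other cells are impassable (infinite resistance).  Rasters extend 500 m
beyond each 1-km² study area so that detour paths outside the area are not
truncated.  Cell membership is a centre-point test against the flat-capped
rectangle of each segment (flat caps keep inserted gap lengths exact);
halo membership is an exact Euclidean distance transform between cell
centres.  Buffering is idempotent and never alters LLE cells.

Grids are exchanged as ESRI ASCII (.asc) with infinite resistance stored as
NODATA.  No projections: coordinates are planar metres, x right, y up,
row 0 = northernmost (ESRI convention).

## Effective resistance

Each finite cell is a node; orthogonal neighbours are joined with
conductance equal to the mean of the two cell conductances (1/resistance),
diagonal neighbours (8-neighbourhood, the default, matching the common
circuit tools for landscape rasters) with that mean divided by sqrt(2).
The neighbourhood and edge-conductance convention is an assumption — the
reference tools do not document a single canonical choice — and the
4-neighbour mode is available.  Pairwise effective resistance is computed
by grounding one plot node of each connected component, factorising the
reduced graph Laplacian once (dense Cholesky below 1 500 nodes, sparse LU
with COLAMD ordering above), and solving one unit-current system per
remaining plot node; `R_ab = v_a(a) - v_a(b) - v_b(a) + v_b(b)`.  Plots are
snapped to the nearest finite cell within 5 m (deterministic row/col
tie-break).  Pairs in different components are flagged disconnected and
excluded from the models — infinite resistance is not on the modelled
scale — with counts logged.

The solver is verified against series/parallel closed forms, a dense
Laplacian-pseudo-inverse oracle on random graphs, the resistance-metric
axioms, Rayleigh monotonicity, and the resistance scaling law.

## Similarity and the pair table

For every unordered pair of plots within a study area the unweighted
Jaccard index J = c/S (c shared species, S union size) is computed for the
full species list and per species subset: each phytosociological group,
each terrestrial dispersal-distance class (short / medium / long), and the
aquatic-dispersal flag (which overlaps the classes).  A pair whose union is
empty for a subset is undefined for that subset and is dropped per model,
not globally.  Each pair carries its Euclidean distance, resistance
distance, and LLE-type combination (margin-margin / margin-ditch /
ditch-ditch; symmetric in plot order).

Responses are coded per species set: proportion coding passes (c, S) as
binomial successes and trials — the only coding under which J = c/S is a
binomial proportion, since the weights actually used in the original
analyses are undocumented — or binary coding 1{J > 0} for sparse sets
(conventionally the arable-weed/trackside/wasteland group and the
aquatic-dispersal class, or automatically when more than half of the
defined J values are zero).  Isolation measures are z-scored (sample SD,
n − 1) over the rows entering each model, with the transform stored for
data-scale predictions.

## The mixed model

Each model is a binomial-logit GLMM with six fixed-effect parameters —
intercept, z-scored isolation measure, two LLE-combination dummies
(margin-margin baseline), and the isolation × combination interactions —
and crossed random intercepts for study area and for each plot of the pair
(each plot appears in many pairs).  Proportion-coded models additionally
receive an observation-level random intercept (OLRE) when the Pearson
overdispersion statistic is significantly large (chi-square test at
alpha = 0.05 on N − p df); binary models never do, as Bernoulli responses
carry no overdispersion information.

Estimation maximises the Laplace-approximate marginal likelihood: the
inner loop is a penalised IRLS (joint Newton with step halving) over the
fixed effects and the conditional modes of the random effects; the outer
loop is bounded L-BFGS-B over the log standard deviations (bounds
log 1e-3 … log 30; a variance at the lower bound is reported as a singular
fit, not an error), refined by a short Nelder–Mead polish.  The fixed-effect
covariance is the fixed-effect block of the inverse joint Hessian at the
optimum (conditional on the estimated variances, the usual convention).
One deliberate difference from lme4's `glmer`: glmer profiles the fixed
effects inside the outer Laplace objective, whereas here they stay at the
joint penalised-likelihood mode; on test data the two agree to ~2% of one
standard error on coefficients and to well under 1% on variance
components.  Fits are deterministic given the data; only bootstrap and
simulation routines consume seeds.

### Inference

The isolation main effect is tested by unconditional parametric bootstrap:
responses are simulated from the fitted null model (re-drawing the random
effects from their estimated distributions), both models are refitted, and
the observed likelihood-ratio statistic is referred to the simulated
distribution with the estimator p = (1 + k)/(B + 1) (never exactly zero).
The null drops the isolation main effect *and* its interactions, since a
main effect cannot be removed below its interaction.  Default B = 999;
calibration studies in the test suite use B = 199.  Replicate refits reuse
the parent estimates as warm starts with a slightly relaxed inner
tolerance; refit failures beyond 5% trigger a warning with the effective B.

Simple slopes per LLE combination are the main effect (margin-margin) or
main + interaction, with standard error
sqrt(se_main² + 2 cov(main, int) + se_int²) taken from the fitted
fixed-effect covariance (the only in-model source for that covariance).
Slopes are t-tested under two bracketing degree-of-freedom conventions,
df_max = N − p − g − 1 (N pairs) and df_min = n − p − g − 1 (n plots,
counted from the rows actually entering the fit), with the conservative
df_min p-value as the headline.  The resistance-vs-Euclidean slope
difference is a standard-normal contrast Z = (b₁ − b₂)/sqrt(se₁² + se₂²),
two-tailed; it is a Z statistic by construction, not a t.

A linearity check runs on the GLM variant of each model (study area as a
fixed effect, no random intercepts): Pearson residuals are ordered by the
isolation predictor, cumulated, and the supremum of the |process|/sqrt(N)
is referred to a wild bootstrap with Rademacher signs on the residuals.
This is a simplification of the Lin–Wei–Ying resampling used by the
`gof::cumres` approach with the same calibration target; its size and
power are verified by simulation in the test suite.

### Predictions

Population-level predicted Jaccard similarities (random effects at zero,
fixed effects only — the standard `glmer` population prediction; a
logit-normal marginalisation would shrink predictions toward 0.5) are
evaluated at the minimum and maximum isolation observed among the
margin-margin pairs included in each model (configurable to the global
range).  The gain ΔJ from maximum to minimum isolation is computed for both
measures; the excess of the resistance gain over the Euclidean gain is
translated into common species via Δc = ΔJ × S̄, rounded to the nearest
integer, where S̄ is the mean union size of the margin-margin pairs for
that species set (configurable to all pairs; which subset the original
tables used is not documented).

## Synthetic data generator

The generator emulates the field study's sampling frame: 8 study areas of
1 km², LLE areal density drawn per area from 2.5–10%, element widths
2–5 m, a configurable ditch fraction (default 0.35), 5–8 plots per area
placed on elements ≥ 2 m wide with ≥ 100 m mutual spacing, and geometry
extending through the 500-m frame.  Landscapes are random rectangular
field mosaics: Poisson-spaced vertical/horizontal boundary lines (mean
spacing scaled to the density target, 40–250 m) partition the extended
area, and LLE grow along a connected random subset of boundaries until the
target density is reached — reproducing the bocage-to-open gradient with
few parameters.  Gaps are inserted by deleting element stretches (default
0.3 gaps per km of LLE, lengths 2–12 m, so some gaps are halo-closable and
some not), avoiding plot locations.  A run seed deterministically spawns
per-area child seeds; identical seeds give identical tables.

Communities are simulated at the plot level (plots are the observation
unit; explicit cell-level spread would add nothing the analysis can see
while multiplying runtime): each of 120 pool species starts as independent
Bernoulli(0.10) occupancy per plot, then per generation colonises
unoccupied plots with per-source probability exp(−d/λ), combined over
occupied source plots.  The distance d is the pair's resistance distance
for corridor-channel species (short- and medium-dispersal classes),
Euclidean distance for matrix-channel species (long-dispersal), and the
larger single-channel probability for species assigned to both.  There is
no extinction, so occupancy is monotone over generations.  Defaults:
4 generations, corridor kernel scale 0.015 ohm, matrix kernel scale 150 m.
These were calibrated once against the field study's data scales — they
yield plot richness ≈ 27 ± 9 species, mean all-species Jaccard ≈ 0.33, and
a resistance–Euclidean correlation of r ≈ 0.50 — and then frozen.  Note
the kernel scales live on different axes: ohms of effective resistance
(O(0.01–0.3) under the 0.01-per-cell parameterisation) versus metres.

What the generator does *not* emulate: cover abundances (presence/absence
only), demography, seed banks and extinction, environmental gradients
between plots, the ditch-specific failure modes of resistance distance
(flow direction, culverts) — so, unlike the field data, synthetic corridor
effects are not specific to margin-margin comparisons — and the
phytosociological idiosyncrasies of real species pools.  Passing end-to-end
tests therefore show that the analysis recovers a corridor signal *when
the generating process matches the model's assumptions*, not that real
landscapes behave this way.

## Numerical choices and problem sizes

- Circuit solver tolerance is that of the direct factorisation (~1e-10
  relative); disconnected pairs are flags, not large constants.
- PIRLS converges at 1e-13 relative change (1e-10 inside bootstrap
  replicates); outer optimiser ftol 1e-12 with a finite-difference step of
  1e-5 on the log-SD scale.
- Logit linear predictors are clipped at ±30 before exponentiation.
- Degenerate inputs: empty geometry rasterises to an all-infinite grid with
  a warning; a plot further than 5 m from finite cells, an unclassified
  species, a zero-variance isolation column, and infeasible plot placement
  all raise informative errors.
- Test-suite problem sizes are chosen for a desk-scale run: Wald-coverage
  study 50 replicates at ~2 000 pairs; bootstrap calibration 100 replicates
  at B = 199 with a single grouping factor; linearity calibration 60
  replicates at B = 199; end-to-end corridor-signal study 20 seeded runs at
  full default conditions (8 areas, 1-m cells, 500-m frames).

## Known limitations

- Resistance of woody LLE and forest edges is treated like open LLE by
  default; the cell resistance values are overridable (`r_lle`, `r_buffer`
  in the rasteriser and CLI) but not per element type.
- No current-density maps or all-to-one modes; no flow direction along
  ditches.
- df_max/df_min bracketing is a heuristic; no Satterthwaite or
  Kenward–Roger approximation is attempted.
- No multiple-testing correction across species sets (by design).
- The bootstrap re-draws random effects (unconditional); conditioning on
  the estimated effects is a defensible alternative not implemented.
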