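# Methods

This note documents the models implemented in `corridorscape`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Ensemble habitat-suitability model

The distribution model is presence/pseudo-absence. Given presence points and
`n` background points (default 1000, drawn uniformly without replacement
from all valid cells not containing a presence), each of the registered
learners is fitted on repeated stratified splits (default 10 replications,
75% of presences and of absences for training) and scored by the area under
the ROC curve on the held-out quarter. AUC is computed as the Mann–Whitney
rank statistic — the probability that a random presence outscores a random
pseudo-absence, ties counting ½ — which is exact under ties and needs no
curve interpolation.

Ensemble weights are the per-learner mean test AUCs normalized to sum to 1,
and the ensemble prediction is the weighted average of each learner's mean
prediction across replications. Weighting by raw AUC (rather than AUC − 0.5)
is the simplest accuracy-proportional rule; an uninformative learner (AUC
0.5) is thereby down-weighted but not excluded, which keeps the weights
well-defined even when all learners are weak. Pseudo-absences are drawn once
per time step and shared across replications, so replication variance
reflects the split, not the background.

The four registered learner families are a regularized logistic scorer (a
maximum-entropy-style linear model on standardized covariates), boosted
depth-2 trees, an additive scorer (cubic-spline basis expansion + logistic),
and bagged decision trees (a random forest). They satisfy a minimal
fit/predict contract — scores in [0, 1], deterministic given a seed — and
scikit-learn estimators back them; any scorer honoring the contract can be
registered. The `fast` subset (logistic + additive) exists for replicated
experiments where hundreds of refits are needed.

Variable importance is leave-one-covariate-out (jackknife): refit the
ensemble without each covariate, take the drop in weighted mean test AUC
(floored at zero), and normalize the drops to percentages. Jackknife
replications default to 5 — importance ranks stabilize well before the AUC
estimate itself does, and the refit count scales with the covariate count.

Suitability maps are classed high/moderate/marginal by exact Jenks natural
breaks: an O(n²k) dynamic program over the sorted values minimizing total
within-class squared deviation, with class boundaries at each lower class's
maximum and membership by half-open intervals. On rasters beyond 20,000
valid cells the breaks are computed on a seeded subsample of that size to
bound the quadratic cost. Binarization uses the threshold maximizing
sensitivity + specificity over midpoints of adjacent unique scores, ties
resolved toward the lowest threshold so the choice is deterministic.

Before fitting, covariates are screened for collinearity: Pearson
correlations over all jointly valid cells, and whenever a pair exceeds
|r| = 0.7 the later-listed member is dropped (a deterministic stand-in for
the analyst's judgement; list order therefore encodes priority).
Zero-variance layers get r = 0 by convention and a warning. The correlation
is computed over the whole grid rather than at presence cells only — the
screen protects the model matrix, not the sampling design.

## Resistance and least-cost corridors

Habitat suitability h ∈ [0, 1] maps to resistance by
R = 100 − 99·(1 − exp(−c·h))/(1 − exp(−c)), a decreasing curve pinned to
R(1) = 1 and R(0) = 100 for every shape factor c > 0. The candidate shape
factors are {2, 1, 0.5, 0.25}; c = 0.25 (nearly linear) is the default, and
`sensitivity_scan` tabulates corridor count and area over the c × cutoff
grid so the choice can be revisited per landscape.

Cost-weighted distance (CWD) is multi-source Dijkstra over the 8-connected
grid with edge cost cellsize·d·(R_i + R_j)/2, d = 1 for cardinal and √2 for
diagonal steps — the averaging convention of the common cost-distance
tools. Source (PA) cells start at cost 0; accumulated units are
cost-weighted km, so with R ∈ [1, 100] on 1 km cells the default 200 cw-km
truncation is on the natural scale. The implementation is a bespoke binary
heap Dijkstra keyed by (cost, row, col), which fixes equal-cost ties toward
lower row then lower column and makes path reconstruction reproducible; a
sparse-graph Dijkstra serves as an independent cross-check in the tests,
and on 4×4 grids the implementation is verified against exhaustive
enumeration of simple paths.

For each PA pair: the LCP cost is the minimum CWD over destination cells,
the LCP length is the geometric length of the reconstructed path, the
Euclidean distance is the minimum center-to-center separation of the two
masks (edge-to-edge), and the quality ratios are CWD:EUD and CWD:LCP.
Overlapping or 8-adjacent PA masks get LCP cost 0 with an empty interior
path. The normalized corridor CWD_A + CWD_B − LCP cost is 0 exactly on the
optimal path; the truncated corridor keeps cells within the cw-km cutoff
(with a 1e-9 slack so the optimal path itself never falls to float
round-off). Per-PA CWD surfaces are computed once and shared across that
PA's pairs. The default pair list is all unordered pairs with a finite
path; a configured pair list reproduces a fixed corridor network.

## Circuit theory

The resistance raster becomes a resistor network: valid cells are nodes,
8-neighbor cells are joined by a resistor equal to the step's CWD edge cost,
and each PA is collapsed to a single supernode by exact node contraction of
its member cells — an ideal zero-internal-resistance region. Contraction
(rather than tying member cells to the supernode with a very large
conductance) keeps the Laplacian well-conditioned and makes effective
resistances exact: finite ties of conductance k·g_max bias the effective
resistance by ~1/(k·g_max) per terminal, which double precision cannot push
below 1e-8 without destroying the solve's forward accuracy.

Injecting 1 A at one supernode and grounding the other, the reduced
Laplacian system is solved by sparse LU with iterative refinement; the
solve must reach a normwise backward error |r|/(|L||v|+|b|) ≤ 1e-8.
Per-cell current density is half the sum of absolute currents on incident
edges (Amps/cell); contracted PA cells carry no individual density. Pinch
points are solved per link on the domain of its truncated corridor plus the
two PA masks, and each corridor's mean and maximum density are reported —
the normalization of per-cell densities differs between summary conventions,
so both are exported. Effective resistance is the supernode voltage
difference per injected Amp; tests pin it to series/parallel closed forms
at 1e-8, and check Kirchhoff conservation, source/ground reciprocity and
Rayleigh monotonicity.

Link centrality is computed on the reduced PA graph (PAs as nodes, each
corridor a resistor of resistance = its LCP cost): for every unordered PA
pair, 1 A is injected and drained, and a link's centrality is its summed
absolute current over all pairs, in Amps. LCP cost is used as the link
resistance; the effective resistance of the corridor strip is a defensible
alternative but couples centrality to the truncation cutoff. A disconnected
PA graph is handled per component (with a warning) via the Laplacian
pseudoinverse.

## Change accounting and validation

Land-cover tables report percent cover per class and time step over
non-nodata cells, interval changes in percent points, and annual rates over
the full span (span change divided by last − first year label, in both %/yr
and km²/yr at the configured total area). Rates are computed from unrounded
internal fractions; rounding happens only at presentation. Classification
accuracy is a reference-by-predicted confusion matrix with overall accuracy
and Cohen's kappa ((p_o − p_e)/(1 − p_e), p_e from the marginals).
Corridor encroachment is the percent of each corridor swath classed
cropland per step, flagged when it exceeds a configurable threshold
(default: any cropland). Corridor activity summarises interview reports per
link: mean and sample (n−1) SD of sightings, the union of reported seasons,
and status "active" iff any respondent reported ≥ 1 sighting in the last
year.

## Synthetic landscape generator

The generator is the package's study-conditions module, not a test fixture.
Defaults: a 120×120 grid of 1 km cells (a desk-scale stand-in for a
~190,000 km² savanna region), 9 protected areas, 300 presence points per
time step, three time steps labelled 2000/2010/2019, and cropland cover
targets 6.71% / 8.79% / 13.14%.

Environmental fields (elevation, vegetation index, rainfall, wetness) are
Gaussian random fields built by kernel-smoothing white noise at a
configurable correlation length (default 8 cells) — the simplest fully
reproducible random-field method. Slope is the central-difference gradient
magnitude of elevation; ruggedness is slope plus 35% noise, which puts the
pair's correlation near 0.95 so the collinearity screen always has a real
casualty. Rivers are momentum random walks, roads straight transects, and
houses cluster half by desirability (flat, river-near cells) and half
uniformly — settlement is deliberately more dispersed than the cropland
that grows from it, keeping the two distance surfaces below the r = 0.7
screen in most draws. Distance surfaces are exact Euclidean
(center-to-center), not chamfer.

Cropland grows outward from house cells outside PAs through a
priority-queue flood fill ordered by desirability, stopping at each step's
target cell count (hence always within ±0.5 percentage points of the
target) and never entering PAs; masks are nested over time by construction.
Remaining cells are labelled water / burned / dense woodland / open
woodland by fixed quantile thresholds on the wetness and vegetation fields,
chosen so the step-one composition approximates a miombo-type mosaic
(roughly 22/38/25/8% with ~7% cropland).

True suitability is a logistic in the standardized covariates with a
dominant positive weight on distance to cropland (2.5, versus ≤ 1.0 for
everything else) and an intercept of −2.5. The intercept matters: it makes
highly suitable habitat the rarer condition (~21% of cells above 0.5),
which is what gives presence-versus-background discrimination headroom.
With suitability-proportional presence sampling, the achievable AUC is
bounded by how much of the background ties with presences; without the
negative intercept that ceiling sits near 0.75 no matter the model, while
with it the fitted ensembles reach weighted AUCs of ~0.81–0.88 — the
performance regime of well-fitted savanna herbivore distribution models.

Validation data: dung-transect centroids on a 5 km grid with Bernoulli
presence at the true suitability, and interview reports of 5 respondents
per corridor whose sighting counts are Poisson with mean decreasing in the
corridor's mean per-km resistance; the costliest corridor (highest CWD:EUD)
is forced to zero reports, creating exactly one known-inactive link.

What the generator does **not** emulate: observation error in presence
locations (points sit exactly on cell centers), spatial autocorrelation of
detection effort, seasonal movement dynamics, within-PA heterogeneity of
protection, and georeferencing/projection issues (grids are abstract
row/col surfaces; no CRS). Passing tests therefore demonstrate that the
analysis machinery recovers known structure under clean sampling — not that
it is robust to the messiness of real survey data.

## Reproducibility and problem sizes

All randomness flows from one master seed through named substreams (fields,
features, PAs, cropland, presences, transects, reports, splits, learners),
so reruns are byte-identical. Replicated experiments (parameter recovery
over 20 seeds) use the default landscape with the fast learner pair and 5
replications per fit; the end-to-end pipeline exercised in the tests uses
40–60 cell grids with 3–4 PAs, which preserves every structural property of
the full-size configuration at a fraction of the cost. Degenerate inputs are
handled explicitly: empty distance masks, single-class label vectors,
zero-variance covariates, unreachable PA pairs, disconnected circuit
domains and infeasible cropland targets all raise (or warn) with specific
messages rather than propagating NaNs.
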