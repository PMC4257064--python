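# Methods

This note records the models implemented in `forestrisk`, the conventions
and defaults that had to be pinned down for the results to be reproducible,
and what the synthetic-landscape tests do and do not demonstrate.

## Rasters and geometry

All layers are planar, axis-aligned grids with square cells (default 100 m,
i.e. 1-ha cells); there is no CRS handling or reprojection. Row 0 is the
top of the map; distances are measured center-to-center; a cell's area is
`cell_size²/10⁴` ha. Nodata cells never contribute to areas, distances,
samples or fits. Patches are 8-connected — the conventional raster-GIS
neighborhood — with centroids at the mean of member cell centers. I/O
supports ESRI ASCII grids and single-band GeoTIFF (pixel scale, tiepoint
and nodata carried in the standard TIFF tags); both round-trip integer and
float32 data losslessly, and categorical grids carry a `key=value` sidecar
table.

## Deforestation rates and carbon

The annualized rate is the instantaneous form `r = ln(A2/A1)/(t2−t1)`,
stored signed (negative = loss) and formatted as positive %/yr. The FAO
compound rate `q = (A2/A1)^(1/Δt) − 1` is provided for comparison; the two
agree to O(r²) and, on the areas this package is typically used with
(|r| ≈ 0.002–0.003), to about 10⁻⁶. Projection `A0·e^(r·years)` is the
exact inverse of the rate, which the tests assert to machine precision.

Carbon accounting multiplies cleared area by an above-ground carbon density
(default 113 Mg C/ha, a median humid-tropics forest value) and converts
with `co2_per_c = 44/12 ≈ 3.6667`, the molar-mass ratio. The rounded
literature factor 3.67 is selectable but not the default: published totals
computed with the exact ratio differ visibly (tens of thousands of Mg CO₂)
from ones computed with 3.67, and the exact ratio is the physically
meaningful constant. Below-ground, soil and deadwood pools are out of
scope.

## Change consensus

A cell is *deforested* only if every classifier source saw forest at the
period start and non-forest at the end; *stable forest* only if every
source saw forest at both dates; everything else — any disagreement, or
nodata (cloud) in any source — is *undetermined*. Undetermined is never
treated as absence; this asymmetry is exactly why the risk model is
presence-only. The three masks partition the study area by construction,
and adding a source can only shrink the deforested mask (asserted as a
property test). Sampling is one point per cell at cell centers, uniform
without replacement, deterministic given a seed.

## Accessibility

Friction (min/m) is `60/(1000·v_eff)` with `v_eff` the land-cover speed,
overridden on river cells and then road cells (road > river precedence),
times a multiplicative slope penalty `1/(1 + s/s0)` (s in degrees,
`s0 = 30` by default). The shipped speed table (forest 2, cleared 4, river
10, dirt road 30, paved road 60 km/h) is an editable calibration file with
plausible regional travel speeds; any real application should replace it
with locally calibrated coefficients. Travel time is the least-cost path
over 8-connected moves with edge cost = step length (×√2 on diagonals) ×
the mean of the two cells' frictions — standard cost-distance semantics,
pinned so the independent shortest-path oracle test is unambiguous.
Computed with Dijkstra on a sparse lattice graph, multi-source, with towns
as sources by default: roads and rivers influence the surface through low
friction rather than acting as sources themselves. The index is
`exp(−t/τ)`; τ defaults to the median finite travel time so mid-landscape
cells score around e⁻¹, and the index is strictly decreasing in time with
sources at 1.

## The maximum-entropy risk model

Presences and a uniform background sample are expanded into features:
continuous variables are min-max scaled to [0,1] **using background
constants only** (stored with the model), then give a linear, a quadratic,
and 8 forward-hinge features at knots k/9 (k = 1..8), each bounded in
[0,1]; categorical variables give one indicator per background category.

The fit maximizes

```
(1/n_p) Σ_presence λ·f(x) − ln Z(λ) − Σ_j β_j |λ_j| ,
Z(λ) = Σ_background exp(λ·f(x))
```

with per-class penalties β = 0.05 (linear/quadratic), 0.5 (hinge), 0.25
(categorical), scaled by 1/√n_presence. These are this package's defaults,
chosen to regularize the many hinge features more heavily; they are
config-exposed. The optimizer is bound-constrained quasi-Newton (L-BFGS-B)
on the split λ = a − b, a,b ≥ 0, which makes the L1 term linear and the
objective smooth; its line search makes the penalized objective
non-decreasing across iterates (recorded and asserted), and convergence is
declared when the objective improves by < 10⁻⁷ or after 500 iterations.
Each fit stores the maximum KKT violation `max_j |E_q[f_j] −
mean_presence[f_j]| − β_j`, which is ≤ 0 at the exact optimum; the test
suite asserts it below 10⁻⁴. On one- and two-feature problems the fitted λ
agrees with brute-force grid search of the same objective to 10⁻³.

Outputs: the *raw* scale is the relative occurrence rate `q(x)·N_bg`
(mean 1 over background); the default *logistic* scale is
`p = q·e^H/(1 + q·e^H)` with H the entropy of the fitted distribution over
the background, so a flat model yields p = 0.5 everywhere. Hard
classification thresholds on this logistic scale.

AUC is the rank (Mann–Whitney) statistic with ties counted ½, computed
from midrank sums, which equals the all-pairs definition exactly.
Replicate runs (`replicate(k)`) subsample presences 70/30 per run (seeded
from a base seed), refit on the training split against the full background,
and score test AUC with background points as pseudo-absences — subsampling
rather than bootstrap, so each run has a proper held-out AUC.

**Percent contribution** is permutation importance: per variable, its
feature columns are permuted across the pooled presence + background
points (10 seeded permutations), and the mean drop in training gain,
clipped at zero, is normalized to sum to 100. This is a deliberate,
path-independent substitute for the heuristic, training-path-dependent
contribution bookkeeping of the classic Maxent tool; the two agree on
which variables dominate but not digit-for-digit.

## Hard prediction

"Select the highest risk until the projected loss area is matched" is made
precise as: evaluate every threshold on the whole-percent ladder
{1.00, 0.99, …, 0.00} over currently forested, non-nodata cells, and keep
the ladder value whose selected area is nearest the target, ties going to
the higher threshold. This is monotone in the target and exhaustively
testable; the achieved area can differ from the target by up to one ladder
step's worth of cells, which is reported.

## Validation

Observed-deforestation points are centroids of consensus-deforested
patches ≥ 10 ha (inclusive); no-change points are uniform study-area
points filtered to consensus stable forest (so the returned count is at
most the requested 500 — the filtering, not a resampling, mirrors how such
points are generated in practice). No exclusion buffer is applied around
deforested patches; users wanting spatial separation should filter the
points themselves. The group contrast uses the two-sided Mann–Whitney U
test, U folded to `min(U, n_a·n_b − U)`: exact enumeration when
`n_a·n_b ≤ 400` with no ties, otherwise the normal approximation with tie
and continuity corrections. Histograms use 10 equal risk bins.

## Synthetic landscapes

The generator emulates the statistical structure the pipeline assumes:
piecewise-linear roads and rivers crossing the grid, towns on roads, a
smooth slope field (Gaussian-filtered noise scaled to 0–30°), a Voronoi
partition into five land-designation zones (unrestricted, agricultural and
forestry concessions, indigenous reserve, protected area), full forest at
t0, and an initial 1% band of prior deforestation in the most accessible
cells. Clearing is drawn cell-wise Bernoulli from a logistic model

```
p ∝ logit⁻¹(b0 + b_acc·accessibility − b_dist·distance_to_prior
            + designation offset + b_hot·hotspot)
```

whose intercept is calibrated by bisection so the expected cleared fraction
of standing forest matches the target annualized rate (default 0.3%/yr, a
business-as-usual frontier rate). The *hotspot* term (blobby zones, ~0.8%
of the grid per epoch, centers drawn ∝ exp(b_acc·accessibility)) encodes
that frontier clearing arrives in multi-hectare patches — farms, not
isolated pixels — while keeping the draws independent Bernoulli given the
field; without it, low annual rates would produce only salt-and-pepper
change and no ≥ 10-ha validation patches. Default coefficients (b_acc = 6
dominant; designation offsets between −2 and +0.5; b_dist = 2; b_hot = 6)
plant accessibility as the overwhelming driver, which is the condition the
recovery tests check. Classifier emulation flips cells independently per
source (default 2%) and masks per-source cloud blobs trimmed to exactly
the configured fraction (default 5%).

The standard study conditions used across the tests are a 200×200 grid of
1-ha cells, a 6-year fitting epoch followed by a 3-year validation epoch
(with the prior-deforestation distance updated in between), 500 presences
and 5,000 background points. A full pipeline run at these sizes takes well
under a second, and replicate blocks use k = 8–10 runs; these sizes were
chosen as the smallest at which the patch statistics and rank tests are
stable.

What the synthetic tests show: that every stage computes what it claims
(oracle agreement), and that the pipeline as a whole recovers a planted
accessibility-driven signal — top contributor ranking, held-out AUC
> 0.85, validation p < 0.01, realized rates within binomial error of
target. What they do not show: performance under real-sensor error
structure (spatially correlated misclassification, georegistration error),
real road-network growth, or economic drivers — the generator's noise is
independent per cell and its landscape geometry is schematic.

## Known limitations

- Slope costs are isotropic; no direction-dependent (uphill/downhill)
  travel.
- The friction speed table is a placeholder calibration, not a fitted one.
- No year-by-year sequential allocation of projected loss; the hard map is
  a single-horizon selection.
- Percent contributions are permutation-based and should be read as
  rankings with rough magnitudes, not exact percentages.
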