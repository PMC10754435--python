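# Methods

## The sampling design

The package implements a two-stage cluster design on a gridded spatial
frame. The frame is a regular square lattice (default 5 km side) anchored
at the minimum corner of the study boundary's bounding box; every lattice
cell overlapping the boundary with positive area is kept, including
partial edge cells, in row-major order. Household points are assigned to
cells by half-open membership `x ∈ [x0, x1), y ∈ [y0, y1)`, which makes
edge assignment unambiguous and the whole frame a partition. Only points
flagged inhabited count toward cell populations; uninhabited structures
are retained for bookkeeping but can never be sampled. Each cell's
population is `household_count × mean_household_size`; the mean size
(default 8) stands in for a roster of actual household sizes, which a
satellite-derived frame does not have.

First stage: systematic PPS. `SI = floor(T/n)` guarantees the series
`RS + j·SI, j = 0…n−1` stays inside the cumulative total for any
`RS ≤ SI`; the floor convention and the 36-term series (not 37 — the
(n+1)-th term can exceed the total) are deliberate. The cumulative walk
runs in the frame's row-major order, so selections are implicitly
spatially stratified, as in any systematic design on a geographically
sorted list. A cell whose interval contains m series values is selected
with multiplicity m and contributes `m·k` households.

Second stage: simple random sampling without replacement of `k`
households (default 25) among the cell's inhabited households. If a cell
holds fewer than `m·k`, all are taken and every row is flagged
(shortfall); nothing is silently under-reported. Inclusion probability
`π = min(1, n·pop_g/T) × (k_drawn/N_g)`; with a constant mean household
size and no shortfalls all weights are equal (self-weighting), which the
test suite asserts to 1e-9 relative tolerance.

The random-number contract is distributional, not bit-stream: any seeded
high-quality generator satisfies it, and the implementation uses NumPy's
default PCG64 generator (the classic tool chain used Mersenne Twister;
both are fine for this purpose).

## Mobility field rules

Movement statuses partition every sampled household: IN_PLACE (within a
25 m GPS tolerance — consumer receivers make exact-zero impossible),
RELOCATED (≤ 5 km), a configurable band rule for (5, 10] km (default:
replace — conservative, treating mid-range movers as lost to the grid),
REPLACED (> 10 km) and UNTRACEABLE (no observation). Grid outcomes use
the precedence ABANDONED (nothing found at all) > REPLACED > RELOCATED >
AS_PLANNED, so each grid gets exactly one label even though field
mixtures are the norm.

Resolution: relocated households are kept and attributed to their
*original* grid (their mapped location is taken as the true residence);
replaced/untraceable households are substituted by a seeded draw from the
same grid's unused inhabited frame; fully abandoned grids are backfilled
with their entire take from the nearest non-abandoned grid (centroid
distance, ties by cell id; configurable to nearest *selected* grid).
Replacement and oversample rows inherit the design weight of the planned
slot they fill — the substitution is treated as preserving the planned
design, the standard field convention; the alternative (recomputing
weights against the donor grid) would make oversampled rows incomparable
with the rest of the roster. Capacity failures produce explicit shortfall
reports, never truncation. Percentages in outcome tables are rounded
half-up to one decimal and always carry their denominator, because
rounded percentages without denominators are unrecoverable.

## The synthetic landscape

`gen_landscape` draws a Thomas (Poisson-cluster) process: settlement
centres ("manyattas") as a homogeneous Poisson process, homestead
offspring Poisson-distributed per centre with an isotropic Gaussian
spread (default 150 m — huts cluster within a shared thorn fence).
Household sizes are `1 + Poisson(mean − 1)` (mean 8) and an inhabited
flag is Bernoulli (default 0.9, emulating structures that look inhabited
from imagery but are not). Defaults describe a ~21,000 km² arid county:
145 × 145 km, 0.3 manyattas/km², 8 homesteads per manyatta — about
50,000 homesteads in ~900 five-km cells, so a 36-cluster design has a
~4% cluster sampling fraction. This scale matters: on a toy landscape
with few cells the cluster sampling fraction is large and the
with-replacement variance approximation becomes visibly conservative.

`gen_movement` has two components chosen to reproduce the qualitative
field mix reported for such surveys (roughly half of households found in
place, a fifth moved within 5 km, a third lost): independent moves with
probability 0.2 and lognormal distance (median 2 km, σ = 1, so ~80% of
movers stay within 5 km), and wholesale manyatta abandonment with
probability 0.15 and a large shared rigid displacement (median 20 km).
Abandoned-manyatta households are modelled as untraceable to the field
team (no observed position) while their true positions remain available
to the experimenter — that is what produces fully abandoned grids.
Displacement distributions are illustrative: no quantitative movement
distribution exists to calibrate against, so they are user-facing
parameters, not claims.

`gen_outcomes` draws per-person snakebite indicators from
`logit(p) = logit(baseline) + β·z`, where z is the standardised count of
inhabited households within 2 km and β defaults to −0.8: risk falls with
local human density, the simplest model consistent with the inverse
density–risk relationship reported for snakebite. Baseline prevalence
defaults to 0.04; with the convex logistic link and the skewed density
distribution the realised population prevalence comes out near 5%.

What the simulator does **not** emulate: seasonal/livestock-driven
movement dynamics, in-migration from outside the frame, imagery
misclassification beyond a constant inhabited probability, household
splitting, or snake-ecology covariates. Passing tests therefore show the
design machinery is correct under a plausible clustered, mobile
landscape — not that any particular real population behaves like the
defaults.

## Estimation

Hájek ratio estimator over persons with household weights; variance by
Taylor linearisation with the with-replacement PSU approximation
(`v = n/(n−1) · Σ(u_g − ū)² / X²`, u the linearised weighted cluster
totals), which is the standard choice for designs with modest cluster
sampling fractions and is conservative. Design effect is that variance
over `p̂(1−p̂)/n_persons`. Designs with a single cluster, or any cluster
with one household, are flagged unstable rather than silently estimated.
Degenerate all-zero outcomes return se = 0 and deff = 1.

Calibration (run by the test suite and the acceptance script): over 500
simulated 36 × 25 surveys on a fixed county-scale landscape, the mean
estimate sits within 3 Monte-Carlo SEs of the enumerated truth and 95% CI
coverage is close to nominal. Coverage is *conditional* on the landscape
and outcome realisation and varies by a few percentage points across
realisations (the Hájek estimator's small conditional bias and the
systematic design's implicit stratification both play in); observed
values across realisations ranged roughly 91–97%.

Sample-size helpers implement the two desk methods: the conventional
closed form `n = ceil(deff·z²p(1−p)/d² / response_rate)` and the
fixed-fraction rule `ceil(frame × fraction)`; `fieldwork_days` divides
the sample across collectors at a fixed daily visit rate (default 5
households/collector/day).

## Frame-bias experiment

On one fixed landscape and outcome realisation, each replicate draws a
fresh movement realisation and a fresh systematic start, then fields the
same 36 × 25 design two ways: (a) the current (satellite-style) frame
with the full field rules, and (b) a stale census-style frame in which
moved households are unfound non-response, never replaced — the minimal
model of a frame that has gone stale. Reported per design: bias, RMSE
and 95% CI coverage against the enumerated truth. The stale design loses
about a third of its sample, drops whole clusters, and ends with a
larger RMSE and no better coverage; with movement off the two designs
coincide. The default experiment landscape is a denser 50 × 50 km
configuration so that every grid can supply replacements and backfill —
the point of the experiment is the frames, not shortfall handling.

## Numerical and degenerate-input choices

- Tie-breaks: half-open cell membership; donor-grid ties by cell id;
  series value exactly on a cumulative boundary belongs to the lower
  cell (interval `(lo, hi]`).
- Cells with zero population can never be selected (their interval is
  empty).
- `estimate_population` rejects non-positive mean sizes; `tessellate`
  rejects empty/degenerate boundaries by name; duplicate point ids and
  non-finite coordinates are rejected with the offending ids listed.
- The landscape generator refuses configurations with more than 10⁶
  expected points.
- Problem sizes in the test suite (500 estimator replicates, 300
  experiment replicates, 200 movement realisations, 1,000 random frames
  for the PPS oracle) were chosen to keep the full suite at a few
  minutes on one CPU while leaving Monte-Carlo error well below the
  tolerances asserted.

## Known limitations

- All geometry is planar; geographic coordinates must be projected
  upstream (the CLI does not reproject).
- Weights for oversampled rows are a convention, not a derivation; any
  reuse for formal inference on abandoned-grid subpopulations should
  revisit it.
- The stale-frame comparator models staleness only as out-movement
  non-response; it does not model in-migration, frame under-coverage, or
  census age structure.
- `est_population` uses a constant mean household size even when true
  sizes are present on the points; that mirrors how such frames are
  built in practice and keeps the design self-weighting.
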