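# Methods

## The audit in one paragraph

A *survey* is the multiset of occurrence records falling in one grid cell
during one time period. The audit asks two questions of a compiled
occurrence database: per cell, *is the species inventory complete enough to
trust?* (completeness metrics and tier classification), and across cells,
*do the surveyed places represent the landscape?* (coverage indices against
the background distribution of every audit gradient). Both stages run
identically on real delimited-text records and on synthetic records with
known ground truth.

## Gridding conventions

Cells are `cell_size`° squares (default 0.1°, roughly 80–112 km² across
mid-latitudes) anchored so edges fall on multiples of the cell size from
the grid origin (default −180, −90). Cells are half-open,
`[edge, edge + size)` in both axes: a record on a shared edge belongs to
exactly one cell, the one on its greater side. Because 0.1 is not exactly
representable in binary floating point, a coordinate within 10⁻⁹ cell
widths of an edge is snapped to that edge before flooring; without this,
records written with rounded coordinates would scatter across neighbouring
cells irreproducibly. Cell ids are row-major integers `iy * n_lon + ix`
local to the grid extent. The study region is an explicit cell-id mask
supplied by the caller; background counts are whatever the mask contains.

Metric cell geometry uses the spherical approximation with
R = 6371.0088 km: height = Δlat·(π/180)·R, width = Δlon·(π/180)·R·cos(lat).
For 0.1° cells this gives ~112 km² at 25°N and ~80 km² at 49.4°N, the
latitude extremes of a contiguous-US-style study region.

## Screening rules

Four rules applied in a fixed order (coordinate issue → year window →
species rank → record type), each charged with the records it removes so
the filter report is reproducible even when a record violates several
rules. Year bounds are inclusive (1800 and 2013 both retained). Record
parse failures (unparseable or out-of-range coordinates and years) are
flagged at read time but only removed by the filter, under the
coordinate-issue rule, so retained + removed always equals the input
count. The record-type allow-list (default `{"specimen"}`) is compared
case-insensitively; the systematic-survey preset disables the record-type
and coordinate-issue rules because standardized monitoring schemes lack
those fields.

## Completeness metrics

**Sampling unit.** Chao2 is an incidence estimator and needs a sampling
unit. Within a cell the only unit the record data model provides is the
record itself, so each record is one unit: *m = n* and Q_k is the number
of species with exactly k records. (This makes Chao2 on incidence
frequencies formally identical to Chao1 on the abundance counts up to the
small-sample factor; the test suite exploits that identity as an
independent cross-check against scikit-bio's published estimator.)

**Chao2.** The bias-corrected form
`S_obs + ((m−1)/m)·Q₁(Q₁−1)/(2(Q₂+1))` is the default because it is finite
for every inventory, including Q₂ = 0 where the classic `Q₁²/(2Q₂)` form
blows up; the classic form is available behind a flag for comparison only.
Completeness is C = S_obs/Ŝ ∈ (0, 1].

**Final accumulation slope.** The expected richness after m of n records
under equiprobable orderings is the exact rarefaction form
`E[S(m)] = S_obs − Σᵢ C(n−nᵢ, m)/C(n, m)`; binomial coefficients are
computed in log space (gammaln) so surveys with thousands of records do
not overflow. The final slope is computed analytically as
`E[S(n)] − E[S(n−1)] = Q₁/n` rather than by fitting the curve's last
segment — identical in expectation, deterministic, and O(1). The
exhaustive permutation mean is kept as a test oracle only. For n = 1 the
slope is 1 by construction (the single record was new).

**Tiers.** A survey is well-surveyed at a tier iff all three criteria hold
(conjunction), with inclusive comparisons: low ≥10 records, C ≥ 0.6,
slope ≤ 0.15; moderate ≥25, ≥0.7, ≤0.10; high ≥50, ≥0.8, ≤0.05.
`ThresholdSet` enforces monotonicity across tiers, which makes the nesting
high ⇒ moderate ⇒ low a structural invariant rather than a convention.
All three tiers are always reported; consumers choose.

## Coverage indices

Coverage is descriptive, not inferential: the two-sample Kolmogorov–
Smirnov D (sup of the absolute ECDF difference, evaluated at pooled data
points with right-continuous steps) indexes how far the surveyed-cell
distribution sits from the background along each gradient. No p-values
are computed or wanted — with tens of thousands of background cells any
visible difference is "significant"; the index is the effect size.
Surveyed cells enter the ECDF once each, unweighted by record count, and
the background *includes* the surveyed cells, since the comparison is
against all cells in the study region.

The eleven gradients: latitude and longitude (spatial); elevation, MAT,
MAP (natural environmental); urban, agricultural and total disturbed
percent cover (anthropogenic; urban = land-cover classes 21+22+23+24,
agriculture = 81+82, disturbed = their sum); forecast ΔMAT and ΔMAP
(climate change); and the temporal gradient. Spatial and environmental
indices are computed on the contemporary period (1990–2013) because a
single land-cover snapshot does not represent historical landscapes. The
temporal index compares survey counts per interval against a discrete
uniform null with weight 1/11 per interval *including* the truncated
14-year final bin — the null is "equal sampling among intervals", not
"equal sampling per year"; a duration-proportional null is available
behind a flag.

The well-surveyed cell class defaults to the moderate tier. For spatial
and environmental gradients the flag is taken from the contemporary-period
inventory; for the temporal gradient each (cell, interval) survey counts
in the well-surveyed ECDF iff that interval's own inventory passes — the
natural reading when the unit being counted is the interval survey itself.
A class with no cells yields D = n/a (never an error), is excluded from
all means, and the exclusion is counted in the summary output and logged.

Summaries: per dataset × class, cumulative D (exact sum over all 11
gradients, plus the spatial+environmental-only sum as its own column) and
mean D per gradient group (all 11 / spatial 2 / environmental 5: MAT, MAP,
urban, agriculture, disturbed / climate-change 2 — elevation and temporal
deliberately belong to no subgroup); per gradient, mean D over caller-
defined dataset groups; and pooled grand means reported both per class
and over all classes, since the two bookkeepings answer different
questions. Paired relative-frequency histograms (surveyed vs background,
equal-width bins) show *where* along a gradient coverage fails, which the
scalar D cannot.

## The synthetic generator

The generator is a virtual-ecologist model: truth is fixed, then an
imperfect observer samples it.

**Landscape.** Gradient fields are smooth Gaussian-filtered noise plus
deterministic trends on a regular grid. MAT = base + lapse·(latitude row)
+ (−0.0065 °C/m)·elevation + smooth noise; with noise and the elevation
coupling at zero MAT is exactly linear in latitude, which anchors a
closed-form generator test. Defaults (base 24 °C, lapse −0.07 °C per 0.1°
latitude, MAP 900 mm/yr with a 3 mm/cell longitudinal trend, elevation up
to 3000 m, warming 2.5 °C strengthening poleward) sketch a plausible
mid-latitude region; they are conventions, not estimates. Land-cover
fractions are valid compositions per cell with urban and agricultural
cover in spatially clustered hotspots (logistic transforms of smooth
fields), split over classes 21–24 and 81–82 in fixed ratios.

**Species pool.** Relative abundances from a selectable species-abundance
distribution: log-series (rank form θᵏ/k, default θ = 0.9 — the
long-tailed, hard-completeness regime), lognormal, or uniform (the easy
regime). Niches are Gaussian on one gradient axis (default MAT) with
uniform random optima and breadths; suitability below 10⁻⁶ is truncated
to zero, which defines crisp true occupancy and hence true richness per
cell.

**Effort.** Opportunistic (GBIF-like) effort visits a fraction of cells
(default 0.25) with negative-binomial per-cell record counts
(gamma-mixed Poisson, shape 0.5 — heavily overdispersed, like real
opportunistic effort) whose mean is multiplied by exp(β·z) with z the
standardized bias gradient: β is the single knob for taxonomist/
institutional surveying bias. Record years follow categorical weights
over the eleven intervals, defaulting to a long tail rising toward the
present. Species are drawn proportional to local suitability × regional
abundance. The systematic preset instead visits few cells (4%) and draws
until 25 consecutive records add no new species — a stopping rule that
emulates near-complete standardized inventories in a narrow, contemporary
time window.

**What the generator does not emulate.** No species interactions,
dispersal limitation, range dynamics, detection differences among species
beyond abundance × suitability, taxonomic errors, or duplicated records.
Passing tests therefore show the *audit machinery* is correct and that
bias of known strength is recovered — not that any particular real
archive has a given completeness.

**Randomness.** Every stream derives from one integer seed through named
CRC-keyed `SeedSequence` substreams (landscape fields, pool, records), so
components regenerate independently and identical inputs give
byte-identical outputs.

## Test and validation regimes

Two deliberate regimes span the difficulty range. The *samplable* regime
(uniform abundances, niche breadths 8–12 °C over a ~20 °C MAT span) is
used for parameter-recovery checks: there every true occupant has
non-negligible detection probability, so saturating effort (500 records
per cell on ≤50-species pools) must push ≥95% of cells past the high tier
and scant effort (5 records) must leave ≤20% past even the low tier. The
*hard* regime (log-series, narrow niches) leaves species near the
suitability floor effectively unobservable; completeness then saturates
below 1 at finite effort — the audit's core message about opportunistic
data, not an estimator defect — and is tested directionally
(systematic preset beats opportunistic at equal record count; mean D on a
biased gradient rises strictly with β over {0, 1, 2, 3}).

Problem sizes used in the validation suites — a 200-cell landscape for
completeness recovery, a 2,000-cell landscape × 20 replicates per β for
bias recovery, 100–1,000 random inventories/sample pairs for the
estimator and K–S oracles — are the smallest at which the checked
contrasts are decisive, keeping the whole suite to a few minutes.

## Numerical and degenerate-case choices

- Rarefaction in log space; `C(a, b) = 0` when `a < b`.
- Edge snapping tolerance 10⁻⁹ cell widths (see gridding).
- An inventory must contain ≥1 record; empty inputs raise rather than
  return sentinel values. Empty *classes* (no well-surveyed cells) are
  data, reported n/a.
- K–S D is computed by scipy's two-sample routine (statistic only);
  an independent brute-force sup over pooled step points serves as the
  test oracle, including heavily tied samples.
- The pipeline's data outputs are byte-deterministic given the config;
  per-stage timings go only to the run log, which is excluded from
  determinism comparisons. Audit stages are recomputed each run rather
  than cached on checksums; at supported problem sizes a cache would add
  invalidation risk for no measurable benefit. The manifest still records
  input checksums for provenance.

## Known limitations

- No taxonomic name resolution; names are opaque labels, so synonymy
  inflates richness on real data.
- Point-in-rectangle assignment only; no polygon spatial joins or
  reprojection (WGS84 decimal degrees assumed).
- Chao2 is a lower-bound estimator; C near 1 means "consistent with
  complete", not "complete".
- The uniform temporal null treats the truncated final interval as a full
  unit; with strongly recent-skewed data the duration-weighted variant
  can differ noticeably.
- Gridded gradient inputs must align to integer multiples of the cell
  grid; arbitrary raster reprojection is out of scope.
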