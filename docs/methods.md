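# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real data.

## Geographic data model

Units live at six levels. `L1Admin` is a city operationalized as the
cluster of sub-city administrative units (`L2`) that cover any part of its
urban extent; `L1Metro` is the country's own metropolitan-area definition,
consumed as configuration (a mapping from metro id to component units) and
never computed; `L1UrbExt` is the satellite-derived built-up extent; and
`L1Excess` its variant keeping area that spills across a national border.
`L3` neighborhood proxies nest uniquely in `L2`s, and `L2`s in at most one
`L1Admin`. The hierarchy validator rejects duplicate parents and level
mismatches but *reports* orphan units rather than dropping them: real unit
files legitimately contain non-city areas, and silently discarding them
would hide data problems.

Open design points and the choices made:

- **Assignment ties.** When an `L2` shares exactly equal built-up area
  with two candidate cities, assignment falls to the lexicographically
  smallest city id, with a logged warning. Any deterministic rule would
  do; this one is reproducible across runs and platforms.
- **Areal weights.** Attribution of `L3` data to an urban extent uses pure
  area share (intersection area / unit area). A population-weighted
  variant would be better where population is strongly clustered within
  `L3`s, but requires gridded population inputs; it is deliberately out of
  scope.
- **CRS handling.** All metric computation assumes a projected CRS in
  meters, declared as a plain string on each unit; operations across
  objects require the strings to match and fail loudly otherwise. The
  package performs no reprojection — inputs must be projected upstream.
  This keeps the geometry stack to a single dependency (shapely) and makes
  the CRS contract explicit rather than implicit.
- **Spatio-temporal keys** are `unit_id@year`, which round-trip by
  splitting on the last `@`; unit ids containing `@` are rejected at key
  construction.

## City-list reconciliation

Two lists describe overlapping universes: an extent-based list (whole
agglomerations, approximate populations) and a census-based list
(administrative cities, authoritative populations). Matching proceeds in
two deterministic passes: exact on (normalized name, normalized
subdivision, country), then name+country where the candidate is unique.
Name normalization casefolds, strips diacritics and bracketed qualifiers,
removes punctuation, and collapses whitespace; it is idempotent, which the
property tests exercise on arbitrary strings.

Unmatched census cities whose recorded location intersects an extent
footprint are *absorbed* — they are part of the larger agglomeration and
contribute provenance, not a new city. The boundary counts as inside
(closed-set rule): a point exactly on a footprint edge is absorbed, which
matches the absorb-into-agglomeration intent and avoids knife-edge
behavior under coordinate rounding. Records without a location go to a
review queue, never silently dropped. Fuzzy (edit-distance) matching is
intentionally **not** applied automatically: near-misses belong in the
review file for a human decision, since wrong automatic merges are far
more damaging than a short review list.

Consolidation keeps the census population where both sources report one
(census projections are the population of record) and applies the
threshold inclusively (population ≥ 100,000 enters). Contiguous cities —
pairs sharing built-up area — merge as connected components under a
deterministic union-find; merged ids are the smallest member id plus a
`+merged` suffix, and previously sub-threshold towns enter when their
combined population clears the cutoff.

## Mortality harmonization

Age keeps single years where available and derives 5-year bands
`0-4 … 80-84, 85+`. The open top band at 85 is a convention choice (common
in vital statistics; the band set must simply match the population tables
and the standard). Sex and education recode through per-country codebooks;
unmapped codes become `missing` and are tallied, never guessed. Causes map
through a longest-prefix table over dot-stripped ICD codes (`Y87.2` ≡
`Y872`), so a map can hold both a chapter-level prefix and more specific
overrides. The repository ships a reduced ~12-group demonstration map —
the full harmonized cause taxonomy is an external configuration artifact
that analyses supply themselves.

Ill-defined causes: ICD-10 R00–R99 (ill-defined disease) and Y10–Y34 plus
Y87.2 (injury of undetermined intent). For ICD-9 the defaults are 780–799
and E980–E989, overridable in configuration since the published rule names
only ICD-10 codes.

Harmonization is record-count preserving, deterministic, and idempotent on
its own output; the data-quality report (missingness and ill-defined
shares by country-year) is recomputed from the harmonized table, so it can
never drift from the data.

## Mortality correction

The pipeline order is fixed as: drop records with missing sub-city
location → impute missing demographics/cause → undercount-correct →
aggregate → redistribute ill-defined causes. The order of the middle steps
is a genuine design choice (the quality problems are separable); imputing
before hot-deck sampling means replicates are drawn from completed
records, and redistributing after aggregation keeps redistribution exact
and fractional.

**Imputation.** Missing age bands draw from P(age5 | sex, cause group),
missing sex from P(sex | age5, cause group), both within country-year; a
missing cause is assigned to one of the two ill-defined classes with
probabilities from observed ill-defined deaths of the same age and sex
(it is then redistributed with the rest of the ill-defined mass, so no
informative cause is ever invented). Sparse donor strata back off along a
fixed margin-dropping order — drop year, then the second conditioning
variable, then to the country marginal — each backoff logged; exhausting
the backoff is an error naming the country-year. Imputed fields carry
provenance flags and non-missing fields are never altered.

**Redistribution.** Within each (country, year, age band, sex) stratum,
ill-defined counts are allocated to well-defined cause groups
proportionally to those groups' observed counts. The allocation keeps the
ill-defined row's other keys (sub-city, education) fixed — only the cause
moves, never the death's location or demographics. Strata with ill-defined
but no well-defined deaths borrow the cause *mix* from coarser strata
(drop sex → drop age → country-year → country); mass that cannot be placed
anywhere lands in an explicit `_unredistributable` bucket rather than
vanishing. Allocation is fractional by default, conserving stratum totals
to machine precision; a record-level integer variant (probabilistic
reassignment per record) exists for workflows needing integer microdata
and conserves totals in expectation.

**Undercount.** Completeness factors c ∈ (0,1] carry a scope (country or
specific sub-city, optionally sex- or age-specific); each record resolves
to the most specific matching factor, with equal-specificity overlaps
rejected as configuration errors. Per correction cell the expected missing
count is M* = D·(1−c)/c; the realized integer is floor(M*) plus a
Bernoulli draw on the fraction (stochastic rounding), so the correction is
unbiased across many small cells, unlike deterministic rounding which
systematically truncates. M records are sampled uniformly with replacement
(hot deck) and appended as flagged clones; aggregation reports observed
(replicates excluded) and corrected (included) counts, each with and
without redistribution — four count columns.

All randomness flows from one seed through named substreams
(SeedSequence keyed by stage name), so adding a stage never perturbs
another stage's draws and every run is exactly reproducible.

## Population denominators and rates

Where a sub-city publishes only a one-dimensional population margin (by
age *or* sex) but the joint age×sex table exists at a higher level, the
missing dimension is filled by the higher level's conditional
distribution: count(g,a,s) = margin(g,s)·P(a|s). This single-step
conditional allocation reproduces the input margin exactly and conserves
totals. Iterative proportional fitting is available behind a flag for the
case where both margins exist at the sub-city but no joint — but the
single-step rule is the default because it is the direct formalization of
"redistribute to the proportions observed at higher levels".

Rates: crude = ΣD/ΣP·scale; age-standardized = Σₐ wₐ(Dₐ/Pₐ)·scale with a
standard population's band weights. The shipped demo standard is a
young-leaning pyramid for examples and tests; no specific international
standard is hard-coded, because the choice of standard is an analysis
decision. Deaths in a zero-population band are a hard error (denominator
violation), never an infinity or silent skip.

## Urban-extent delineation

Pixels of a binary built-up raster are classified by the share of built
pixels within a surrounding 1-km² window. Defaults: urban ≥ 0.50, suburban
≥ 0.25, following Atlas-of-Urban-Expansion-style conventions; both fully
configurable. The window is circular by default (square available), is
realized as a precomputed boolean offset mask on the grid, and truncates
at raster edges with normalization by the in-bounds cell count, so edge
shares remain genuine fractions. Implementation detail: the two
convolutions (built count, in-bounds count) run via FFT and are rounded
back to integers — both count whole cells — so threshold comparisons are
exact and the classification matches a brute-force per-cell recount bit
for bit.

"Urbanized open space" is not formally defined in the delineation
tradition; here it is operationalized as non-built cells whose window
built-share reaches the suburban threshold, plus holes fully enclosed by
urban/suburban cells. Clusters are connected components (8-connectivity
default) over urban ∪ suburban ∪ urbanized-open, with deterministic ids
(descending area, then scanline position). Agglomeration merges clusters
whose minimum edge-to-edge distance is within a join threshold (default
500 m — the published "inclusion rule" is unspecified, so this is a
prominent configuration knob), taking the transitive closure so the result
is independent of merge order; a zero threshold is the identity. The
extent of an administrative city is the largest intersecting cluster.

Spillover classification, checked in priority order: excess crossing the
national border → keep both a clipped extent and a separate cross-border
"excess" extent; excess reaching a neighboring administrative city →
flagged for case-by-case review, no modification; excess under 20% of the
administrative area → clipped and ignored; larger within-country excess →
flag the sub-city units under it for addition to the city.

## Landscape metrics

Patch-based metrics use FRAGSTATS-style definitions. Effective mesh size
Σaᵢ²/A is the expected area of the patch containing a random point; it is
bounded by the largest patch area, with equality only for a single patch.
The raster shape index uses 0.25·p/√a so a square scores exactly 1 (the
FRAGSTATS minimum-perimeter normalization is available behind a flag).
Perimeters count exterior *and* interior (hole) edges, in meters via the
cell size. The aggregation index is 100·g/g_max with g the like-adjacency
count and g_max from the largest-integer-square construction; a single
cell is trivially fully aggregated (100), zero cells is missing.
Area-weighted nearest-neighbor distance is undefined (missing, not 0) with
fewer than two patches. The Gini coefficient is computed by the sorted
(Lorenz) form, exactly equivalent to the pairwise definition
Σᵢⱼ|xᵢ−xⱼ|/(2n²μ), and is unweighted across units by default (a
density-based variant is a flag); all-zero input is missing.

## Synthetic data and what the tests show

The generator plants: a rectangular nested geography; a built-up raster
with solid blocks whose sizes exceed the 1-km² window and whose gaps
exceed its smearing scale, so the planted cluster count is recoverable; a
mortality stream drawn per (sub-city, age band, sex) stratum as
Poisson(population × rate) from a realistic age-rate schedule (child
mortality, injury hump, Gompertz-like old-age rates, crude rate ≈ 7–8 per
1,000) with sub-city multipliers spread ±20%; and a two-list city scenario
with planted matches, absorbed satellites, standalone cities, a record
pinned at exactly the population threshold, and a sub-threshold contiguous
pair. Defects are applied in order — garbage coding (age/sex preserved),
missingness (MCAR by default; an age-dependent mode exists to stress
conditional imputation), undercount thinning — with defaults 5% missing
age, 5% missing sex, 10% garbage, completeness 0.85 on a 500,000-person,
10-sub-city country. These sizes keep the full suite and the acceptance
script at desk scale (the whole pipeline runs in seconds per seed).

What passing tests show: the pipeline recovers planted stratum rates to a
median relative error of a few percent under those defect rates; the
correction steps conserve what they must conserve; the raster pipeline
equals brute-force oracles exactly. What they do not show: performance on
real vital-registration data, where missingness is not MCAR, completeness
factors are themselves estimates, garbage coding correlates with cause
structure, city names require human review, and boundaries change over
time. The generator also makes no attempt at spatial autocorrelation of
mortality or realistic place-name typology.

## Known limitations

- No reprojection: all geometry must arrive in a shared projected CRS.
- Longitudinal boundary harmonization is out of scope; keys are
  (unit, year) and extents are expected to be re-delineated per epoch.
- Completeness estimation is an input, not a product: the package corrects
  for undercount given factors, it does not estimate them.
- The agglomerative join is O(k²) in cluster count with exact polygon
  distances — fine for per-city rasters, not tuned for continental mosaics.
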