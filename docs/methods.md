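# Methods

`c3c4niche` implements a comparative analysis of the climatic and edaphic
niches of C3, C3–C4 intermediate, and C4 plant lineages, together with a
ground-truthed synthetic-data generator used to validate every stage. This
note records the statistical model, the numerical conventions, the defaults
and why they were chosen, and the known limitations.

## The analysis chain

**Occurrence QC.** Raw aggregator records pass four filters in a fixed
order: (1) coordinate validation — non-finite, missing, out-of-range, or
exactly (0, 0) ("null island") coordinates; (2) a land-mask test on the
containing raster cell; (3) an institution-proximity filter, by default a
50 km great-circle radius around GBIF headquarters in Copenhagen
(55.6761° N, 12.5683° E), catching records geocoded to the database rather
than the collection site; (4) per-taxon deduplication after rounding
coordinates to two decimal degrees (~1 km), keeping the first record of each
rounded key. Order matters: the land and proximity tests see original
coordinates; rounding happens only at deduplication. Every dropped record
carries exactly one machine-readable reason, so the pipeline is idempotent
and the report auditable. Rounding is half-away-from-zero (computed through
`decimal`, not float arithmetic) for platform determinism.

**Environmental extraction.** Rasters are regular lat/lon grids anchored at
their north-west corner. A cell owns the half-open rectangle
[west, west + s) × (south, south + s] — one bit-exact ownership rule shared
by extraction, the land mask and the synthetic sampler. No interpolation is
performed; overlay extraction reads the containing cell, and off-extent or
nodata lookups become missing values. From monthly temperature and
precipitation stacks the package derives:

* MAT = mean of the 12 monthly means (°C);
* MAP = Σₘ xₘ (mm), with xₘ the month-m precipitation total;
* growing-season temperature = mean temperature of the wettest quarter,
  where a quarter is any 3 consecutive months with December–January
  wrap-around and ties break to the earliest calendar start;
* minimum temperature = coldest monthly value (supply monthly minima to get
  the conventional coldest-month minimum);
* minimum precipitation = driest monthly total;
* rainfall seasonality, a 0–100 concentration index

  SI = 100 · [Σₘ |xₘ − R/12| / R] / (11/6),  R = Σₘ xₘ,

  which is 0 for equal rain in all months and exactly 100 when all annual
  rain falls in one month; zero-rain cells map to 0 by convention. The
  index is an absolute-deviation statistic rescaled so those two endpoints
  hold exactly; the external seasonality product it stands in for publishes
  only the endpoints, so any index matching them is admissible here.

Frost days, wet days, sunshine, fire return interval, soils and elevation
have no in-package derivation and are accepted as direct layers only.

**Ordination.** Climate and soil variables are summarized by separate
correlation-matrix PCAs: columns are standardized to zero mean and unit
sample variance (ddof = 1), rows with any missing value among the selected
variables are excluded listwise, and eigenvector signs are fixed so each
loading vector's largest-magnitude entry is positive (removing the
arbitrary sign of eigenvectors from all downstream outputs). Per-occurrence
PC scores are appended to the environment matrix as ordinary variables, so
species medians and group means of the composite axes are computed exactly
like any direct variable. The PCA is fitted on pooled occurrences of all
photosynthetic types so the three types share one coordinate system.

**Niche aggregation.** The species-level summary is the per-variable median
over retained occurrences — robust against residual misidentifications and
bad coordinates that survive QC. The lineage-level summary is the
arithmetic mean of member-species medians ("mean of medians"), computed
separately per photosynthetic type within each comparison group.
Single-occurrence species are retained with a logged warning. The
descriptive range table reports per-lineage min–max over pooled C3–C4
members for latitude, altitude, MAT, MAP and the four soil variables.
A Whittaker-style biome label (9 classes) is available for (MAT, MAP)
points from a packaged synthetic polygon set; it is descriptive output
only and feeds no test statistic.

## Inference over sister groups

Comparison groups pair each C3–C4 lineage with its C3 sister group and,
where one exists, its C4 sister group. A lineage may lack either sister;
eligibility is decided per comparison (this is why the three comparisons can
have different lineage counts, e.g. 19 / 14 / 15).

**Phylogenetic effect (niche conservatism).** Kendall's tau-b between the
focal type's lineage values and its sister's, across lineages. Under
independence the sister values carry no information about each other; a
positive rank correlation indicates conserved niches. The p-value is exact
(enumeration over pairings) for n ≤ 9 without ties, otherwise a normal
approximation with continuity correction on the S statistic using the
standard tie-corrected variance.

**Directional shift (sign test).** For each variable, count the lineages k
(out of n non-tied) where the focal type's mean-of-medians exceeds the
reference type's. Under no association, k ~ Binomial(n, ½). The default
two-tailed convention is

    p = min(1, 2 · min(F(k), 1 − F(k))),   F = Binomial(n, ½) CDF,

which includes the observed count in the lower tail and excludes it from
the upper. This asymmetric convention is what the published shift table's
p-values follow (e.g. 12/14 → 0.0018, where the symmetric convention gives
0.0129), so it is the default; the symmetric convention
min(1, 2·min(P(X ≤ k), P(X ≥ k))) is available behind a flag. Two
consequences of the asymmetry are worth noting: at an exact half split with
even n the default convention yields 2·(1 − F(n/2)) < 1 (only the symmetric
convention yields exactly 1), and at k = n the upper tail would be empty,
so it is floored at the point mass P(X = n) to keep p > 0. All binomial
tails are computed in exact integer arithmetic (`math.comb` / `Fraction`);
no floating binomial coefficients enter at any n.

**Multiple testing.** Eight variables are tested (climate PC1, soil PC1,
growing-season temperature, minimum temperature, minimum precipitation,
rainfall seasonality, topsoil organic carbon, TEB); significance is
declared at the Bonferroni-corrected threshold α/m = 0.05/8 = 0.00625.
Because the sign test is discrete, its attainable levels sit below nominal
α — at n = 14 the actual size of the nominal-0.05 test is 0.0352 — and the
null-calibration test accounts for this by computing the envelope around
the attainable level, not the nominal one.

## The synthetic generator

No machine-readable occurrence/raster bundle accompanies the study design,
so the generator emulates the statistical structure the analysis assumes,
with full ground truth.

**World.** A regional grid (default lon −25…65°, lat −40…70°, 2° cells —
deliberately regional so the Copenhagen filter centre lies on-grid and
off-extent space exists for planting off-land errors). Monthly mean
temperature follows a latitudinal gradient (28 °C at the equator,
−0.55 °C per degree |lat|) with a seasonal amplitude growing with |lat|
(0.25 °C/deg, warm peak in July north of the equator, January south) plus a
spatially smooth noise field (sd 2 °C, Gaussian smoothing over 3 cells);
monthly minima sit a fixed 6 °C below the means. Precipitation has a wet
equatorial belt (2500 mm peak over a 150 mm base, Gaussian in latitude with
40° width) with multiplicative lognormal-style smooth noise and a monthly
concentration profile that sharpens with latitude. Soil fields are smooth
random surfaces squashed into plausible topsoil ranges (OC 0.05–40 %weight,
TEB 0.5–80 and CEC 0.5–90 cmol kg⁻¹, pH 3–10); elevation is a smooth
non-negative surface. The mask is all land unless ocean blobs are
requested.

**Lineages and conservatism.** Each lineage has a base niche b_ℓ; each
member species an optimum scattered around it; C3–C4 and C4 species
optionally receive additive shifts δ. Spreads are expressed in per-variable
baseline units so the conservatism index ρ = σ_L²/(σ_L² + σ_S²) is
variable-free; σ_L = σ_S = 1 (ρ = 0.5) by default, 19 lineages of which
5/19 lack a C4 sister, 3 species per type. Without a raster world, bases
and optima are free Gaussian draws (used for the statistical calibration
ensembles); with a world, bases are the environments of random land cells
and species optima are environments of land cells drawn with a Gaussian
kernel around the base-plus-shift target — optima therefore always lie on
the jointly realizable environmental manifold.

**Occurrences.** Species records sample land cells with probability
∝ exp(−½ Σ_v ((env_v − opt_v)/τ_v)²), uniform jitter within the cell. The
default kernel uses the single thermal axis (τ_MAT = 1 °C). This is a
deliberate design choice: with a multi-variable kernel over spatially
correlated fields, the suitability-weighted population median of available
environment values is displaced from the optimum by ~0.2–0.3 τ for an
appreciable fraction of species (availability confounding on the
realizable manifold — empirically insensitive to grid resolution,
smoothing scale and τ), so the occurrence median would not be a consistent
estimator of the optimum and "median recovery" would conflate estimator
bias with pipeline defects. The one-variable kernel keeps recovery a clean
consistency check; multi-variable kernels remain supported and tested.

Clean records are generated collision-free at the QC rounding resolution,
away from (0, 0) and outside the institution zone, so "clean" in the
ground truth means "should survive QC" exactly. Error records (duplicates
5%, off-land 2%, institution-proximity 1%, out-of-range 2% of clean
records by default) are appended after the clean block and logged
one-to-one. Randomness derives from one integer seed through
`numpy.random.SeedSequence` children spawned in the fixed order (world,
lineages, occurrences, errors).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial sampling bias (herbarium-road effects),
taxonomic misidentification, phylogenetic tree uncertainty in group
assignment, dispersal limitation and biogeographic barriers (species occupy
every climatically suitable cell), temporal climate mismatch, and niche
shapes beyond separable Gaussians.

## Problem sizes and runtime choices

The test-suite ensembles run at the sizes the checks require while staying
comfortably inside a single-CPU budget: null calibration uses 500
niche-level replicates × 8 variables at 14 lineages; shift detection 100
replicates of a 2σ_S thermal shift; conservatism 200 replicates at ρ = 0.9;
QC recovery and median recovery each run one full raster pipeline (19 or 14
lineages, 40 or 200 occurrences per species). Niche-level replication
(drawing group values directly from the lineage model) is used for the
ensembles because the sign test operates on group means regardless of how
they were estimated; the raster path is exercised end-to-end by the
recovery checks.

## Numerical conventions, collected

* Cell ownership: half-open [west, west+s) × (south, south+s], rows
  north-to-south; extraction, masks and sampling all share it.
* Coordinate rounding: half away from zero via `decimal`, 2 digits.
* Duplicate retention: first record in input order wins and keeps the
  rounded coordinates.
* Wettest-quarter tie-break: earliest calendar start month.
* PCA: listwise deletion; standardization with ddof = 1; sign convention
  as above; axes kept in full for variance accounting (shares sum to 100).
* Sign test: exact integer arithmetic at all n; k = n upper tail floored
  at P(X = n).
* Kendall p: exact for n ≤ 9 without ties, else continuity-corrected
  normal approximation with tie-corrected variance.
* Output stability: CSV floats at 12 significant digits, JSON keys sorted,
  config hash recorded in the run log; equal hashes give byte-equal
  outputs.
* CSV reads use round-trip float parsing so generated occurrence files
  survive the reader bit-exactly.

## Limitations

* The seasonality index is endpoint-matched to its external reference, not
  formula-matched; absolute values between the endpoints are specific to
  this implementation.
* The biome polygon set is a hand-digitized approximation of the classic
  diagram, packaged as `biome_polygons_synthetic.json`; labels are
  descriptive only.
* The sister-group design tests directional consistency, not effect
  magnitude; no phylogenetically explicit models (PGLS, Ornstein–Uhlenbeck)
  are provided.
* Real-data results of the original study that depend on its proprietary
  occurrence snapshot and raster products (species ranges, PCA variance
  shares, Kendall taus) are not reproducible here; the package reproduces
  the study's inferential machinery exactly and validates it on synthetic
  ground truth instead.
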