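# Methods

## Scope and data model

`mycoroot` estimates, per pixel and per spatial unit, the fine-root biomass
carbon colonized by arbuscular (AM) and ectomycorrhizal (EcM) fungi. All
spatial layers are `RasterGrid` objects: WGS84 lon/lat lattices with an
upper-left-corner geotransform, values understood as cell means referenced
to cell centers, and a declared nodata sentinel (NaN is always invalid in
float layers as well). GeoTIFF I/O writes the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory for EPSG:4326)
plus GDAL's nodata tag, so files interoperate with GDAL/QGIS. No
reprojection is performed: inputs must already share the lon/lat grid.

A *spatial unit* is one observed (ecoregion, land-cover class, continent)
triple. Pixels with nodata in any categorical layer or with an excluded
land-cover class belong to no unit. For real ESA-CCI-coded data the
recommended exclusion set is {0, 10, 20, 30, 190, 200, 201, 202, 210, 220}
(no-data, croplands including the >50 % cropland mosaic, urban, bare,
water, permanent snow/ice), which retains the 15 natural classes 40–180;
the set is always a parameter, never hard-coded. Unit ids are assigned
1..n in lexicographic order of the triple, making them stable across
re-runs. Tundra routing is by a configurable ecoregion-code list, since no
authoritative code enumeration is available.

## Stocks

Belowground biomass C layers arrive at fine resolution and are coarsened
by block means over valid cells (`aggregate_mean`); the categorical
land-cover layer is coarsened by nearest-neighbour sampling of the block
center. For even factors the center is equidistant from four cells; the
tie-break takes the smallest (row, col) in scan order, i.e. the cell at
offset `(factor−1)//2` — documented and tested.

Per growth form, the colonizable stock in a pixel is
`BGB × f_fine × (1 − β^d)` with

| parameter | default | meaning |
|---|---|---|
| `f_fine` woody | 0.141 | fine-root share of woody root biomass |
| `f_fine` herbaceous | 0.885 | fine-root share of herbaceous root biomass |
| β tree / shrub / herb | 0.970 / 0.978 / 0.952 | vertical-distribution extinction coefficients |
| β woody | (0.970+0.978)/2 = 0.974 | always the tree/shrub mean |
| `d` | 30 cm | depth horizon of colonization |

giving depth shares 0.546 (woody) and 0.771 (herbaceous). The fine-root
fractions are shipped as constants because they, not the underlying
ratios, enter the workflow; `fine_fraction_from_ratios` optionally
rederives them from a coarse/fine mass-ratio table as `1/(1 + r̄)` with
`r̄` the back-transformed mean of log ratios (the geometric mean — the log
base is immaterial and natural log is used). A single herbaceous ratio of
0.13 reproduces 0.885 under this convention, which is why it was adopted.

The AM (EcM) woody fraction is the sum of the tree and shrub fraction
layers; sums marginally above 1 (inconsistent upstream maps) are clipped
to 1 with a logged warning rather than an error. Tundra pixels skip the
woody/herbaceous paths entirely: the tundra biomass layer is multiplied by
growth-form-free AM/EcM fraction layers. No established tundra-specific
fine-root fraction or β exists; the herbaceous values are used as defaults
(tundra vegetation is predominantly herbs and small shrubs) and are
exposed as `fine_fraction_tundra` / `beta_tundra` for overriding.

Zonal statistics are arithmetic means over valid pixels; a unit with no
valid pixel is *empty* (NaN), never zero.

## Colonization intensity

Records are filtered (naturalness `non_natural` and season `non_growing`
dropped; `unknown` kept for both, since colonization is normally scored in
the growing season of natural habitats), categorical labels are converted
through a user-supplied label→percent mapping (the per-source conversion
tables are not public, so the mapping is a required input; unmapped labels
are an error naming the label), and the per-species arithmetic mean per
measurement kind becomes the trait value. AM (% root length) and EcM
(% root tips) are distinct measurement kinds and are never pooled; a
dual-colonizing species needs records of each kind to contribute to each
pool.

Species matching everywhere is case-insensitive exact matching after
whitespace normalization, with the genus as the first name token; no fuzzy
matching (silent mismatches are worse than logged drop counts). Genus-based
type assignment resolves plot abundances: dual species contribute half
their abundance to each type, facultative AM counts as AM, unassignable
species are excluded. Growth-form-unknown species are excluded from the
woody/herbaceous pools but retained in the growth-form-free tundra pool.

Among candidate plot subsets (emulating databases that ship several
balanced resamples), the one covering the most units is chosen (ties to
the first by input order, logged) and plots from other subsets are added
only for units the winner leaves empty. Plots are assigned to units by
point-in-pixel lookup; plots on nodata/excluded pixels are dropped with a
logged count. Plot intensity per pool is the abundance-weighted mean of
species trait values with weights renormalized over covered species; pools
with zero covered abundance are empty and excluded from unit averaging.
Unit intensity is the unweighted mean over plots (plot size is not used —
the averaging rule is deliberately the literal, simplest one).

## Assembly and quality

`colonized_stock = stock × intensity/100` per pool. Gap-filling operates on
per-pool colonized stocks *before* growth forms are combined, so partial
data is used maximally: an empty pool receives the mean of observed values
among units sharing ecoregion and continent; observed units are never
altered, filling never crosses group boundaries, and groups with no
observed member stay nodata. Per-type totals are woody + herbaceous
(tundra pool alone for tundra units); a pool missing while the type has
any data contributes zero, not missing. Output maps are piecewise constant
per unit, as in the published product, in two variants: observed-only
(empty units nodata) and gap-filled.

Quality indices are computed before gap-filling (borrowed values carry no
observed quality) and per mycorrhizal type, merging growth-form pools at
the plot level: mean observations per covered species (plot mean, then
unit mean), mean covered abundance (%), and plot count. `compare_rasters`
masks reference pixels whose standard error exceeds a threshold (default
20 percentage points) and returns the difference map plus a histogram
(default 10-point bins over [−100, 100] — a presentation choice).

## The synthetic world

The generator emulates every input source: banded ecoregions (the first
band tundra by default) × column-banded continents × randomly scattered
land covers (plus excluded classes and water pixels that carry the nodata
sentinel in all value layers), block-constant fine-resolution biomass
layers, per-pixel AM/EcM fractions drawn so that AM + EcM ≤ 1 within every
growth form, colonization records, three overlapping plot subsets, trait
tables and a log-symmetric coarse/fine ratio table whose back-transformed
log means equal the shipped constants exactly.

The recovery guarantee is structural: the species pool is partitioned
among units and every species in a unit pool carries that unit's true
intensity as its species mean, so community-weighted means equal the truth
for any plot composition — species turnover, not abundance structure,
carries the spatial signal, as in the real workflow. Perturbations around
this exact backbone are individually switchable: Gaussian record noise
(default 5 pp s.d., truth drawn in [20, 80] so clipping at [0, 100] is
negligible), extra off-season/non-natural records biased +25 pp (so a
missing filter is detectable), categorical conversion, species without
records (default 10 %), plots on water pixels, and units visible in only
one subset (exercising supplementation). Plot coordinates are drawn
uniformly inside a pixel of the unit footprint, so each plot maps to
exactly one unit. What the generator does *not* emulate: realistic spatial
covariance of land cover or biomass, plot-size variation, phylogenetic
structure in traits, and intraspecific intensity gradients — passing tests
therefore demonstrate correctness of the aggregation machinery, not
robustness to those real-data features.

Ground truth stores the configured intensities and brute-force per-unit
zonal means of the per-pixel stock products. Stock truths match the
pipeline only up to floating-point summation order (tests use 1e-12
relative; the recovery experiment's tolerance is 1e-9).

## The recovery experiment

`recovery_config` fixes the study conditions: a 100×100 coarse grid with 5
ecoregion bands × 4 retained land covers × 1 continent = 20 observed units
and 1200 species (~15 per unit pool). The noiseless variant (30
plots/unit, exact records, full coverage) must recover unit intensities
and colonized stocks to 1e-9 relative. The noisy variant uses 10 pp record
noise with 100 plots/unit and 25 observations/species; the observation
count was sized by a power argument — the species-mean standard error is
10/√25 = 2 pp, and averaging over ~15 pool species leaves a unit-level
error around 0.5 pp, so at least 95 % of unit pools fall within 2 pp of
truth with large margin. The generator's plain default stays at 3
observations/species, the realistic order of magnitude for compiled
colonization databases.

Problem sizes throughout (grids of 24–100 cells a side, hundreds to ~2000
plots) are chosen so the whole suite and the acceptance script run in
seconds while every code path — tundra routing, gap-filling, subset
supplementation, categorical conversion, nodata handling — is exercised.

## Known limitations

Intensity is assumed equal to the colonized share of root *biomass*
(% root length for AM, % root tips for EcM), inherited from the source
method; AM and EcM estimates are therefore not strictly comparable with
each other. No uncertainty is propagated from the source biomass or
fraction maps, and colonized-root carbon is not converted to fungal
biomass (the published conversion equations require root-length
colonization and do not apply). Validation by raster comparison is done at
pixel level; whether the original comparison was pixel- or unit-level is
not stated.
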