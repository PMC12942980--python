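# Methods

`tickclim` analyses how climate structures the global distribution of
ticks (Ixodidae) parasitizing humans and livestock, and how that
structure shifts under warming.  The pipeline runs end to end on a
synthetic study system with known ground truth; this note records the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Climate representation: Holdridge life zones

Climate enters the analysis as the Holdridge triple:

* **biotemperature** `BT = mean_m max(0, min(30, T_m))` over the twelve
  monthly mean temperatures `T_m` (°C) — an annual mean clamped to the
  0–30 °C range within which plant metabolism operates;
* **annual precipitation** `P` (mm);
* **PET ratio** `= 58.93 · BT / P`, annual potential evapotranspiration
  over precipitation, using the standard Holdridge constant of
  58.93 mm yr⁻¹ °C⁻¹.

Life zones are the cells of the classical triangular chart: log2 bands
of `BT` (boundaries 1.5, 3, 6, 12, 24 °C) crossed with log2 bands of `P`
(boundaries 62.5·2ᵏ mm).  Because the PET ratio is a deterministic
function of the other two axes, classification keys on (`BT`, `P`) only;
the PET band is implied.  A frost-line sub-split of the 12–24 °C band at
12·√2 ≈ 16.97 °C (the band's log2 midpoint, standing in for the critical
temperature line) separates warm temperate from subtropical zones and
brings the enumeration to the classical 38 classes.  All intervals are
half-open `[low, high)`.  The id → name table ships as an editable CSV
(`src/tickclim/data/hlz_zones.csv`, ids 1–38 in belt-major, dry-to-wet
order) so the numbering can be re-aligned to any external zone raster;
the classifier itself hard-codes no ids.  Published zone rasters use
their own numbering — before comparing against one, recalibrate the
table to it.

## Record cleaning

The QC chain mirrors practice for large georeferenced compilations, in
this order: coordinate precision (≥ 3 decimal places *as written*, hence
the text columns — a float cannot distinguish "12.340" from "12.34"),
offshore removal (point-in-polygon against land, boundary points kept),
optional country-checklist consistency (species absent from the
checklist are kept and flagged, since their range is merely unknown),
deduplication on the (species, lon, lat) key with coordinates rounded at
3 decimals (harmonization noise in later digits should not defeat the
key), and finally the ≥ 200-records-per-species rule.  The record-local
filters commute; the minimum-record rule is order-dependent by design
and always runs last.  Inside the indicator-species test the record
threshold is strict (> 200), matching how such thresholds are usually
stated for the test as opposed to the compilation.

## Genus niches, indicator species, MANOVA

Sites for the indicator analysis are the hexagonal grid cells (see
below), each labeled with its dominant (modal) life zone; tiny coastal
fragments that contain no raster-cell center fall back to the modal zone
of their own records.  For species *i* and zone *j*:

* specificity `A_ij` = share of the species' records collected in *j*;
* fidelity `B_ij` = share of *j*'s sites occupied by the species;
* `IndVal_ij = A_ij · B_ij · 100`, reported alongside
  `stat = sqrt(A·B)` on the conventional [0, 1] square-root scale.

Each species is assigned its best zone (maximal stat, ties to the lower
zone id), and significance comes from permuting the site → zone labeling
(999 permutations by default): `p = (r+1)/(n+1)` with `r` the count of
permutations whose best-zone stat reaches the observed one.  On tiny
matrices the test can enumerate every ordering of the label vector
(`n_perm="exact"`), which the tests compare against an independent
rational-arithmetic enumeration.

Genus separation in the climate triple is tested with a one-way MANOVA.
Pillai's trace is computed directly as `V = tr(H (H+E)⁻¹)` from the
between- and within-group cross-product matrices, with the standard F
approximation.  The direct form is used because generic eigenvalue
routes degenerate at the exact null (H = 0), which the tests exercise; a
pre-check names any collinear response before the solve.  The three
responses are functionally dependent (PET ratio derives from the other
two) but not linearly so, which keeps the within-group problem
non-singular on real-valued data.

## Suitability and the hybrid zone-mean transfer

The projection method assumes genera track their climatic niches as
zones move, and needs only (a) a baseline suitability surface per genus
and (b) the zone geometry of each time slice:

1. **Baseline** `p_i(x)`: a product-Gaussian kernel density over the
   standardized climate triples of genus *i*'s records, evaluated at
   every land cell's triple and divided by its maximum (the modal
   climate maps to 1).  Per-axis Scott bandwidths (`σ_j · n^(-1/7)`) on
   a diagonal kernel: the axes' functional dependence makes a
   full-covariance density ill-conditioned.  This construction is a
   stand-in — the transfer accepts any [0, 1] surface registered to the
   zone raster — and outputs that depend on it should be read as
   relative, not calibrated, probabilities.
2. **Genus–zone matrix** `m[i, z]` = mean of `p_i` over the baseline
   cells of zone *z* (support counts kept; zones with no baseline cells
   are flagged).
3. **Transfer**: each future cell of zone *z′* takes `m[i, z′]`.  Zones
   with no baseline support (novel climates) fill with 0 under a logged
   warning — conservative and explicit.

Derived surfaces: expected richness `Σ_i p_i`; treating genus presences
as independent Bernoulli draws, `P(≥1) = 1 − Π(1−p_i)` and
`P(>1) = P(≥1) − Σ_i p_i Π_{j≠i}(1−p_j)` (both are emitted because
"more than one" is ambiguous between them); and the change map
`Δ = future − base` with a strict `Δ > 0.2` gain mask.  The 20% gain is
read as an absolute suitability increase of 0.2 on the [0, 1] scale —
relative change is unstable near 0 — with a relative mode available.

## Hexagonal accounting

Hexagons are laid out flat-topped in a cylindrical equal-area projection
(standard parallel at the land's mid-latitude; area-true everywhere,
which is all the accounting needs) and clipped to land, so fragments
keep their true km² area.  The grid is sized by circumradius; the
package default for the synthetic world is 60 km, chosen so the ~7,300 ×
1,800 km land mass carries a grid of ~1,300 cells — large enough for
site statistics, small enough that the whole pipeline runs in seconds.
Radius, projection and origin are free parameters; no cell count is
hard-coded.  Points and raster-cell centers are assigned by containment
with boundary ties broken to the lowest cell id, making every
aggregation an exact partition: per-hexagon population sums reproduce
the raster total, and any grouping of hexagons sums to the global value.

## Exposure indices

The five-level biting-frequency scale ("very rare" … "very frequent")
maps to weights 0.8, 1.1, 1.4, 1.7, 2.0.  Human impact per hexagon and
slice is `population · Σ_s w_s · p_s`, species inheriting their genus's
suitability; because population is area × density, this is equivalently
the area-weighted density form, stated once to avoid double-weighting.
Impacts aggregate to countries (one country per hexagon by largest-area
intersection, keeping additivity exact) with per-country gained/lost
suitable area, and to 10° latitude bands as persons-at-risk: residents
of hexagons whose *best* species suitability reaches the medium-to-high
threshold τ (default 0.5) — "suitable for some tick", the natural
reading when genera occupy disjoint niches.  Livestock overlap (share of
cattle/sheep/goats kept in qualifying hexagons, and their density
there) is computed for the baseline slice only; no future livestock
surfaces exist to project onto.

**A known degeneracy:** with the default synthetic conditions the
zone-mean transfer tops out near 0.45 (max-normalized kernel peaks are
diluted by the broad log2 zones), so at τ = 0.5 the at-risk sets are
empty and the pipeline reports zeros.  That is the honest consequence of
the threshold's definition, not a bug; lower τ to profile the at-risk
population, and treat τ as a statement about the suitability scale in
use.

## The synthetic world

The generator exists so every stage is testable with no downloads; it
makes no attempt to mimic real tick biogeography or archive sampling
effort.  Defaults (the package's study conditions, all overridable):

* **Domain**: lon −10…10°, lat 0…70°, 0.5° cells; land is the window
  inset by a 1.5° ocean margin; 7 latitudinal-strip countries.
* **Climate**: annual mean temperature 29 − 0.5·|lat| °C plus a smooth
  unit-variance random field ×1.2; sinusoidal seasonality with amplitude
  2 + 0.18·|lat| °C peaking in July; log-precipitation with a zonal sine
  and a smooth field giving ~175–8,800 mm.  This spans 26 of the 38 life
  zones.  Slices 2020–2100 in 20-year steps; +1.0 °C per slice
  (≈ +4 °C by 2100, a high-end-scenario-like trend).
* **Genera**: four Gaussian niches in the climate triple — cold
  (BT 4.5 °C), temperate (9), hot-dry (21), hot-wet (27 °C) — each with
  2 species × 280 records.  Centers sit in band interiors so each genus
  has a well-defined home zone; 280 records leaves the >200-record rules
  satisfied with margin after corruption at any seed.
* **Sampling**: records drawn per cell with probability ∝ niche density
  × a smooth log-normal effort surface, jittered within the cell and
  written with 4-decimal coordinates; record keys are kept unique at the
  dedup resolution so the only duplicates are injected ones.
* **Corruption**: 5% exact duplicates, 5% offshore displacements, 5%
  2-decimal precision loss, on disjoint record sets — so a QC run
  recovers the injected counts exactly.
* **Populations**: smooth log-normal surfaces; 5·10⁸ people growing 5%
  per slice; cattle/sheep/goats 8/6/5·10⁷ head, baseline only.
* One world seed fans out to per-stage seeds by fixed offsets, so any
  stage regenerates alone, bit-for-bit.

Because records are drawn from niche × availability × effort, genus
record means sit up to ~0.5 niche-spreads away from the niche centers
(availability bias).  Recovery tests therefore compare sample statistics
with the *density-implied* values — the exact expectation of the
sampler — rather than the raw centers; the generator's job is to be
exactly the distribution it claims to be.  Passing tests show the
pipeline's arithmetic and bookkeeping are right under these conditions;
they do not show that real archives are unbiased, that real niches are
Gaussian, or that 38 climate classes capture real tick habitat.

## Numerical conventions

Half-open bands everywhere, with the driest/wettest and coldest/hottest
classes absorbing out-of-range values; classification is total over
BT ∈ [0, 30], P > 0 and returns 0 for no-data.  Permutation p-values use
the add-one rule and a 10⁻¹² slack when comparing permuted to observed
statistics so float rounding cannot flip exact ties.  Kernel tails
underflow to exactly 0 beyond ~38σ; suitability surfaces are
max-normalized per genus.  Ties in modal-zone and best-zone selection
break to the lowest id.  Empty zones, missing weights, non-positive
precipitation, and singular MANOVA problems raise errors naming the
offender rather than guessing.

## Problem sizes

The shipped configuration — 4,692 land cells, ~1,340 hexagons, 2,352
occurrence rows, 999 permutations — was chosen so the full pipeline
(`scripts/acceptance.py`) completes in a few seconds and the test suite
in well under a minute, while every stage still exercises non-trivial
spatial structure.

## Known limitations

* The baseline suitability kernel is a stand-in for an unspecified
  model; only the transfer machinery around it is validated.
* The Bernoulli composition of multi-genus probability assumes
  independence between genera, which co-occurrence data would violate.
* The equal-area projection is exact for areas but distorts shapes far
  from the standard parallel; hexagons are "hexagonal" only near it.
* Country assignment by largest-area intersection gives each hexagon to
  exactly one country; border hexagons are not split.
* The dedup key resolution (3 decimals) is a convention; sources with
  coarser honest precision would need it relaxed.
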