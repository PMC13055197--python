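# Methods

## The model of generational niche expansion

The analysis treats each fern species as two point clouds — sporophyte and
gametophyte occurrence records — under one standing biological assumption:
an observed sporophyte implies the recent presence of a gametophyte at the
same location (the converse does not hold).  All expansion metrics are
therefore partitions of the *pooled* occupancy into a sporophyte part and a
gametophyte-only remainder; a "sporophyte-only" area or volume is undefined
by construction and never reported.

Geographic occupancy is the union of geodesic circular buffers
(default radius 1 km) around records.  Each circle is traced with the
spherical great-circle destination formula (equivalent to buffering in a
local azimuthal equidistant frame) and all circles are merged and measured
in one Lambert azimuthal equal-area frame centred on the species' point
cloud; at 1-km radii the residual distortion of this construction is below
0.1% (the test suite checks circle and two-circle-lens areas to 0.5%).
GEP = G_geo/(G_geo+S_geo) where G_geo is the area the gametophyte records
add on top of the sporophyte union.

Climate occupancy is measured in a reduced climate space.  Variables are
bioclim-style summaries (annual mean or total, wettest/driest and
warmest/coldest quarter statistics over circularly consecutive 3-month
windows, annual range) of monthly precipitation, air temperature, soil
temperature, potential evapotranspiration, vapour pressure deficit and soil
water content.  Soil-medium variables enter only for terrestrial species;
epiphytes are characterized by air-medium variables.  Per species and per
variable category, both life stages are pooled, standardized to zero mean
and unit variance, and decomposed by PCA; the number of retained axes k is
the one whose cumulative explained variance is closest to 0.80 (ties toward
smaller k).  Occupancy is the exact convex-hull k-volume of a cloud in that
space (interval length for k = 1), computed with Qhull.
CEP = G_env/(G_env+S_env), with G_env = max(0, V_pooled − V_sporophyte); if
every pooled point lies inside the sporophyte hull (facet half-space test,
tolerance 1e-9) G_env is snapped to exactly zero.  Exact hulls are monotone
under point addition, so the "erroneous sporophyte volume" correction that
stochastic estimators require is identically zero; the subtraction hook is
retained for estimator extensibility.  The per-variable CEP applies the same
definition one variable at a time (the 1-D hull is the range) and averages
over variables.

Degenerate clouds: when either cloud has fewer than k+1 points the
dimensionality is reduced to what the smaller cloud supports; if nothing is
estimable the partition is flagged degenerate and CEP is 0 with a flag,
never NaN.

## Phylogenetic comparative fits

Under Brownian motion the between-tip trait covariance is proportional to
shared root-to-ancestor branch length (matrix C).  Pagel's λ multiplies the
off-diagonal of C, leaving the diagonal unchanged; λ is estimated by profile
maximum likelihood (β and σ² profiled out analytically) with a bounded
scalar search on [0, 1] (tolerance 1e-6), and boundary optima are reported
as exactly 0 or 1.  `fit_phylo_lm` is GLS with this covariance; its R² is
1 − RSS/TSS with both sums GLS-weighted about the GLS mean, and the focal
slope gets a Wald t test.  `fit_phylo_rma` estimates one shared λ from the
two intercept-only profile likelihoods, computes phylogenetically corrected
means, variances and covariance, and takes slope = sign(cov)·√(var_y/var_x);
the p-value is the analytic t test of zero correlation.  λ = 0 on an
ultrametric tree reproduces OLS to machine precision (tested), and RMA
slopes are reciprocal under axis exchange at fixed λ.

The GEP~CEP regression first excludes species with positive GEP and zero
CEP: their gametophyte climate is nested, so they carry no information about
the *coordination* of the two expansions.  A log-scale variant drops any
remaining nonpositive values before transforming.

## Trait harmonization

Light-response curves are fitted with the non-rectangular hyperbola
(parameters A_max, quantum yield φ, convexity θ ∈ (0,1], dark respiration
R_d) by bounded nonlinear least squares with a small multistart over (θ, φ),
because the SSE surface has local minima along the θ/φ trade-off; the
standardized rate is the model evaluated at 100 µmol m⁻² s⁻¹ PAR.  O₂-based
rates divide by a configurable photosynthetic quotient (default 1.0);
chlorophyll-based rates multiply by a configured chlorophyll-per-dry-mass
constant (no literature value is hard-coded).  Desiccation rates from
studies at different atmospheric water potentials are harmonized by a linear
factor derived from species shared between studies (the ratio of their two
rates, averaged when several species are shared); the worked example
0.646 × (−1.54) = −0.995 ΔRWC min⁻¹ is reproduced by the acceptance script.

The default trait~environment suite fits A_mass against twelve
habit-synthesized climate summaries (annual means, extreme-quarter
statistics and annual ranges of water input, temperature and PET — each
drawn from air media for epiphytes and soil media for terrestrial species,
with a logged fall-back to the 2-m air variable when a soil layer is
missing) plus ΔRWC against A_mass.  Water input and its annual range enter
log-transformed by default, reflecting the monotone-but-saturating shape of
those relationships; the transform is selectable per pair.  Growth habit is
available as an optional 0/1 fixed factor.

## What the synthetic data emulate — and what they do not

The generator provides every input with known ground truth.

*Climate.*  Smoothed, empirically orthonormalized Gaussian fields on a
regular ~1.1-km grid give each quantity a latent "level" field F_q and all
quantities one shared "seasonality strength" field H (continentality).
Monthly layers are affine in (F_q, H) with a window-constant amplitude, so
every derived summary is an exact affine function of the latents; soil
fields are damped copies of the air fields; PET and VPD mix temperature
positively and precipitation negatively with a common demand residual
(corr(PET, T) ≈ 0.65, corr(PET, P) ≈ −0.30).  The cell size (0.01°) keeps
all inter-cell distances above the 1-km thinning radius, and coordinate
jitter is ±4% of a cell, so QC never removes the records that support a
species' hull.

*Occurrences.*  A species' sporophyte cells are sampled from a climatic
window around a centroid seeded in commonly available climates.  Because
summaries are affine in the latents and standardization + PCA are affine
maps, convex-hull containment established on raw variables carries over
exactly to the reduced space.  The generator exploits this to make its
ground-truth labels *geometric guarantees* rather than statistical
tendencies: gametophyte cells of a non-expanding species are accepted only
if an LP feasibility test places their variable vector inside (a slightly
shrunk copy of) the sporophyte hull, giving CEP exactly 0; cells of an
expanding species sit a requested number of sporophyte-niche standard
deviations beyond the niche edge on the target axis while passing the same
nesting test on every other axis, giving off-axis CEPs of exactly 0.
Coupled species are additionally verified to register a positive overall
CEP after the closest-to-80% reduction (re-seeding the niche otherwise), so
a scenario's "13 expanding / 10 tracking" structure is deterministic.
Expanding species carry gametophyte record counts proportional to their
injected shift, which couples geographic to climatic expansion across
species the way spatial autocorrelation couples them in nature.

*Phylogeny and traits.*  Trees are pure-birth with unit depth and labels
sp_001….  A_mass is a known linear function of the species' mean annual PET
plus a Brownian deviate with covariance σ²·λ-transformed C; ΔRWC is an
affine function of A_mass plus noise, clipped to ≤ 0.  Light curves come
from a known hyperbola at a measurement ladder concentrated around the
100-µmol standardization irradiance (0, 40, 70, 90, 100, 110, 130, 250,
600), with anchors at darkness and saturation — the protocol one would use
when the target quantity is the rate at 100 µmol.

What passing tests therefore show: the estimators recover known truth under
the stated noise and sample sizes, the metrics' invariants hold exactly,
and the pipeline's structural behaviour (exclusion rule, axis attribution)
is correct.  What they do not show: performance under real-data pathologies
the generator omits — spatially biased sampling, georeferencing error,
taxonomic misidentification, non-affine climate structure, and the far
larger and more heterogeneous record counts of real aggregator downloads.
In particular, with 30–40 records per species convex-hull volumes are
noisy, so the *strength* of the cross-species GEP~CEP relationship varies
considerably between synthetic realizations even though its structure
(which species enter the regression) is fixed; absolute CEP/GEP values are
sensitive to occurrence counts and only their coordination should be
interpreted.

## Numerical choices and defaults

| parameter | default | meaning |
| --- | --- | --- |
| buffer radius | 1 km | geographic occupancy buffer |
| thinning distance | 1 km | greedy first-seen spatial thinning |
| outlier threshold | 0.75 | isolation-forest anomaly score, strict `>` |
| isolation forest | 100 trees, ψ = min(256, n) | per species, stages pooled |
| dedup precision | 4 decimal degrees | ~11 m |
| PCA target | 0.80 | closest cumulative variance, ties to smaller k |
| zero-area tolerance | 1e-6 km² | buffer-union slivers |
| hull nesting tolerance | 1e-9 | facet half-space test |
| λ search | bounded, xatol 1e-6 | boundary snapped to 0/1 |
| photosynthetic quotient | 1.0 | O₂→CO₂, configurable |
| chlorophyll per dry mass | none | must be configured when needed |

Scenario defaults (the study conditions of the test suite): 64×64 grid, 23
species, 30 sporophyte and 10 gametophyte-only records per species, 10
zero-CEP species, expansion up to 3 niche SD along temperature×water,
λ_true = 1, trait slope 0.004 per unit PET, trait noise SD 0.05.  Recovery
studies use 100-tip trees with 50 replicates, and 20 seeds per condition for
the expansion-recovery grid; the acceptance script uses 10–25 replicates per
quantity to keep a full run under a minute.

## Known limitations

- Buffer unions assume a spherical Earth and a single equal-area frame per
  species; species spanning more than a few thousand kilometres would incur
  visible distortion (irrelevant at the 1-km scales tested).
- The greedy thinning is order-dependent by design (deterministic), not a
  maximal-subset optimizer.
- The λ profile likelihood is unimodal in practice but not provably so; the
  optimizer cross-checks the boundary values.
- CEP comparisons across species mix reduced spaces of different
  dimensionality (k = 1–4), inheriting the scale caveats above.
- The per-variable CEP uses ranges (1-D hulls); quantile-based variants
  would be more outlier-robust but are not what the polytope definition
  implies.
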