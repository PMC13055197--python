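# fernexpand

Ferns are unique among vascular plants in having two free-living life
stages: the familiar sporophyte and a small, poikilohydric gametophyte that
survives without cuticle, vasculature or stomata.  Gametophytes of some
species establish beyond the geographic range of their conspecific
sporophytes, which raises a quantitative question: **how much geographic and
climatic niche space do gametophytes occupy that sporophytes do not, and
along which axes of climate does that expansion happen?**

`fernexpand` is a Python library for macroecologists and fern biologists
that implements this generational niche-expansion analysis end to end:
occurrence-record QC, geographic and climatic expansion metrics, axis-wise
climate decomposition, phylogenetic comparative regressions, and the
harmonization of heterogeneous gametophyte ecophysiology — together with a
synthetic-data module that generates occurrences, ~1-km climate grids,
phylogenies, traits and light-response curves with known ground truth, so
every stage is testable without any download.

## The metrics

For each species, occurrence records of both life stages are cleaned
(preserved-specimen filter, deduplication, 1-km spatial thinning, and an
isolation-forest environmental outlier screen at anomaly score > 0.75) under
the standing assumption that a sporophyte observation implies recent
gametophyte presence at that location.

**Geographic expansion potential.**  Each record is buffered by a geodesic
1-km circle; with S_geo the sporophyte buffer-union area and G_geo the extra
area contributed by gametophyte-only records,

    GEP = G_geo / (G_geo + S_geo)

**Climate expansion potential.**  Environmental values (bioclim-style
seasonal summaries of monthly precipitation, air/soil temperature, PET, VPD
and soil water content; soil media used for terrestrial species only) are
extracted at the records, standardized, and reduced per species by PCA to
the number of axes whose cumulative variance is closest to 80%.  Niche
occupancy is the exact convex-polytope (convex hull) volume of a point cloud
in that space; with S_env the sporophyte hull volume and G_env the volume
added by gametophyte-only records,

    CEP = G_env / (G_env + S_env)

CEP is computed overall and per climate axis — temperature variables only,
water variables only, and the temperature×water variables (PET, VPD) that
express atmospheric water demand.  Because exact hulls can only grow when
points are added, the "erroneous sporophyte volume" that stochastic
hypervolume estimators produce is identically zero here.

**Comparative statistics.**  GEP and CEP are related across species by
phylogenetic reduced major axis regression (slope = sign(cov)·√(var_y/var_x)
on phylogenetically corrected moments) under a Pagel's λ covariance
transform estimated by profile maximum likelihood; species with positive GEP
but zero CEP are excluded first.  Trait–environment convergence (A_mass, the
CO₂ assimilation rate per dry mass standardized to 100 µmol m⁻² s⁻¹ PAR,
against habit-synthesized climate summaries, and desiccation rate ΔRWC min⁻¹
against A_mass) is fitted by phylogenetic GLS.

## A worked example

```bash
python examples/climate_expansion.py
```

simulates a terrestrial species whose gametophytes were pushed three
niche standard deviations along the temperature–water axis and prints:

```
CEP (all variables)        =   8.6%
CEP temperature            =   0.0%
CEP water                  =   0.0%
CEP temperature x water    =  28.5%
mean per-variable CEP      =   6.0%
```

28.5% of the species' climate occupancy on the temperature×water axis is
attributable to gametophytes only, while on the pure temperature and water
axes the gametophyte cloud is exactly nested inside the sporophyte hull —
the analysis recovers both the presence and the axis of the injected
expansion.  The other scripts in `examples/` each demonstrate one
capability: occurrence QC, buffer-union GEP, the 23-species GEP~CEP
regression, light-curve standardization, and the trait–environment suite.
A thin CLI (`fernexpand simulate|qc|expansion|traits|all`) wraps the same
pipeline for shell use.

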