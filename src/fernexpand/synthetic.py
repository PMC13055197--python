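"""Synthetic data with the statistical structure the analysis assumes.

Every pipeline stage is testable offline because the generators provide known
ground truth:

* spatially autocorrelated climate layers in which potential
  evapotranspiration and vapour pressure deficit are genuinely interdependent
  with temperature (positively) and water (negatively);
* two-point-cloud species occurrences in which sporophyte presence implies
  gametophyte presence, and gametophyte-only points either nest inside the
  sporophyte climate exactly or are shifted a controlled number of niche
  standard deviations along a chosen climate axis;
* Brownian-motion traits on a simulated pure-birth phylogeny with a known
  Pagel's lambda and a known trait-environment slope;
* noisy saturating light-response curves from known hyperbola parameters.

Monthly layers for each quantity q are affine in two latent fields
(F_q: annual level; H_q: seasonal amplitude):

    layer_m = b_q + (amp_q + gamma_q * H_q) * s_m + alpha_q * F_q

with a shared seasonal shape s_m and gamma_q small enough that the seasonal
amplitude stays positive everywhere.  Every bioclim-style summary is then an
exact affine function of (F_q, H_q), so convex-hull containment established
on the latent/raw variables carries over exactly to standardized PCA scores.
The nestedness of a "no-expansion" species is therefore a geometric
guarantee, not a statistical accident.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate import (CATEGORIES, ClimateLayerSet, Grid, MonthlySeries,
                      QUANTITY_META, point_in_hull_lp, summaries_to_layerset)
from .occurrences import OccurrenceRecord
from .phylo import phylo_covariance, read_newick, simulate_brownian
from .traits import LightResponseCurve, TraitRecord, non_rectangular_hyperbola

QUANTITIES = tuple(QUANTITY_META)

#: monthly model constants per quantity: (baseline b, seasonal amplitude amp,
#: spatial slope alpha, amplitude-variation gamma); units are nominal
_MONTHLY_CONSTANTS = {
    "precipitation": (100.0, 20.0, 15.0, 3.0),
    "air_temperature": (15.0, 8.0, 5.0, 1.2),
    "soil_temperature": (14.0, 6.0, 4.0, 0.9),
    "pet": (80.0, 30.0, 20.0, 4.5),
    "vpd": (1.0, 0.4, 0.3, 0.06),
    "soil_water_content": (0.25, 0.05, 0.08, 0.008),
}

_UNITS = {
    "precipitation": "mm", "air_temperature": "degC", "soil_temperature": "degC",
    "pet": "mm", "vpd": "kPa", "soil_water_content": "m3/m3",
}

#: ~1.1-km cells: keeps all inter-cell great-circle distances above the 1-km
#: thinning radius so QC thinning never breaks generated nestedness
CELL_SIZE_DEG = 0.01


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    grid_size: int = 64
    n_species: int = 23
    n_spor: int = 30
    n_gam_extra: int = 10
    expansion_delta: float = 3.0
    expansion_category: str = "none"  # none | temperature | water | temperature_water
    lambda_true: float = 1.0
    trait_slope_true: float = 0.004
    noise_sd: float = 0.05
    n_zero_cep: int = 10  # species with positive GEP but exactly nested climate

    def __post_init__(self) -> None:
        if min(self.grid_size, self.n_species, self.n_spor, self.n_gam_extra) <= 0:
            raise ValueError("counts must be positive")
        if self.grid_size < 16:
            raise ValueError("grid_size must be at least 16")
        if self.expansion_delta < 0:
            raise ValueError("expansion_delta must be non-negative")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.expansion_category not in ("none",) + CATEGORIES:
            raise ValueError(f"unknown expansion category {self.expansion_category!r}")


@dataclass
class SyntheticClimate:
    """Bundle of the generated climate: derived-summary layers, the monthly
    series they came from, and the latent fields behind each quantity."""

    summaries: ClimateLayerSet
    monthly: dict  # quantity -> MonthlySeries
    level_fields: dict  # quantity -> F_q grid (unit variance, zero mean)
    amplitude_fields: dict  # quantity -> H_q grid
    grid: Grid = field(init=False)

    def __post_init__(self) -> None:
        self.grid = self.summaries.grid


def _smooth_fields(rng, n_fields: int, shape, sigma: float) -> np.ndarray:
    """Smoothed white-noise fields, empirically orthonormalized (zero mean,
    unit variance, mutually uncorrelated) so mixing weights translate into
    exact empirical correlations."""
    ncell = shape[0] * shape[1]
    cols = [np.ones(ncell)]
    for _ in range(n_fields):
        cols.append(gaussian_filter(rng.standard_normal(shape), sigma=sigma).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    fields = q[:, 1:] * np.sqrt(ncell)  # drop the constant column -> zero-mean fields
    return fields.T.reshape(n_fields, *shape)


def simulate_climate_layers(scenario: SyntheticScenario) -> SyntheticClimate:
    """Seeded, spatially autocorrelated monthly climate plus derived summaries.

    PET and VPD share a common demand residual and mix temperature positively
    and precipitation negatively, so the temperature-water axis is genuinely
    interdependent with, yet not reducible to, the other two axes.
    """
    rng = np.random.default_rng([int(scenario.seed), 7])
    gs = scenario.grid_size
    grid = Grid(lon_min=-gs / 2 * CELL_SIZE_DEG, lat_min=-gs / 2 * CELL_SIZE_DEG,
                cell_size_deg=CELL_SIZE_DEG, nx=gs, ny=gs)
    e = _smooth_fields(rng, 4, (gs, gs), sigma=gs / 8)
    t_field, p_field, demand = e[0], e[1], e[2]
    # soil fields are damped transforms of the air fields (buffered medium);
    # keeping them affine in the same latents keeps each climate axis low-
    # dimensional, which the hull-nesting guarantees rely on
    level = {
        "air_temperature": t_field,
        "precipitation": p_field,
        "soil_temperature": 0.9 * t_field,
        "soil_water_content": 0.9 * p_field,
        "pet": (0.65 * t_field - 0.30 * p_field + 0.70 * demand) / np.sqrt(0.9925),
        "vpd": (0.60 * t_field - 0.30 * p_field + 0.74 * demand) / np.sqrt(0.9976),
    }
    # one shared seasonality-strength field (continentality): amplitude
    # variation is perfectly coherent across quantities
    amplitude = {q: e[3] for q in QUANTITIES}
    s = np.sin(2.0 * np.pi * np.arange(12) / 12.0)
    monthly = {}
    for q in QUANTITIES:
        b, amp, alpha, gamma = _MONTHLY_CONSTANTS[q]
        layers = np.stack([
            b + (amp + gamma * amplitude[q]) * s[m] + alpha * level[q]
            for m in range(12)
        ])
        monthly[q] = MonthlySeries(quantity=q, grid=grid, layers=layers, units=_UNITS[q])
    return SyntheticClimate(
        summaries=summaries_to_layerset([monthly[q] for q in QUANTITIES]),
        monthly=monthly, level_fields=level, amplitude_fields=amplitude,
    )


# ---------------------------------------------------------------------------
# species occurrences
# ---------------------------------------------------------------------------

def _category_matrix(climate: SyntheticClimate, category: str, cells) -> np.ndarray:
    """Derived-summary variable vectors of ``category`` (or all) at flat cell
    indices."""
    cols = [arr.ravel()[cells] for var, arr in climate.summaries.variables
            if category == "all" or var.category == category]
    return np.column_stack(cols)


def _inside_shrunk_hull(v: np.ndarray, hull_pts: np.ndarray, shrink: float) -> bool:
    center = hull_pts.mean(axis=0)
    return point_in_hull_lp(center + (v - center) / shrink, hull_pts)


def _cell_records(climate, cells, species_id, stage, source, basis, rng):
    grid = climate.grid
    ii, jj = np.unravel_index(np.asarray(cells, dtype=int), grid.shape)
    lon = grid.lon_min + (jj + 0.5) * grid.cell_size_deg
    lat = grid.lat_min + (ii + 0.5) * grid.cell_size_deg
    # jitter small enough that adjacent-cell records stay > 1 km apart, so
    # 1-km thinning never removes the records that support a species' hull
    jit = rng.uniform(-0.04, 0.04, size=(len(cells), 2)) * grid.cell_size_deg
    return [
        OccurrenceRecord(species_id=species_id, life_stage=stage,
                         longitude=float(lon[k] + jit[k, 0]),
                         latitude=float(lat[k] + jit[k, 1]),
                         basis_of_record=basis, source=source)
        for k in range(len(cells))
    ]


def simulate_species_occurrences(climate: SyntheticClimate, scenario: SyntheticScenario,
                                 species_index: int, *, expansion_delta=None,
                                 expansion_category=None,
                                 zero_cep_positive_gep: bool = False,
                                 n_gam_override: int | None = None):
    """Occurrence records for one species: ``n_spor`` sporophyte points from a
    climatic niche window plus ``n_gam_extra`` gametophyte-only points.

    With ``expansion_delta = 0`` the gametophyte cells are drawn from the
    sporophyte cells themselves (exactly nested climate).  With a positive
    delta they come from cells shifted ``delta`` sporophyte-niche standard
    deviations along the chosen category's level fields while remaining
    nested, by convex-hull test, in every other category.  With
    ``zero_cep_positive_gep`` they are spatially distant cells whose climate
    stays nested in all categories (positive GEP, CEP exactly zero).
    """
    if n_gam_override is not None:
        scenario = dataclasses.replace(scenario, n_gam_extra=int(n_gam_override))
    delta = scenario.expansion_delta if expansion_delta is None else float(expansion_delta)
    category = scenario.expansion_category if expansion_category is None else expansion_category
    if category == "none":
        delta = 0.0
    rng = np.random.default_rng([int(scenario.seed), 1000 + int(species_index)])
    species_id = f"sp_{species_index + 1:03d}"
    gs = scenario.grid_size
    ncell = gs * gs
    F = {q: climate.level_fields[q].ravel() for q in QUANTITIES}
    H = {q: climate.amplitude_fields[q].ravel() for q in QUANTITIES}

    target_qs = [q for q in QUANTITIES if QUANTITY_META[q][0] == category] if delta > 0 else []

    # --- sporophyte niche window ------------------------------------------------
    # niche centroids sit in climatically central cells (species centre in
    # commonly available climates); with an injected expansion, additionally
    # away from the target axis' upper tail so the outward shift stays on grid
    cut = np.abs(H["pet"]) <= 1.2
    for q in QUANTITIES:
        cut &= np.abs(F[q]) <= 1.2
    for q in target_qs:
        cut &= F[q] <= np.quantile(F[q], 0.6)
    seed_pool = np.where(cut)[0]
    if seed_pool.size == 0:
        seed_pool = np.arange(ncell)
    last_err = None
    for niche_try in range(10):
        for attempt in range(12):
            w = 0.75 * (1.0 + 0.15 * attempt)
            seed_cell = int(rng.choice(seed_pool))
            c = {q: F[q][seed_cell] for q in QUANTITIES}
            ch = H["pet"][seed_cell]
            mask = np.abs(H["pet"] - ch) <= 1.0 + 0.3 * attempt
            for q in QUANTITIES:
                mask &= np.abs(F[q] - c[q]) <= w
            eligible = np.where(mask)[0]
            if eligible.size >= scenario.n_spor:
                break
        else:
            raise RuntimeError("unreachable niche; regenerate layers or widen niche")
        spor_cells = rng.choice(eligible, size=scenario.n_spor,
                                replace=eligible.size < scenario.n_spor)

        # --- gametophyte-only cells ---------------------------------------------
        if delta == 0 and not zero_cep_positive_gep:
            n = min(scenario.n_gam_extra, len(spor_cells))
            gam_cells = list(rng.choice(spor_cells, size=n, replace=False))
            while len(gam_cells) < scenario.n_gam_extra:
                gam_cells.append(int(rng.choice(spor_cells)))
            break
        try:
            gam_cells = _expansion_cells(climate, scenario, rng, F, H, spor_cells,
                                         target_qs, delta, zero_cep_positive_gep, gs)
            if (delta > 0 and niche_try < 6
                    and not _registers_overall_expansion(climate, spor_cells,
                                                         gam_cells)):
                # the expansion axis fell below the retained PC axes: this
                # niche cannot carry the ground-truth label; reseed
                raise RuntimeError("expansion does not register in overall CEP")
            break
        except RuntimeError as err:  # niche placement unlucky: reseed and retry
            last_err = err
            if zero_cep_positive_gep and niche_try >= 3:
                # guaranteed fallback: gametophytes at sporophyte cells (same
                # climate, offset location) -> CEP exactly 0, GEP still > 0
                n = min(scenario.n_gam_extra, len(spor_cells))
                gam_cells = list(rng.choice(spor_cells, size=n, replace=False))
                while len(gam_cells) < scenario.n_gam_extra:
                    gam_cells.append(int(rng.choice(spor_cells)))
                break
    else:
        raise RuntimeError(f"unreachable niche after retries: {last_err}")

    records = _cell_records(climate, spor_cells, species_id, "sporophyte",
                            "database", "PRESERVED_SPECIMEN", rng)
    records += _cell_records(climate, gam_cells, species_id, "gametophyte",
                             "literature", "", rng)
    return records


def _registers_overall_expansion(climate: SyntheticClimate, spor_cells, gam_cells) -> bool:
    """Check that the injected expansion survives the closest-to-80% PCA
    reduction of the pooled variable set — i.e. that the species' overall CEP
    is positive — for both the soil-inclusive (terrestrial) and air-only
    (epiphytic) variable selections.

    A coupled species in a scenario is labelled "expanding" in the ground
    truth; this check makes the generator honour its own label instead of
    silently producing a species whose expansion is confined to a discarded
    axis.
    """
    from .climate import (EnvSample, cep_by_axis)

    # duplicate cells are what 1-km thinning removes downstream, so the check
    # runs on unique cells and demands a margin, not a marginal registration
    spor_u = np.unique(np.asarray(spor_cells))
    gam_u = np.unique(np.asarray(gam_cells))
    cells = np.concatenate([spor_u, gam_u])
    matrix = _category_matrix(climate, "all", cells)
    stages = np.array(["sporophyte"] * len(spor_u) + ["gametophyte"] * len(gam_u))
    sample = EnvSample(matrix=matrix, variable_meta=list(climate.summaries.meta),
                       stage_labels=stages)
    for habit in ("terrestrial", "epiphytic"):
        if cep_by_axis(sample, habit)["cep_all"] <= 0.01:
            return False
    return True


def _empirical_window(values, frac):
    """Interval around the median covering ``frac`` of the spread toward each
    empirical extreme."""
    m = float(np.median(values))
    return (m - frac * (m - float(np.min(values))),
            m + frac * (float(np.max(values)) - m))


def _expansion_cells(climate, scenario, rng, F, H, spor_cells,
                     target_qs, delta, zero_cep, gs):
    ncell = gs * gs
    spor_ij = np.column_stack(np.unravel_index(spor_cells, (gs, gs)))
    # delta is measured in sporophyte-niche standard deviations on the target
    # axis, anchored at the niche's upper edge so any positive delta reaches
    # beyond the occupied climate; non-target coordinates are held inside the
    # sporophyte cells' empirical intervals so they stay hull-nested
    sd_t = {q: max(float(np.std(F[q][spor_cells], ddof=0)), 0.15) for q in target_qs}
    hi_t = {q: float(np.max(F[q][spor_cells])) for q in target_qs}
    hulls = {cat: _category_matrix(climate, cat, spor_cells)
             for cat in CATEGORIES + ("all",)}

    # a zero-expansion species must be nested in the pooled variable hull as
    # well, so its overall CEP is exactly zero, not merely each axis-wise CEP
    nested_cats = [cat for cat in CATEGORIES
                   if not any(q in target_qs for q in QUANTITIES if QUANTITY_META[q][0] == cat)]

    for attempt in range(12):
        widen = 1.0 + 0.25 * attempt
        shrink = min(0.88 + 0.04 * attempt, 1.0)
        frac = min(0.55 + 0.08 * attempt, 0.95)
        lo_h, hi_h = _empirical_window(H["pet"][spor_cells], frac)
        mask = (H["pet"] >= lo_h) & (H["pet"] <= hi_h)
        for q in QUANTITIES:
            if q in target_qs:
                # the window's lower edge stays put while widening, so early
                # retries cannot quietly shrink the injected shift
                relax = widen if attempt >= 5 else 1.0
                lo = hi_t[q] + max(delta - 1.0, 0.0) * sd_t[q] / relax
                hi = hi_t[q] + delta * sd_t[q] + 0.5 * widen
                mask &= (F[q] >= lo) & (F[q] <= hi)
            else:
                lo, hi = _empirical_window(F[q][spor_cells], frac)
                mask &= (F[q] >= lo) & (F[q] <= hi)
        if zero_cep:
            cand_ij = np.column_stack(np.unravel_index(np.arange(ncell), (gs, gs)))
            dmin = np.min(
                np.abs(cand_ij[:, None, :] - spor_ij[None, :, :]).max(axis=2), axis=1
            )
            mask &= dmin >= 3  # buffers cannot touch -> positive GEP guaranteed
        candidates = np.where(mask)[0]
        rng.shuffle(candidates)
        accepted = []
        # nesting in the pooled hull implies nesting in every category
        # projection, so the zero-expansion check reduces to "all"; on late
        # attempts for an expanding species, off-axis spill beats failure
        if zero_cep:
            check_cats = ("all",)
        elif attempt >= 10:
            check_cats = ()
        else:
            check_cats = nested_cats
        for cell in candidates:
            ok = all(
                _inside_shrunk_hull(
                    _category_matrix(climate, cat, np.array([cell]))[0],
                    hulls[cat], shrink)
                for cat in check_cats
            )
            if ok:
                accepted.append(int(cell))
            if len(accepted) >= scenario.n_gam_extra:
                break
        if attempt >= 8:
            required = 1
        elif attempt >= 5:
            required = max(1, scenario.n_gam_extra // 2)
        else:
            required = scenario.n_gam_extra
        if len(accepted) >= required:
            while len(accepted) < scenario.n_gam_extra:
                accepted.append(int(rng.choice(accepted)))
            return accepted
    raise RuntimeError("unreachable niche; regenerate layers or widen niche")


def simulate_scenario_dataset(scenario: SyntheticScenario):
    """Full multi-species dataset for one scenario.

    The first ``n_species - n_zero_cep`` species are "coupled": their
    gametophytes expand along ``expansion_category`` with per-species deltas
    spread over [0.5, 1.0] x ``expansion_delta`` (so the GEP~CEP regression
    sees a gradient, not a single point).  The remaining ``n_zero_cep``
    species have positive GEP but exactly nested climate.  With category
    "none" every species is plainly nested.

    Returns a dict with records (per species), climate, tree, habits and a
    ground-truth log.
    """
    climate = simulate_climate_layers(scenario)
    tree = simulate_tree(scenario.n_species, seed=scenario.seed)
    n_coupled = scenario.n_species - scenario.n_zero_cep \
        if scenario.expansion_category != "none" else 0
    if n_coupled < 0:
        raise ValueError("n_zero_cep exceeds n_species")
    deltas = (np.linspace(0.5, 1.0, n_coupled) * scenario.expansion_delta
              if n_coupled else np.empty(0))
    records, habits, truth = {}, {}, {}
    for i in range(scenario.n_species):
        sp = f"sp_{i + 1:03d}"
        habits[sp] = "epiphytic" if i % 2 == 0 else "terrestrial"
        if i < n_coupled:
            # stronger climate expanders carry more gametophyte-only records,
            # so geographic and climatic expansion co-vary across species
            n_gam = max(3, round(scenario.n_gam_extra * deltas[i]
                                 / max(scenario.expansion_delta, 1e-9)))
            recs = simulate_species_occurrences(
                climate, scenario, i, expansion_delta=float(deltas[i]),
                expansion_category=scenario.expansion_category,
                n_gam_override=n_gam)
            truth[sp] = {"delta": float(deltas[i]),
                         "category": scenario.expansion_category,
                         "n_gam": n_gam}
        elif scenario.expansion_category != "none":
            recs = simulate_species_occurrences(
                climate, scenario, i, expansion_delta=0.0,
                zero_cep_positive_gep=True)
            truth[sp] = {"delta": 0.0, "category": "none", "positive_gep": True}
        else:
            recs = simulate_species_occurrences(climate, scenario, i,
                                                expansion_delta=0.0)
            truth[sp] = {"delta": 0.0, "category": "none"}
        records[sp] = recs
    return {"climate": climate, "tree": tree, "records": records,
            "habits": habits, "ground_truth": truth, "scenario": scenario}


# ---------------------------------------------------------------------------
# tree, traits, light curves
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0):
    """Pure-birth (Yule) tree with unit root-to-tip depth and labels sp_001..."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng([int(seed), 11])

    class _Node:
        __slots__ = ("time", "children", "label")

        def __init__(self, time):
            self.time = time
            self.children = []
            self.label = None

    root = _Node(0.0)
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    active, t = [a, b], 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        parent.time = t
        kids = [_Node(t), _Node(t)]
        parent.children = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / len(active))
    for i, leaf in enumerate(active):
        leaf.label = f"sp_{i + 1:03d}"

    def newick(node, parent_time):
        tip_time = t_end if not node.children else node.time
        length = (tip_time - parent_time) / t_end  # scale depth to 1
        if not node.children:
            return f"{node.label}:{length:.10f}"
        inner = ",".join(newick(ch, node.time) for ch in node.children)
        return f"({inner}):{length:.10f}"

    inner = ",".join(newick(ch, 0.0) for ch in root.children)
    return read_newick(f"({inner});")


def simulate_traits(tree, env_summaries, scenario: SyntheticScenario):
    """Trait records with a known trait-environment slope and lambda.

    ``a_mass = trait_slope_true * mapet + BM`` where the Brownian deviate has
    covariance noise_sd^2 * lambda-transformed C; ``delta_rwc`` is an affine
    function of a_mass plus small noise (the photosynthesis-desiccation
    coupling).  Habits alternate epiphytic/terrestrial by species order.
    """
    rng = np.random.default_rng([int(scenario.seed), 23])
    C, labels = phylo_covariance(tree)
    missing = [s for s in labels if s not in env_summaries.index]
    if missing:
        raise ValueError(f"env summaries missing for {missing}")
    bm = simulate_brownian(C, scenario.noise_sd, rng, lam=scenario.lambda_true)
    out = []
    for i, sp in enumerate(labels):
        env = {k: float(v) for k, v in env_summaries.loc[sp].items()}
        a_mass = max(scenario.trait_slope_true * env["mapet"] + bm[i], 1e-6)
        delta_rwc = min(-1.3 + 1.0 * a_mass + 0.05 * rng.standard_normal(), 0.0)
        out.append(TraitRecord(
            species_id=sp, habit="epiphytic" if i % 2 == 0 else "terrestrial",
            a_mass=float(a_mass), delta_rwc=float(delta_rwc), env=env))
    return out


#: measurement ladder aimed at rate standardization: levels concentrated
#: around the 100 umol m-2 s-1 reference irradiance, with anchors at darkness
#: and saturation to pin respiration and A_max
_PAR_LADDER = np.array([0.0, 40.0, 70.0, 90.0, 100.0, 110.0, 130.0, 250.0,
                        600.0])


def simulate_light_curves(true_params: dict, n_points: int = 9,
                          noise_sd: float = 0.0, seed: int = 0) -> LightResponseCurve:
    """Noisy observations of a known non-rectangular hyperbola, always
    including the 100 umol PAR standardization level."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng([int(seed), 31])
    if n_points > _PAR_LADDER.size:
        extra = np.linspace(0.0, 600.0, n_points - _PAR_LADDER.size + 2)
        par = np.unique(np.concatenate([_PAR_LADDER, extra]))
    else:
        idx = np.round(np.linspace(0, _PAR_LADDER.size - 1, n_points)).astype(int)
        par = np.unique(np.concatenate([[0.0, 100.0, 600.0], _PAR_LADDER[idx]]))
    clean = non_rectangular_hyperbola(par, true_params["a_max"],
                                      true_params["quantum_yield"],
                                      true_params["convexity"],
                                      true_params["dark_respiration"])
    noisy = clean + noise_sd * rng.standard_normal(par.size)
    return LightResponseCurve(par=par, assimilation=noisy, species_id="synthetic")
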