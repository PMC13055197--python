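"""Climate niche occupancy and the climate expansion potential (CEP).

Environmental values are extracted at occurrence points from ~1-km gridded
layers, reduced per species by PCA to the number of axes that most closely
captures 80% of the cumulative variance, and niche volumes are measured as
exact convex-polytope (convex hull) volumes in the reduced space:

    CEP = G_env / (G_env + S_env)

where S_env is the sporophyte hull volume and G_env the additional volume
contributed by gametophyte-only points.  CEP is decomposable by climate axis
(temperature | water | temperature×water variables), with soil-medium
variables included for terrestrial species only.

Rasters are plain regular lon/lat grids held as numpy arrays with NaN as the
nodata sentinel; they can be round-tripped through a text format (one
whitespace-separated grid per variable plus a JSON header).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

CATEGORIES = ("temperature", "water", "temperature_water")
MEDIA = ("air", "soil")

#: quantity -> (category, medium) used throughout the synthetic and derived layers
QUANTITY_META = {
    "precipitation": ("water", "air"),
    "air_temperature": ("temperature", "air"),
    "pet": ("temperature_water", "air"),
    "vpd": ("temperature_water", "air"),
    "soil_temperature": ("temperature", "soil"),
    "soil_water_content": ("water", "soil"),
}


@dataclass(frozen=True)
class ClimateVariable:
    name: str
    category: str
    medium: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")


@dataclass(frozen=True)
class Grid:
    """Regular geographic grid; cell (i, j) is centred at
    (lon_min + (j + 0.5) dx, lat_min + (i + 0.5) dy)."""

    lon_min: float
    lat_min: float
    cell_size_deg: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size_deg <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self):
        return (self.ny, self.nx)

    def cell_centers(self):
        lon = self.lon_min + (np.arange(self.nx) + 0.5) * self.cell_size_deg
        lat = self.lat_min + (np.arange(self.ny) + 0.5) * self.cell_size_deg
        return lon, lat

    def index_of(self, lon, lat):
        """Nearest-cell indices (i, j) and an in-bounds mask for point arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        j = np.floor((lon - self.lon_min) / self.cell_size_deg).astype(int)
        i = np.floor((lat - self.lat_min) / self.cell_size_deg).astype(int)
        inside = (j >= 0) & (j < self.nx) & (i >= 0) & (i < self.ny)
        return i, j, inside

    def to_dict(self):
        return {
            "lon_min": self.lon_min,
            "lat_min": self.lat_min,
            "cell_size_deg": self.cell_size_deg,
            "nx": self.nx,
            "ny": self.ny,
        }


@dataclass
class ClimateLayerSet:
    """A set of congruent gridded variables."""

    grid: Grid
    variables: list  # list[(ClimateVariable, np.ndarray)]

    def __post_init__(self) -> None:
        for var, arr in self.variables:
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {var.name} not congruent with grid")

    @property
    def names(self):
        return [v.name for v, _ in self.variables]

    @property
    def meta(self):
        return [v for v, _ in self.variables]

    def get(self, name: str) -> np.ndarray:
        for var, arr in self.variables:
            if var.name == name:
                return arr
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return name in self.names

    # -- plain-text persistence -------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        header = {
            "grid": self.grid.to_dict(),
            "variables": [
                {"name": v.name, "category": v.category, "medium": v.medium, "units": v.units}
                for v in self.meta
            ],
        }
        (path / "grid.json").write_text(json.dumps(header, indent=1))
        for var, arr in self.variables:
            np.savetxt(path / f"{var.name}.txt", arr)

    @classmethod
    def from_dir(cls, path) -> "ClimateLayerSet":
        path = Path(path)
        header = json.loads((path / "grid.json").read_text())
        grid = Grid(**header["grid"])
        variables = []
        for meta in header["variables"]:
            arr = np.loadtxt(path / f"{meta['name']}.txt").reshape(grid.shape)
            variables.append((ClimateVariable(**meta), arr))
        return cls(grid=grid, variables=variables)


@dataclass
class MonthlySeries:
    """Twelve monthly layers of one quantity on a shared grid."""

    quantity: str
    grid: Grid
    layers: np.ndarray  # (12, ny, nx)
    units: str = ""

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.shape != (12,) + self.grid.shape:
            raise ValueError("MonthlySeries needs exactly 12 congruent layers")
        if self.quantity not in QUANTITY_META:
            raise ValueError(f"unknown quantity {self.quantity!r}")


@dataclass
class EnvSample:
    """Environmental values at occurrence points (no nodata rows)."""

    matrix: np.ndarray  # (n_records, n_variables)
    variable_meta: list
    stage_labels: np.ndarray | None = None  # per-row 'gametophyte' | 'sporophyte'
    kept_rows: np.ndarray | None = None  # indices into the original point list
    dropped_rows: list = field(default_factory=list)  # (index, reason)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.variable_meta):
            raise ValueError("matrix shape inconsistent with variable metadata")
        if np.isnan(self.matrix).any():
            raise ValueError("EnvSample must not contain nodata values")
        if self.stage_labels is not None:
            self.stage_labels = np.asarray(self.stage_labels)
            if self.stage_labels.shape[0] != self.matrix.shape[0]:
                raise ValueError("stage labels must align with matrix rows")

    def subset_variables(self, meta_subset) -> "EnvSample":
        idx = [self.variable_meta.index(v) for v in meta_subset]
        return EnvSample(
            matrix=self.matrix[:, idx],
            variable_meta=list(meta_subset),
            stage_labels=self.stage_labels,
            kept_rows=self.kept_rows,
        )


@dataclass
class ClimatePartition:
    """Partitioned climate volume in PC-space units."""

    g_env: float
    s_env: float
    erroneous_sporophyte_volume: float
    k_dims: int
    category: str = "all"
    degenerate: bool = False

    def __post_init__(self) -> None:
        for v in (self.g_env, self.s_env, self.erroneous_sporophyte_volume):
            if v < 0:
                raise ValueError("volumes must be non-negative")


@dataclass
class ExpansionResult:
    """Per-species expansion summary (percent scales)."""

    species_id: str
    habit: str
    gep_percent: float
    cep_percent: float
    cep_temperature_percent: float
    cep_water_percent: float
    cep_interaction_percent: float
    per_variable_mean_cep_percent: float
    n_gam: int
    n_spor: int


# ---------------------------------------------------------------------------
# extraction and derived layers
# ---------------------------------------------------------------------------

def extract_env(points, layers: ClimateLayerSet, stage_labels=None) -> EnvSample:
    """Nearest-cell environmental values per point; rows with any nodata are
    dropped and logged (as are points outside the grid extent)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    i, j, inside = layers.grid.index_of(pts[:, 0], pts[:, 1])
    n = pts.shape[0]
    mat = np.full((n, len(layers.variables)), np.nan)
    for col, (_, arr) in enumerate(layers.variables):
        mat[inside, col] = arr[i[inside], j[inside]]
    ok = inside & ~np.isnan(mat).any(axis=1)
    dropped = [(int(r), "outside grid" if not inside[r] else "nodata") for r in np.where(~ok)[0]]
    labels = None
    if stage_labels is not None:
        labels = np.asarray(stage_labels)[ok]
    return EnvSample(
        matrix=mat[ok],
        variable_meta=list(layers.meta),
        stage_labels=labels,
        kept_rows=np.where(ok)[0],
        dropped_rows=dropped,
    )


def derive_seasonal_summaries(series: MonthlySeries) -> dict:
    """Bioclim-style summaries from 12 monthly layers.

    Returns ``annual_mean`` (annual total for precipitation), the mean of the
    most extreme 3-month circular window (``max_quarter``/``min_quarter``;
    window totals for precipitation), and ``annual_range`` (max month − min
    month).  NaN in any month propagates to every summary at that cell.
    """
    months = series.layers
    is_precip = series.quantity == "precipitation"
    annual = months.sum(axis=0) if is_precip else months.mean(axis=0)
    windows = np.empty_like(months)
    for q in range(12):
        win = months[[q, (q + 1) % 12, (q + 2) % 12]]
        windows[q] = win.sum(axis=0) if is_precip else win.mean(axis=0)
    return {
        "annual_mean": annual,
        "max_quarter": windows.max(axis=0),
        "min_quarter": windows.min(axis=0),
        "annual_range": months.max(axis=0) - months.min(axis=0),
    }


def summaries_to_layerset(series_set: Sequence[MonthlySeries]) -> ClimateLayerSet:
    """Derive the seasonal-summary variables of every monthly series into one
    ClimateLayerSet with category/medium metadata attached."""
    variables = []
    grid = series_set[0].grid
    for series in series_set:
        category, medium = QUANTITY_META[series.quantity]
        for suffix, arr in derive_seasonal_summaries(series).items():
            var = ClimateVariable(
                name=f"{series.quantity}_{suffix}", category=category,
                medium=medium, units=series.units,
            )
            variables.append((var, arr))
    return ClimateLayerSet(grid=grid, variables=variables)


def select_variables(meta, habit: str, category: str = "all"):
    """Variables of one category, with soil-medium variables excluded for
    epiphytic species (included for terrestrial)."""
    if habit not in ("epiphytic", "terrestrial"):
        raise ValueError(f"unknown habit {habit!r}")
    selected = [
        v for v in meta
        if (category == "all" or v.category == category)
        and not (habit == "epiphytic" and v.medium == "soil")
    ]
    if not selected:
        raise ValueError(f"no variables for habit={habit!r}, category={category!r}")
    return selected


#: synthesized summary key -> (air-medium variable, soil-medium variable)
HABIT_SYNTHESIS = {
    "mat": ("air_temperature_annual_mean", "soil_temperature_annual_mean"),
    "temp_max_qtr": ("air_temperature_max_quarter", "soil_temperature_max_quarter"),
    "temp_min_qtr": ("air_temperature_min_quarter", "soil_temperature_min_quarter"),
    "temp_annual_range": ("air_temperature_annual_range", "soil_temperature_annual_range"),
    "water_input": ("precipitation_annual_mean", "soil_water_content_annual_mean"),
    "water_max_qtr": ("precipitation_max_quarter", "soil_water_content_max_quarter"),
    "water_min_qtr": ("precipitation_min_quarter", "soil_water_content_min_quarter"),
    "water_annual_range": ("precipitation_annual_range", "soil_water_content_annual_range"),
    "mapet": ("pet_annual_mean", "pet_annual_mean"),
    "pet_max_qtr": ("pet_max_quarter", "pet_max_quarter"),
    "pet_min_qtr": ("pet_min_quarter", "pet_min_quarter"),
    "pet_annual_range": ("pet_annual_range", "pet_annual_range"),
}


def synthesize_habit_environment(species_env: EnvSample, habit: str, warnings=None) -> dict:
    """Per-species habit-synthesized environment summary (mean over occurrences).

    Epiphytes draw each metric from air-medium layers, terrestrial species from
    soil-medium layers; a missing soil layer falls back to the corresponding
    air-medium (2-m height) variable with a logged warning.
    """
    if habit not in ("epiphytic", "terrestrial"):
        raise ValueError(f"unknown habit {habit!r}")
    names = [v.name for v in species_env.variable_meta]
    out = {}
    for key, (air_name, soil_name) in HABIT_SYNTHESIS.items():
        name = air_name if habit == "epiphytic" else soil_name
        if name not in names:
            if habit == "terrestrial" and air_name in names:
                if warnings is not None:
                    warnings.append(f"{key}: soil layer {soil_name} missing; using {air_name}")
                name = air_name
            else:
                continue
        out[key] = float(species_env.matrix[:, names.index(name)].mean())
    return out


# ---------------------------------------------------------------------------
# dimension reduction and polytope volumes
# ---------------------------------------------------------------------------

@dataclass
class PcaReduction:
    scores: np.ndarray  # (n, k)
    k: int
    cumvar_at_k: float
    explained_ratio: np.ndarray
    dropped_variables: list


def pca_reduce(sample: EnvSample, target_cumvar: float = 0.80) -> PcaReduction:
    """Standardize variables and keep the number of PC axes whose cumulative
    explained variance is closest to ``target_cumvar`` (ties toward fewer axes).

    Both life stages are reduced in one shared fit so the two volume estimates
    live in the same space.  Zero-variance variables are dropped (logged); an
    all-constant matrix is an error.
    """
    X = sample.matrix
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [sample.variable_meta[i].name for i in np.where(~keep)[0]]
    if not keep.any():
        raise ValueError("all variables have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k = int(np.argmin(np.abs(cum - target_cumvar))) + 1  # argmin takes the first (smaller k) on ties
    return PcaReduction(
        scores=u[:, :k] * s[:k],
        k=k,
        cumvar_at_k=float(cum[k - 1]),
        explained_ratio=ratio,
        dropped_variables=dropped,
    )


def hull_volume(points) -> tuple[float, bool]:
    """Exact convex-hull k-volume of an n x k point cloud.

    For k = 1 this is the interval length max − min.  Degenerate (affinely
    dependent) clouds return ``(0.0, True)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = pts.shape
    if k < 1:
        raise ValueError("need at least one dimension")
    if k == 1:
        if n == 0:
            return 0.0, True
        vol = float(pts.max() - pts.min())
        return vol, vol == 0.0
    if n < k + 1:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def points_in_hull(points, hull_points, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask: which ``points`` lie inside the convex hull of
    ``hull_points`` (facet half-space test; 1-D uses interval bounds)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hp = np.atleast_2d(np.asarray(hull_points, dtype=float))
    if pts.shape[1] == 1:
        lo, hi = hp.min(), hp.max()
        return (pts[:, 0] >= lo - tol) & (pts[:, 0] <= hi + tol)
    try:
        hull = ConvexHull(hp)
    except QhullError:
        return np.zeros(pts.shape[0], dtype=bool)
    a, b = hull.equations[:, :-1], hull.equations[:, -1]
    return (pts @ a.T + b <= tol).all(axis=1)


def point_in_hull_lp(point, hull_points, tol: float = 1e-8) -> bool:
    """Convex-combination membership test by LP feasibility.

    Works for affinely degenerate clouds (where Qhull cannot build a
    full-dimensional hull), which arise whenever variables are collinear.
    """
    v = np.asarray(point, dtype=float)
    A = np.asarray(hull_points, dtype=float)
    scale = np.maximum(np.abs(A).max(axis=0), 1.0)
    A_eq = np.vstack([(A / scale).T, np.ones(A.shape[0])])
    b_eq = np.concatenate([v / scale, [1.0]])
    res = linprog(
        c=np.zeros(A.shape[0]), A_eq=A_eq, b_eq=b_eq,
        bounds=(0, None), method="highs",
        options={"primal_feasibility_tolerance": tol},
    )
    return bool(res.status == 0)


def partition_climate_volume(all_scores, spor_scores, estimator: str = "convex_exact",
                             category: str = "all") -> ClimatePartition:
    """Partition the climate volume into sporophyte and gametophyte-only parts.

    ``s_env`` is the sporophyte hull volume; ``g_env = max(0, V_all − V_s)``.
    Any erroneous excess ``max(0, V_s − V_all)`` is recorded and subtracted —
    identically zero for the exact convex estimator (a hull can only grow when
    points are added) but retained as the correction hook for stochastic
    estimators.  When every row lies inside the sporophyte hull, ``g_env`` is
    snapped to exactly 0.
    """
    if estimator != "convex_exact":
        raise ValueError(f"unknown estimator {estimator!r}")
    all_pts = np.atleast_2d(np.asarray(all_scores, dtype=float))
    k = all_pts.shape[1]
    spor_pts = (np.atleast_2d(np.asarray(spor_scores, dtype=float))
                if len(spor_scores) else np.empty((0, k)))
    if spor_pts.shape[0] == 0:
        v_all, degen = hull_volume(all_pts)
        return ClimatePartition(g_env=v_all, s_env=0.0, erroneous_sporophyte_volume=0.0,
                                k_dims=k, category=category, degenerate=degen)
    # degeneracy policy: reduce dimensionality to what the smaller cloud supports
    k_eff = int(min(k, all_pts.shape[0] - 1, spor_pts.shape[0] - 1))
    if k_eff < 1:
        return ClimatePartition(g_env=0.0, s_env=0.0, erroneous_sporophyte_volume=0.0,
                                k_dims=0, category=category, degenerate=True)
    a, s = all_pts[:, :k_eff], spor_pts[:, :k_eff]
    v_all, degen_a = hull_volume(a)
    v_s, degen_s = hull_volume(s)
    nested = bool(points_in_hull(a, s).all()) if not degen_s else False
    err = max(0.0, v_s - v_all)
    g_env = 0.0 if nested else max(0.0, v_all - v_s - err)
    return ClimatePartition(g_env=g_env, s_env=v_s, erroneous_sporophyte_volume=err,
                            k_dims=k_eff, category=category,
                            degenerate=degen_a or degen_s)


def compute_cep(partition: ClimatePartition, as_percent: bool = False) -> float:
    """Climate expansion potential CEP = g_env / (g_env + s_env); a fully
    degenerate partition (zero total volume) yields 0."""
    total = partition.g_env + partition.s_env
    cep = 0.0 if total <= 0 else partition.g_env / total
    return 100.0 * cep if as_percent else cep


def per_variable_cep(sample: EnvSample) -> float:
    """Mean single-variable CEP over all variables.

    In one dimension the convex polytope is the range, so per variable
    cep_v = (R_all − R_spor) / R_all, with zero-range variables contributing 0.
    """
    if sample.stage_labels is None:
        raise ValueError("stage labels required")
    spor = sample.matrix[sample.stage_labels == "sporophyte"]
    if spor.shape[0] == 0 or sample.matrix.shape[0] == 0:
        raise ValueError("need at least one sporophyte and one record")
    r_all = sample.matrix.max(axis=0) - sample.matrix.min(axis=0)
    r_s = spor.max(axis=0) - spor.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cep_v = np.where(r_all > 0, (r_all - r_s) / np.where(r_all > 0, r_all, 1.0), 0.0)
    return float(cep_v.mean())


def cep_by_axis(sample: EnvSample, habit: str, target_cumvar: float = 0.80,
                estimator: str = "convex_exact") -> dict:
    """CEP overall and along each climate axis.

    For each of {all, temperature, water, temperature×water}: select the
    habit-appropriate variables, reduce to the closest-to-80% PC axes with
    both life stages pooled, and measure convex-hull volumes.  Returns a dict
    with keys ``cep_all``, ``cep_temperature``, ``cep_water``,
    ``cep_interaction`` plus the underlying partitions under ``partitions``.
    """
    if sample.stage_labels is None:
        raise ValueError("stage labels required")
    spor_mask = sample.stage_labels == "sporophyte"
    out, partitions = {}, {}
    keymap = {"all": "cep_all", "temperature": "cep_temperature",
              "water": "cep_water", "temperature_water": "cep_interaction"}
    for category, key in keymap.items():
        meta = select_variables(sample.variable_meta, habit, category)
        sub = sample.subset_variables(meta)
        red = pca_reduce(sub, target_cumvar=target_cumvar)
        part = partition_climate_volume(red.scores, red.scores[spor_mask],
                                        estimator=estimator, category=category)
        out[key] = compute_cep(part)
        partitions[category] = part
    out["partitions"] = partitions
    return out
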