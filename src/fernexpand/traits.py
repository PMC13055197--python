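"""Harmonization of published gametophyte ecophysiology.

Published photosynthesis measurements arrive in incompatible forms: spot
rates at 100 umol m-2 s-1 PAR, full light-response curves, rates per gram
chlorophyll instead of per gram dry mass, and O2 evolution instead of CO2
assimilation.  Desiccation rates (delta RWC per minute) from different
studies were measured at different atmospheric water potentials.  This
module standardizes everything to

* ``a_mass`` — CO2 assimilation per gram dry mass at 100 umol PAR, and
* ``delta_rwc`` — rate of relative-water-content loss (<= 0; less negative
  means more desiccation resistant),

then runs the phylogenetic trait~environment regression suite.

Light-response curves are fitted with the non-rectangular hyperbola

    A(Q) = [phi*Q + Amax - sqrt((phi*Q + Amax)^2 - 4*theta*phi*Q*Amax)]
           / (2*theta) - Rd

with quantum yield phi, convexity theta in (0, 1], and dark respiration Rd;
theta -> 0 recovers the rectangular (Michaelis-type) hyperbola.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .phylo import fit_phylo_lm, prune_tree

RATE_UNITS = ("co2_per_mass", "o2_per_mass", "co2_per_chlorophyll")


@dataclass
class LightResponseCurve:
    par: np.ndarray
    assimilation: np.ndarray
    rate_units: str = "co2_per_mass"
    species_id: str = ""

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.par, dtype=float))
        self.par = np.asarray(self.par, dtype=float)[order]
        self.assimilation = np.asarray(self.assimilation, dtype=float)[order]
        if self.rate_units not in RATE_UNITS:
            raise ValueError(f"rate_units must be one of {RATE_UNITS}")
        if (self.par < 0).any():
            raise ValueError("PAR values must be non-negative")
        if np.unique(self.par).size < 4:
            raise ValueError("need at least 4 distinct PAR levels")


@dataclass
class TraitRecord:
    species_id: str
    habit: str
    a_mass: float | None = None
    delta_rwc: float | None = None
    env: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habit not in ("epiphytic", "terrestrial"):
            raise ValueError("habit must be epiphytic or terrestrial")
        if self.a_mass is not None and self.a_mass < 0:
            raise ValueError("a_mass must be non-negative")
        if self.delta_rwc is not None and self.delta_rwc > 0:
            raise ValueError("delta_rwc must be <= 0")


class LightCurveFitError(RuntimeError):
    """Non-convergence; carries the best parameters found."""

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


def non_rectangular_hyperbola(par, a_max, quantum_yield, convexity, dark_respiration):
    """Net assimilation at photon flux ``par`` (vectorized)."""
    q = np.asarray(par, dtype=float)
    b = quantum_yield * q + a_max
    theta = convexity
    if theta < 1e-9:
        gross = quantum_yield * q * a_max / np.where(b > 0, b, 1.0)
    else:
        disc = np.clip(b * b - 4.0 * theta * quantum_yield * q * a_max, 0.0, None)
        gross = (b - np.sqrt(disc)) / (2.0 * theta)
    return gross - dark_respiration


def fit_light_response(curve: LightResponseCurve) -> dict:
    """Nonlinear least-squares fit of the non-rectangular hyperbola.

    Returns {a_max, quantum_yield, convexity, dark_respiration, sse};
    convexity is constrained to (0, 1].
    """
    q, a = curve.par, curve.assimilation
    if q.min() > 100 or q.max() < 100:
        raise ValueError("curve must span PAR levels below and above 100")
    a_max0 = max(a.max() - min(a.min(), 0.0), 0.1)
    rd0 = max(-a.min(), 0.01)
    bounds = ([1e-6, 1e-6, 1e-6, 0.0], [np.inf, 5.0, 1.0, np.inf])
    best = None
    # multistart over convexity and quantum yield: the SSE surface has local
    # minima along the theta/phi trade-off
    for theta0 in (0.3, 0.7, 0.95):
        for phi0 in (0.03, 0.05, 0.1):
            try:
                popt, _ = curve_fit(non_rectangular_hyperbola, q, a,
                                    p0=[a_max0, phi0, theta0, rd0],
                                    bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            resid = a - non_rectangular_hyperbola(q, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise LightCurveFitError(
            "light-response fit did not converge",
            params={"a_max": a_max0, "quantum_yield": 0.05, "convexity": 0.7,
                    "dark_respiration": rd0})
    sse, popt = best
    return {"a_max": float(popt[0]), "quantum_yield": float(popt[1]),
            "convexity": float(popt[2]), "dark_respiration": float(popt[3]),
            "sse": sse}


def a_at_par(params: dict, par: float = 100.0) -> float:
    """Evaluate the fitted model at ``par`` (default: the 100 umol standard)."""
    return float(non_rectangular_hyperbola(
        par, params["a_max"], params["quantum_yield"],
        params["convexity"], params["dark_respiration"]))


def convert_o2_to_co2(rate: float, photosynthetic_quotient: float = 1.0) -> float:
    """O2 evolution -> CO2 assimilation: rate_CO2 = rate_O2 / PQ."""
    if photosynthetic_quotient <= 0:
        raise ValueError("photosynthetic quotient must be positive")
    return rate / photosynthetic_quotient


def convert_chl_to_mass(rate_per_chl: float, chl_per_dry_mass: float) -> float:
    """Rate per g chlorophyll -> rate per g dry mass."""
    if chl_per_dry_mass is None or chl_per_dry_mass <= 0:
        raise ValueError("chl_per_dry_mass must be a positive configuration value")
    return rate_per_chl * chl_per_dry_mass


def cross_study_calibration(shared_species_rates) -> float:
    """Linear conversion factor between two studies' rates: the mean of
    rate_A / rate_B over shared species (e.g. the published 0.646 factor
    between the two desiccation-rate sources)."""
    pairs = list(shared_species_rates)
    if not pairs:
        raise ValueError("need at least one shared species")
    ratios = []
    for rate_a, rate_b in pairs:
        if rate_b == 0:
            raise ValueError("zero denominator rate in calibration pair")
        ratios.append(rate_a / rate_b)
    return float(np.mean(ratios))


def apply_calibration(rate: float, factor: float) -> float:
    return rate * factor


# ---------------------------------------------------------------------------
# trait ~ environment regression suite
# ---------------------------------------------------------------------------

#: default suite: (response, predictor, transform); log-transformed predictors
#: cover the monotonic-but-nonlinear water relationships
DEFAULT_SUITE = [
    ("a_mass", "water_input", "log"),
    ("a_mass", "water_max_qtr", "none"),
    ("a_mass", "water_min_qtr", "none"),
    ("a_mass", "mat", "none"),
    ("a_mass", "temp_max_qtr", "none"),
    ("a_mass", "temp_min_qtr", "none"),
    ("a_mass", "mapet", "none"),
    ("a_mass", "pet_max_qtr", "none"),
    ("a_mass", "pet_min_qtr", "none"),
    ("a_mass", "water_annual_range", "log"),
    ("a_mass", "temp_annual_range", "none"),
    ("a_mass", "pet_annual_range", "none"),
    ("delta_rwc", "a_mass", "none"),
]


def _trait_value(rec: TraitRecord, key: str):
    if key in ("a_mass", "delta_rwc"):
        return getattr(rec, key)
    return rec.env.get(key)


def run_trait_env_regressions(traits, tree, suite=None,
                              habit_factor: bool = False) -> pd.DataFrame:
    """Fit the phylogenetic regression suite; one row per (response,
    predictor) pair with slope, lambda, R^2, p and n.  Pairs with fewer than
    3 species carrying both variables are flagged ``fitted=False`` and the
    suite continues.  ``habit_factor`` adds growth habit (epiphytic vs
    terrestrial) as a 0/1 fixed factor."""
    suite = DEFAULT_SUITE if suite is None else suite
    rows = []
    for response, predictor, transform in suite:
        data = []
        for rec in traits:
            yv, xv = _trait_value(rec, response), _trait_value(rec, predictor)
            if yv is None or xv is None:
                continue
            if transform == "log":
                if xv <= 0:
                    continue
                xv = np.log(xv)
            elif transform != "none":
                raise ValueError(f"unknown transform {transform!r}")
            data.append((rec.species_id, float(yv), float(xv), rec.habit))
        base = {"response": response, "predictor": predictor, "transform": transform}
        if len(data) < 3:
            rows.append({**base, "fitted": False, "n": len(data)})
            continue
        species = [d[0] for d in data]
        y = np.array([d[1] for d in data])
        x = np.array([d[2] for d in data])
        try:
            pruned, _ = prune_tree(tree, species)
            if habit_factor:
                h = np.array([1.0 if d[3] == "epiphytic" else 0.0 for d in data])
                fit = fit_phylo_lm(y, np.column_stack([x, h]), pruned, labels=species)
            else:
                fit = fit_phylo_lm(y, x, pruned, labels=species)
        except ValueError as err:
            rows.append({**base, "fitted": False, "n": len(data), "error": str(err)})
            continue
        rows.append({**base, "fitted": True, "n": fit.n, "slope": fit.slope,
                     "intercept": fit.intercept, "lambda": fit.lam,
                     "r_squared": fit.r_squared, "p_value": fit.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def traits_to_frame(traits) -> pd.DataFrame:
    env_keys = sorted({k for t in traits for k in t.env})
    rows = []
    for t in traits:
        row = {"species": t.species_id, "habit": t.habit,
               "a_mass": t.a_mass, "delta_rwc": t.delta_rwc}
        row.update({k: t.env.get(k) for k in env_keys})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_traits(frame: pd.DataFrame):
    meta = {"species", "habit", "a_mass", "delta_rwc"}
    env_keys = [c for c in frame.columns if c not in meta]
    out = []
    for row in frame.to_dict("records"):
        env = {k: row[k] for k in env_keys if pd.notna(row[k])}
        out.append(TraitRecord(
            species_id=str(row["species"]), habit=str(row["habit"]),
            a_mass=None if pd.isna(row.get("a_mass")) else float(row["a_mass"]),
            delta_rwc=None if pd.isna(row.get("delta_rwc")) else float(row["delta_rwc"]),
            env=env))
    return out


def read_light_curves_csv(path):
    """Light-curve CSV (species, par, assimilation, rate_units) -> curves."""
    frame = pd.read_csv(path)
    curves = []
    for (species, units), grp in frame.groupby(["species", "rate_units"]):
        curves.append(LightResponseCurve(par=grp["par"].to_numpy(),
                                         assimilation=grp["assimilation"].to_numpy(),
                                         rate_units=str(units), species_id=str(species)))
    return curves
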