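"""End-to-end orchestration: QC -> GEP -> CEP by axis -> phylogenetic fits.

The pipeline runs per species, pools both life stages where the method
requires it (PCA, isolation forest), writes auditable intermediates, and
never lets one failing species stop the rest: failures are logged and the
species is excluded from the cross-species regressions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as cl
from . import geo, occurrences as occ, phylo, synthetic, traits as tr

logger = logging.getLogger("fernexpand")

CEP_FIELDS = {
    "all": "cep_percent",
    "temperature": "cep_temperature_percent",
    "water": "cep_water_percent",
    "temperature_water": "cep_interaction_percent",
}


@dataclass
class AnalysisConfig:
    """All analysis parameters with their published defaults."""

    buffer_radius_km: float = 1.0
    thinning_km: float = 1.0
    outlier_threshold: float = 0.75
    pca_target: float = 0.80
    dedup_precision: int = 4
    isolation_trees: int = 100
    categories: tuple = ("all", "temperature", "water", "temperature_water")
    habit_map: dict = field(default_factory=dict)  # species -> epiphytic|terrestrial
    photosynthetic_quotient: float = 1.0
    chl_per_dry_mass: float | None = None
    calibration_factor: float | None = None
    seed: int = 0
    out_dir: str | None = None
    # input paths (optional; in-memory data can be passed instead)
    occurrences_csv: str | None = None
    rasters_dir: str | None = None
    tree_newick: str | None = None
    traits_csv: str | None = None

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["categories"] = list(self.categories)
        return d


def analyze_species(species_id, records, layers, habit, config: AnalysisConfig):
    """QC one species and compute its GEP and every CEP flavour."""
    cleaned, report = occ.run_qc(
        records, env_layers=layers,
        dedup_precision=config.dedup_precision, thin_km=config.thinning_km,
        outlier_threshold=config.outlier_threshold,
        n_trees=config.isolation_trees, seed=config.seed)
    gam_pts = [(r.longitude, r.latitude) for r in cleaned if r.life_stage == "gametophyte"]
    spor_pts = [(r.longitude, r.latitude) for r in cleaned if r.life_stage == "sporophyte"]
    if not gam_pts and not spor_pts:
        raise ValueError("no records survived QC")
    part = geo.partition_geographic_area(gam_pts, spor_pts, radius_km=config.buffer_radius_km)
    gep = geo.compute_gep(part, as_percent=True)

    pts = [(r.longitude, r.latitude) for r in cleaned]
    stages = [r.life_stage for r in cleaned]
    sample = cl.extract_env(pts, layers, stage_labels=stages)
    ceps = cl.cep_by_axis(sample, habit, target_cumvar=config.pca_target)
    pv = cl.per_variable_cep(sample.subset_variables(
        cl.select_variables(sample.variable_meta, habit, "all")))
    result = cl.ExpansionResult(
        species_id=species_id, habit=habit,
        gep_percent=gep,
        cep_percent=100.0 * ceps["cep_all"],
        cep_temperature_percent=100.0 * ceps["cep_temperature"],
        cep_water_percent=100.0 * ceps["cep_water"],
        cep_interaction_percent=100.0 * ceps["cep_interaction"],
        per_variable_mean_cep_percent=100.0 * pv,
        n_gam=len(gam_pts), n_spor=len(spor_pts),
    )
    return result, report, ceps["partitions"]


def run_expansion_pipeline(config: AnalysisConfig, *, records_by_species=None,
                           layers=None, tree=None):
    """Per-species QC + GEP + CEP, then the GEP~CEP phylogenetic RMA for each
    CEP flavour.  Inputs come from ``config`` paths unless passed in memory.

    Returns a dict with the per-species results table, the fits, the QC
    reports, and a run manifest; intermediates are written when
    ``config.out_dir`` is set.
    """
    if records_by_species is None:
        recs = occ.read_occurrences_csv(config.occurrences_csv)
        records_by_species = {}
        for r in recs:
            records_by_species.setdefault(r.species_id, []).append(r)
    if layers is None:
        layers = cl.ClimateLayerSet.from_dir(config.rasters_dir)
    if tree is None and config.tree_newick is not None:
        tree = phylo.read_newick(config.tree_newick)
    if len(records_by_species) < 3:
        raise ValueError("need at least 3 species")

    results, reports, failures = [], {}, {}
    for sp in sorted(records_by_species):
        habit = config.habit_map.get(sp, "terrestrial")
        try:
            result, report, _ = analyze_species(sp, records_by_species[sp],
                                                layers, habit, config)
            results.append(result)
            reports[sp] = report
        except (ValueError, RuntimeError) as err:
            failures[sp] = str(err)
            logger.warning("species %s failed: %s", sp, err)

    fits = {}
    if tree is not None:
        for cat, fld in CEP_FIELDS.items():
            if cat not in config.categories:
                continue
            try:
                fit, used = phylo.regress_gep_cep(results, tree, cep_field=fld)
                fits[cat] = {"fit": fit, "species": used}
            except ValueError as err:
                fits[cat] = {"error": str(err)}

    table = pd.DataFrame([dataclasses.asdict(r) for r in results])
    out = {"results": results, "table": table, "fits": fits,
           "qc_reports": reports, "failures": failures,
           "manifest": {"parameters": config.manifest(), "n_species": len(results)}}
    if config.out_dir:
        _write_expansion_outputs(out, config)
    return out


def _write_expansion_outputs(out, config):
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out["table"].round(2).to_csv(outdir / "expansion_results.csv", index=False)
    fits_json = {}
    for cat, payload in out["fits"].items():
        if "fit" in payload:
            fits_json[cat] = {**dataclasses.asdict(payload["fit"]),
                              "species": payload["species"]}
        else:
            fits_json[cat] = payload
    (outdir / "gep_cep_fits.json").write_text(json.dumps(fits_json, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(out["manifest"], indent=1))
    qc = {sp: dataclasses.asdict(rep) for sp, rep in out["qc_reports"].items()}
    (outdir / "qc_reports.json").write_text(json.dumps(qc, indent=1))


def harmonize_traits(trait_records=None, light_curves=None, config=None):
    """Attach light-curve-standardized a_mass values to trait records.

    Curves are fitted and evaluated at 100 umol PAR; O2-based and
    chlorophyll-based rates are converted with the configured constants; an
    optional cross-study calibration factor rescales desiccation rates.
    """
    config = config or AnalysisConfig()
    traits_by_sp = {t.species_id: t for t in (trait_records or [])}
    for curve in light_curves or []:
        params = tr.fit_light_response(curve)
        a100 = tr.a_at_par(params, 100.0)
        if curve.rate_units == "o2_per_mass":
            a100 = tr.convert_o2_to_co2(a100, config.photosynthetic_quotient)
        elif curve.rate_units == "co2_per_chlorophyll":
            a100 = tr.convert_chl_to_mass(a100, config.chl_per_dry_mass)
        rec = traits_by_sp.get(curve.species_id)
        if rec is None:
            continue
        rec.a_mass = max(float(a100), 0.0)
    if config.calibration_factor is not None:
        for rec in traits_by_sp.values():
            if rec.delta_rwc is not None:
                rec.delta_rwc = tr.apply_calibration(rec.delta_rwc,
                                                     config.calibration_factor)
    return list(traits_by_sp.values())


def run_trait_pipeline(config: AnalysisConfig, *, trait_records=None,
                       light_curves=None, tree=None, suite=None):
    """Harmonization followed by the trait~environment regression suite."""
    if trait_records is None:
        trait_records = tr.frame_to_traits(pd.read_csv(config.traits_csv))
    if tree is None and config.tree_newick is not None:
        tree = phylo.read_newick(config.tree_newick)
    trait_records = harmonize_traits(trait_records, light_curves, config)
    table = tr.run_trait_env_regressions(trait_records, tree, suite=suite)
    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "trait_regressions.csv", index=False)
    return table


def run_scenario(scenario: synthetic.SyntheticScenario, config: AnalysisConfig | None = None):
    """Simulate a scenario and run the expansion pipeline on it."""
    config = config or AnalysisConfig(seed=scenario.seed)
    data = synthetic.simulate_scenario_dataset(scenario)
    config.habit_map = dict(data["habits"])
    out = run_expansion_pipeline(config, records_by_species=data["records"],
                                 layers=data["climate"].summaries, tree=data["tree"])
    out["ground_truth"] = data["ground_truth"]
    return out
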