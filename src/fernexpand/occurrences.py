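"""Occurrence-record cleaning for two-stage (gametophyte/sporophyte) datasets.

The multistep QC procedure, in fixed order:

1. basis-of-record filter — database records are kept only when their basis
   matches the accepted set (preserved specimens by default); literature
   records are exempt;
2. deduplication on (species, life stage, rounded coordinates);
3. spatial thinning to a minimum pairwise great-circle distance (~1 km),
   greedy in input order so results are deterministic;
4. environmental-outlier removal with an isolation forest per species (both
   life stages pooled), dropping records whose anomaly score is strictly
   greater than 0.75.

An optional on-land check against a boolean grid can precede the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .climate import ClimateLayerSet, EnvSample, extract_env
from .geo import great_circle_km

LIFE_STAGES = ("gametophyte", "sporophyte")
SOURCES = ("literature", "database")

#: canonical accepted basis-of-record designations (normalized form)
DEFAULT_ACCEPTED_BASIS = frozenset({"preservedspecimen"})


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced observation of one life stage of one species."""

    species_id: str
    life_stage: str
    longitude: float
    latitude: float
    basis_of_record: str = ""
    source: str = "database"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"life_stage must be one of {LIFE_STAGES}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError("longitude out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")


@dataclass
class QcReport:
    """Record counts and removals per QC step (counts are non-increasing)."""

    n_input: int = 0
    n_after_basis_filter: int = 0
    n_after_dedup: int = 0
    n_after_thinning: int = 0
    n_after_outlier_removal: int = 0
    removed_ids: dict = field(default_factory=dict)

    def validate(self) -> None:
        counts = [self.n_input, self.n_after_basis_filter, self.n_after_dedup,
                  self.n_after_thinning, self.n_after_outlier_removal]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("QC counts must be non-increasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _normalize_basis(basis: str) -> str:
    return "".join(ch for ch in basis.lower() if ch.isalnum())


def filter_basis_of_record(records, accepted=DEFAULT_ACCEPTED_BASIS, removed=None):
    """Keep database records whose basis-of-record is in ``accepted``
    (case/punctuation-insensitive); literature records pass through.  A
    database record with a missing basis is removed (and logged)."""
    accepted = {_normalize_basis(b) for b in accepted}
    kept = []
    for idx, rec in enumerate(records):
        if rec.source == "literature" or _normalize_basis(rec.basis_of_record) in accepted:
            kept.append(rec)
        elif removed is not None:
            removed.append(idx)
    return kept


def deduplicate(records, precision: int = 4, removed=None):
    """At most one record per (species, life stage, coordinates rounded to
    ``precision`` decimal degrees); first occurrence wins."""
    seen, kept = set(), []
    for idx, rec in enumerate(records):
        key = (rec.species_id, rec.life_stage,
               round(rec.longitude, precision), round(rec.latitude, precision))
        if key in seen:
            if removed is not None:
                removed.append(idx)
        else:
            seen.add(key)
            kept.append(rec)
    return kept


def thin_occurrences(records, min_distance_km: float = 1.0, removed=None):
    """Greedy spatial thinning: keep a record iff it is at least
    ``min_distance_km`` (great-circle) from every record already kept.
    First-seen retention in input order makes the result deterministic."""
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    kept, kept_lon, kept_lat = [], [], []
    for idx, rec in enumerate(records):
        if kept:
            d = great_circle_km(np.array(kept_lon), np.array(kept_lat),
                                rec.longitude, rec.latitude)
            if (d < min_distance_km).any():
                if removed is not None:
                    removed.append(idx)
                continue
        kept.append(rec)
        kept_lon.append(rec.longitude)
        kept_lat.append(rec.latitude)
    return kept


def isolation_forest_scores(env_matrix, n_trees: int = 100, subsample=None,
                            seed: int = 0) -> np.ndarray:
    """Isolation-forest anomaly score per row, in (0, 1).

    The score is the standard s(x) = 2^(−E[h(x)]/c(ψ)) with the average-path-
    length normalizer c(ψ); 0 means hard to isolate (typical), 1 means very
    easy to isolate (anomalous).  Seeded and reproducible.
    """
    X = env_matrix.matrix if isinstance(env_matrix, EnvSample) else np.atleast_2d(np.asarray(env_matrix, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("insufficient data for outlier model (need >= 2 rows)")
    if subsample is None:
        subsample = min(256, n)
    forest = IsolationForest(n_estimators=n_trees, max_samples=subsample,
                             random_state=seed)
    forest.fit(X)
    # sklearn's score_samples is the negated anomaly score of the original formulation
    return -forest.score_samples(X)


def flag_outliers(scores, threshold: float = 0.75) -> np.ndarray:
    """True (remove) exactly where score > threshold; ties are retained."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(scores, dtype=float) > threshold


def validate_on_land(records, grid, land_mask, removed=None):
    """Keep records whose nearest cell in ``land_mask`` (boolean array on
    ``grid``) is land; records on water/nodata cells or outside the grid are
    removed and logged with a reason."""
    land = np.asarray(land_mask)
    kept = []
    for idx, rec in enumerate(records):
        i, j, inside = grid.index_of(rec.longitude, rec.latitude)
        if not inside:
            if removed is not None:
                removed.append((idx, "outside grid"))
            continue
        cell = float(land[int(i), int(j)])
        if np.isnan(cell) or cell == 0.0:
            if removed is not None:
                removed.append((idx, "water or nodata"))
            continue
        kept.append(rec)
    return kept


def run_qc(records, env_layers: ClimateLayerSet | None = None, *,
           accepted_basis=DEFAULT_ACCEPTED_BASIS, dedup_precision: int = 4,
           thin_km: float = 1.0, outlier_threshold: float = 0.75,
           n_trees: int = 100, seed: int = 0):
    """Full per-species QC pipeline; returns ``(records, QcReport)``.

    ``records`` should belong to one species.  Thinning runs per life stage;
    the isolation forest pools both stages of the species (conservative
    reading of the per-species outlier screen) and requires ``env_layers``.
    """
    report = QcReport(n_input=len(records), removed_ids={})

    removed = []
    records = filter_basis_of_record(records, accepted=accepted_basis, removed=removed)
    report.n_after_basis_filter = len(records)
    report.removed_ids["basis_filter"] = removed

    removed = []
    records = deduplicate(records, precision=dedup_precision, removed=removed)
    report.n_after_dedup = len(records)
    report.removed_ids["dedup"] = removed

    thinned, removed = [], []
    for stage in LIFE_STAGES:
        idx_stage = [i for i, r in enumerate(records) if r.life_stage == stage]
        stage_removed = []
        kept = thin_occurrences([records[i] for i in idx_stage],
                                min_distance_km=thin_km, removed=stage_removed)
        thinned.extend(kept)
        removed.extend(idx_stage[i] for i in stage_removed)
    records = thinned
    report.n_after_thinning = len(records)
    report.removed_ids["thinning"] = removed

    removed = []
    if env_layers is not None and len(records) >= 2:
        pts = [(r.longitude, r.latitude) for r in records]
        sample = extract_env(pts, env_layers)
        scores = isolation_forest_scores(sample, n_trees=n_trees, seed=seed)
        drop_rows = set(np.asarray(sample.kept_rows)[flag_outliers(scores, outlier_threshold)])
        drop_rows |= {i for i, _ in sample.dropped_rows}  # no-environment rows cannot be screened
        removed = sorted(drop_rows)
        records = [r for i, r in enumerate(records) if i not in drop_rows]
    report.n_after_outlier_removal = len(records)
    report.removed_ids["outlier_removal"] = removed

    report.validate()
    return records, report


# ---------------------------------------------------------------------------
# CSV interface (Darwin-Core-style columns)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["species", "lifeStage", "decimalLongitude", "decimalLatitude",
               "basisOfRecord", "source"]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.species_id, r.life_stage, r.longitude, r.latitude,
          r.basis_of_record, r.source) for r in records],
        columns=CSV_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame):
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    return [
        OccurrenceRecord(
            species_id=str(row.species), life_stage=str(row.lifeStage),
            longitude=float(row.decimalLongitude), latitude=float(row.decimalLatitude),
            basis_of_record="" if pd.isna(row.basisOfRecord) else str(row.basisOfRecord),
            source=str(row.source),
        )
        for row in frame.itertuples(index=False)
    ]


def read_occurrences_csv(path):
    return frame_to_records(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def write_occurrences_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)
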