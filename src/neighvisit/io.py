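"""CSV / JSON / GeoJSON readers and writers for the pipeline tables.

Dialect: RFC-4180 comma-separated with a header row, UTF-8.  JSON
artifacts are written with sorted keys so reruns diff byte-for-byte.
Underscore-prefixed columns (latent generator state) are never written.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import DEMOGRAPHIC_COLUMNS, MEASURE_COLUMNS
from .errors import ReferentialIntegrityError, SchemaError

TRACT_REQUIRED = ("tract_id", "x", "y", "population", "device_count")
POI_REQUIRED = ("poi_id", "category", "x", "y")
VISIT_REQUIRED = ("tract_id", "poi_id", "recorded_count")


def _public(frame: pd.DataFrame) -> pd.DataFrame:
    return frame[[c for c in frame.columns if not c.startswith("_")]]


def write_tracts(tracts: pd.DataFrame, path: Path) -> None:
    _public(tracts).to_csv(path, index=False, float_format="%.17g")


def write_pois(pois: pd.DataFrame, path: Path) -> None:
    pois.to_csv(path, index=False, float_format="%.17g")


def write_visits(visits: pd.DataFrame, path: Path, include_true: bool = False) -> None:
    cols = list(VISIT_REQUIRED) + (["true_count"] if include_true else [])
    visits[[c for c in cols if c in visits.columns]].to_csv(path, index=False, float_format="%.17g")


def write_measures(measures: pd.DataFrame, path: Path) -> None:
    measures.to_csv(path, index=False, float_format="%.17g")


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_centroids_geojson(tracts: pd.DataFrame, path: Path) -> None:
    """Tract centroids as a GeoJSON Point feature collection (planar x/y,
    no CRS)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {"tract_id": r.tract_id},
        }
        for r in tracts.itertuples()
    ]
    write_json({"type": "FeatureCollection", "features": features}, path)


def _require(frame: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} missing column(s): {', '.join(missing)}")


def read_tables(
    tracts_path: Path, pois_path: Path, visits_path: Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three input tables with referential integrity."""
    tracts = pd.read_csv(tracts_path, float_precision="round_trip")
    pois = pd.read_csv(pois_path, float_precision="round_trip")
    visits = pd.read_csv(visits_path, float_precision="round_trip")
    _require(tracts, TRACT_REQUIRED, str(tracts_path))
    _require(pois, POI_REQUIRED, str(pois_path))
    _require(visits, VISIT_REQUIRED, str(visits_path))
    if tracts["tract_id"].duplicated().any():
        raise SchemaError("duplicate tract_id values")
    if pois["poi_id"].duplicated().any():
        raise SchemaError("duplicate poi_id values")
    bad_tract = set(visits["tract_id"]) - set(tracts["tract_id"])
    if bad_tract:
        raise ReferentialIntegrityError(
            f"visits reference unknown tract_id(s): {sorted(bad_tract)[:5]}"
        )
    bad_poi = set(visits["poi_id"]) - set(pois["poi_id"])
    if bad_poi:
        raise ReferentialIntegrityError(
            f"visits reference unknown poi_id(s): {sorted(bad_poi)[:5]}"
        )
    return tracts, pois, visits


def read_measures(path: Path) -> pd.DataFrame:
    measures = pd.read_csv(path, float_precision="round_trip")
    _require(measures, ("tract_id", *MEASURE_COLUMNS), str(path))
    return measures


def demographic_columns_present(tracts: pd.DataFrame) -> list[str]:
    return [c for c in DEMOGRAPHIC_COLUMNS if c in tracts.columns]
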