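"""CSV and GeoJSON readers/writers for event tables and area polygons.

Events travel as plain CSV with ISO-8601 dates; areas as GeoJSON
FeatureCollections whose properties carry the attribute columns.  Geometry
round-trips through shapely.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

EVENT_REQUIRED = ["event_id", "occurrence_date", "report_date", "district_id"]


def write_events_csv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for c in ("occurrence_date", "report_date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_events_csv(path, required=EVENT_REQUIRED) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV missing mandatory columns: {missing}")
    for c in ("occurrence_date", "report_date"):
        parsed = pd.to_datetime(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            logger.warning(
                "%s: %d malformed %s values at rows %s (dropped)",
                path, int(bad.sum()), c, list(df.index[bad][:5]),
            )
        df[c] = parsed
    n0 = len(df)
    df = df.dropna(subset=["occurrence_date", "report_date"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("read_events_csv: dropped %d malformed rows", n0 - len(df))
    return df


def write_areas_geojson(frame: pd.DataFrame, path, id_col: str) -> None:
    features = []
    for _, row in frame.iterrows():
        props = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in row.items()
            if k != "geometry"
        }
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(row["geometry"])}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_areas_geojson(path, id_col: str) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        props = dict(feat["properties"])
        geom = shape(feat["geometry"])
        if not geom.is_valid or geom.is_empty:
            raise ValueError(
                f"invalid polygon for feature {id_col}={props.get(id_col)!r} in {path}"
            )
        props["geometry"] = geom
        rows.append(props)
    df = pd.DataFrame(rows)
    if id_col not in df.columns:
        raise ValueError(f"GeoJSON {path} lacks the id property {id_col!r}")
    return df
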