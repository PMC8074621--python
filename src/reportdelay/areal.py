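"""Population-weighted areal aggregation of tract attributes onto districts.

Census tracts and police districts are independent partitions of a city.
Assuming population is uniform within a tract, the population of a
tract/district intersection is the tract population times the intersected
area fraction.  District attribute values are then population-weighted
averages of the contributing tracts (intensive attributes) or
area-apportioned sums (extensive attributes such as total population).

All geometry is computed in the supplied planar coordinates; callers with
lon/lat data must project to an equal-area-safe CRS first.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import STRtree

logger = logging.getLogger(__name__)

#: attributes that are totals (area-apportioned then summed); everything
#: else is treated as intensive (population-proportion weighted average)
EXTENSIVE_ATTRIBUTES = frozenset({"pop.total", "occ.units"})

#: intersections below this area fraction are boundary slivers and dropped
MIN_AREA_FRACTION = 1e-9


def _check_polygons(frame: pd.DataFrame, id_col: str) -> None:
    for uid, geom in zip(frame[id_col], frame["geometry"]):
        if geom is None or geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid or empty polygon for {id_col}={uid!r}")


def intersection_weights(tracts: pd.DataFrame, districts: pd.DataFrame) -> pd.DataFrame:
    """Tract-by-district intersection table.

    Columns: tract_id, district_id, ``area_fraction`` (share of the tract's
    area inside the district; sums to 1 over districts for tracts fully
    covered), ``pop_share`` (estimated persons in the intersection) and
    ``pop_prop`` (share of the district's population contributed by the
    tract; sums to 1 per district).  Zero-intersection pairs are omitted;
    districts with zero estimated population are flagged and carry NaN
    ``pop_prop``.
    """
    _check_polygons(tracts, "tract_id")
    _check_polygons(districts, "district_id")
    dist_geoms = list(districts["geometry"])
    tree = STRtree(dist_geoms)
    rows = []
    for tract_id, geom, pop in zip(
        tracts["tract_id"], tracts["geometry"], tracts["pop.total"]
    ):
        if pop < 0:
            raise ValueError(f"negative population for tract {tract_id!r}")
        area = geom.area
        for j in tree.query(geom, predicate="intersects"):
            inter = geom.intersection(dist_geoms[j])
            frac = inter.area / area
            if frac < MIN_AREA_FRACTION:
                continue
            rows.append(
                (tract_id, districts["district_id"].iloc[j], frac, frac * pop)
            )
    w = pd.DataFrame(rows, columns=["tract_id", "district_id", "area_fraction", "pop_share"])
    district_pop = w.groupby("district_id")["pop_share"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        w["pop_prop"] = np.where(district_pop > 0, w["pop_share"] / district_pop, np.nan)
    empty = w.loc[district_pop == 0, "district_id"].unique()
    if len(empty):
        logger.warning("districts with zero estimated population: %r", list(empty))
    return w


def aggregate_attributes(
    tracts: pd.DataFrame,
    weights: pd.DataFrame,
    attributes: Sequence[str] | None = None,
    extensive: frozenset = EXTENSIVE_ATTRIBUTES,
) -> pd.DataFrame:
    """District attribute table from tract attributes and intersection weights.

    Intensive attributes (rates, medians, averages) are population-proportion
    weighted means; extensive attributes are area-apportioned sums, so that
    e.g. total population is conserved when districts tile the tracts.
    """
    if attributes is None:
        attributes = [
            c for c in tracts.columns if c not in ("tract_id", "geometry")
        ]
    attr = tracts.set_index("tract_id")[list(attributes)]
    if attr.isna().any().any():
        bad = attr.columns[attr.isna().any()].tolist()
        raise ValueError(f"missing attribute values in tracts: {bad}")
    merged = weights.merge(attr, left_on="tract_id", right_index=True, how="left")
    out = {}
    for col in attributes:
        weight = merged["area_fraction"] if col in extensive else merged["pop_prop"]
        contrib = merged[col] * weight
        summed = contrib.groupby(merged["district_id"]).sum()
        out[col] = summed
    return pd.DataFrame(out).rename_axis("district_id")


def locate_points(xs, ys, tracts: pd.DataFrame):
    """Containing tract id for each point; boundary ties go to the smallest
    tract id so assignment is deterministic.  A point outside every tract is
    an error (its coordinates are logged)."""
    from shapely import points as mk_points

    geoms = list(tracts["geometry"])
    ids = tracts["tract_id"].to_numpy()
    tree = STRtree(geoms)
    pts = mk_points(np.column_stack([np.asarray(xs), np.asarray(ys)]))
    q_pt, q_geom = tree.query(pts, predicate="intersects")
    assigned = np.full(len(pts), -1, dtype=object)
    # iterate in reverse-sorted tract-id order so the smallest id wins ties
    order = np.argsort([ids[g] for g in q_geom])[::-1]
    for row in order:
        assigned[q_pt[row]] = ids[q_geom[row]]
    missing = [i for i, a in enumerate(assigned) if a == -1]
    if missing:
        coords = [(float(pts[i].x), float(pts[i].y)) for i in missing[:5]]
        logger.error("points outside all tracts, first offenders: %r", coords)
        raise ValueError(f"{len(missing)} points fall outside every tract")
    return assigned


def event_context(
    events: pd.DataFrame,
    tracts: pd.DataFrame,
    district_attributes: pd.DataFrame,
    regime: str,
    attributes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Areal covariates for each event.

    Under the point regime the event inherits the raw attributes of the
    census tract containing its coordinates; under the centroid regime
    (district-level locations only) it inherits the district's aggregated
    attribute vector.
    """
    if attributes is None:
        attributes = [c for c in tracts.columns if c not in ("tract_id", "geometry")]
    if regime == "point":
        tract_ids = locate_points(events["lon"], events["lat"], tracts)
        attr = tracts.set_index("tract_id")[list(attributes)]
        out = attr.loc[list(tract_ids)].reset_index(drop=True)
    elif regime == "district_centroid":
        out = district_attributes.loc[
            events["district_id"], list(attributes)
        ].reset_index(drop=True)
    else:
        raise ValueError(f"unknown coordinate regime {regime!r}")
    out.index = events.index
    return out
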