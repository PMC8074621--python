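import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import reportdelay as rd
from reportdelay import areal


def make_districts_2x2():
    # four 1.5x1.5 districts over the 3x3 tract grid -> tracts split
    geoms = [
        box(0, 0, 1.5, 1.5), box(1.5, 0, 3, 1.5),
        box(0, 1.5, 1.5, 3), box(1.5, 1.5, 3, 3),
    ]
    return pd.DataFrame({"district_id": np.arange(4), "geometry": geoms})


def test_containment_and_split_fractions(unit_grid):
    unit_grid["pop.total"] = 100.0
    districts = make_districts_2x2()
    w = areal.intersection_weights(unit_grid, districts)
    # corner tract 0 lies wholly inside district 0
    w0 = w[(w.tract_id == 0) & (w.district_id == 0)]
    assert np.isclose(w0["area_fraction"].iloc[0], 1.0)
    # edge tract 1 (x in [1,2]) is split in half by the district boundary
    w1 = w[w.tract_id == 1].set_index("district_id")["area_fraction"]
    assert np.allclose(sorted(w1), [0.5, 0.5])
    # centre tract 4 is split in four quarters
    w4 = w[w.tract_id == 4]["area_fraction"]
    assert np.allclose(sorted(w4), [0.25] * 4)
    # per-tract area fractions always sum to 1 under exact covering
    sums = w.groupby("tract_id")["area_fraction"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    # per-district population proportions sum to 1
    psums = w.groupby("district_id")["pop_prop"].sum()
    assert np.allclose(psums, 1.0, atol=1e-9)


def test_population_proportion_ratio():
    tracts = pd.DataFrame(
        {
            "tract_id": [0, 1],
            "geometry": [box(0, 0, 1, 1), box(1, 0, 2, 1)],
            "pop.total": [100.0, 300.0],
        }
    )
    districts = pd.DataFrame({"district_id": [0], "geometry": [box(0, 0, 2, 1)]})
    w = areal.intersection_weights(tracts, districts)
    props = w.set_index("tract_id")["pop_prop"]
    assert np.isclose(props[0], 0.25) and np.isclose(props[1], 0.75)


def test_aggregation_identities(unit_grid):
    rng = np.random.default_rng(0)
    unit_grid["pop.total"] = rng.uniform(50, 500, len(unit_grid)).round()
    unit_grid["poverty"] = rng.uniform(5, 40, len(unit_grid))
    unit_grid["constant"] = 7.5
    districts = make_districts_2x2()
    w = areal.intersection_weights(unit_grid, districts)
    agg = areal.aggregate_attributes(unit_grid, w)
    # constant intensive attribute is invariant (convex combination)
    assert np.allclose(agg["constant"], 7.5, atol=1e-9)
    # extensive attribute conserved in total
    assert np.isclose(agg["pop.total"].sum(), unit_grid["pop.total"].sum(), atol=1e-9)
    # equal-population tracts average their intensive values
    t2 = pd.DataFrame(
        {
            "tract_id": [0, 1],
            "geometry": [box(0, 0, 1, 1), box(1, 0, 2, 1)],
            "pop.total": [200.0, 200.0],
            "poverty": [10.0, 30.0],
        }
    )
    d2 = pd.DataFrame({"district_id": [0], "geometry": [box(0, 0, 2, 1)]})
    agg2 = areal.aggregate_attributes(t2, areal.intersection_weights(t2, d2))
    assert np.isclose(agg2.loc[0, "poverty"], 20.0)


def test_identity_when_districts_equal_tracts(unit_grid):
    rng = np.random.default_rng(1)
    unit_grid["pop.total"] = rng.uniform(100, 1000, len(unit_grid)).round()
    unit_grid["med.income"] = rng.uniform(3e4, 9e4, len(unit_grid))
    same = unit_grid.rename(columns={"tract_id": "district_id"})[
        ["district_id", "geometry"]
    ]
    w = areal.intersection_weights(unit_grid, same)
    agg = areal.aggregate_attributes(unit_grid, w)
    ref = unit_grid.set_index("tract_id")[["pop.total", "med.income"]]
    assert np.allclose(agg.sort_index(), ref.sort_index(), atol=1e-9)


def test_missing_attribute_errors(unit_grid):
    unit_grid["pop.total"] = 100.0
    unit_grid["poverty"] = np.nan
    districts = make_districts_2x2()
    w = areal.intersection_weights(unit_grid, districts)
    with pytest.raises(ValueError, match="poverty"):
        areal.aggregate_attributes(unit_grid, w)


def test_invalid_polygon_named():
    from shapely.geometry import Polygon

    bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
    tracts = pd.DataFrame(
        {"tract_id": ["bad"], "geometry": [bowtie], "pop.total": [1.0]}
    )
    districts = pd.DataFrame({"district_id": [0], "geometry": [box(0, 0, 1, 1)]})
    with pytest.raises(ValueError, match="bad"):
        areal.intersection_weights(tracts, districts)


def test_event_context_point_and_centroid(unit_grid):
    unit_grid["poverty"] = np.arange(9, dtype=float)
    events = pd.DataFrame(
        {"lon": [0.5, 2.5], "lat": [0.5, 2.5], "district_id": [0, 3]}
    )
    ctx = areal.event_context(events, unit_grid, None, "point")
    assert list(ctx["poverty"]) == [0.0, 8.0]
    district_attrs = pd.DataFrame({"poverty": [1.0, 2.0, 3.0, 4.0]}, index=range(4))
    district_attrs.index.name = "district_id"
    ctx2 = areal.event_context(events, unit_grid, district_attrs, "district_centroid")
    assert list(ctx2["poverty"]) == [1.0, 4.0]
    with pytest.raises(ValueError):
        areal.event_context(
            pd.DataFrame({"lon": [99.0], "lat": [99.0]}), unit_grid, None, "point"
        )


def test_boundary_point_goes_to_smallest_tract_id(unit_grid):
    unit_grid["poverty"] = np.arange(9, dtype=float)
    # (1.0, 0.5) lies on the shared edge of tracts 0 and 1: both contain it
    assert unit_grid.geometry[0].intersects(unit_grid.geometry[1])
    ids = areal.locate_points([1.0], [0.5], unit_grid)
    assert ids[0] == 0


def test_conservation_on_random_tilings():
    rng = np.random.default_rng(42)
    cfg = rd.ScenarioConfig(n_events=10, grid_tracts=(6, 4), district_factor=2, seed=3)
    tracts, districts = rd.synth.generate_areas(cfg)
    w = areal.intersection_weights(tracts, districts)
    # sum of intersection areas equals each tract's area (geometry oracle)
    for tid, geom in zip(tracts.tract_id, tracts.geometry):
        pieces = w[w.tract_id == tid]
        inter_area = sum(
            geom.intersection(
                districts.set_index("district_id").geometry[d]
            ).area
            for d in pieces.district_id
        )
        assert np.isclose(inter_area, geom.area, atol=1e-9)
    total = w["pop_share"].sum()
    assert np.isclose(total, tracts["pop.total"].sum(), atol=1e-6)
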