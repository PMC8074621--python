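"""Population-weighted aggregation of tract attributes onto districts.

Computes the tract-by-district intersection-weight table and the district
attribute table for the spatial scenario, and checks the conservation
identities (area fractions and population proportions sum to one; total
population conserved).
"""

from pathlib import Path

import numpy as np

from reportdelay import areal, io

OUT = Path("results/tables")
OUT.mkdir(parents=True, exist_ok=True)

tracts = io.read_areas_geojson("results/data/spatial_tracts.geojson", "tract_id")
districts = io.read_areas_geojson("results/data/spatial_districts.geojson", "district_id")

w = areal.intersection_weights(tracts, districts)
agg = areal.aggregate_attributes(tracts, w)
w.to_csv(OUT / "intersection_weights.csv", index=False)
agg.to_csv(OUT / "district_attributes.csv")

frac_err = (w.groupby("tract_id")["area_fraction"].sum() - 1).abs().max()
prop_err = (w.groupby("district_id")["pop_prop"].sum() - 1).abs().max()
pop_err = abs(agg["pop.total"].sum() - tracts["pop.total"].sum())
print(f"{len(w)} tract-district intersections over {len(tracts)} tracts / {len(districts)} districts")
print(f"max |sum area fraction - 1| = {frac_err:.2e}; max |sum pop prop - 1| = {prop_err:.2e}")
print(f"total population conserved to {pop_err:.2e} persons")
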