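"""Generate the two study scenarios and write them to disk.

The "null" scenario has no spatial structure in reporting delays and is
used to calibrate every permutation test; the "spatial" scenario adds a
district random effect (SD 0.5 on the log-delay scale) plus holiday,
survivor-age and area-poverty effects, and drives the power and model
comparisons.  Events go to CSV, areas to GeoJSON.
"""

from pathlib import Path

import reportdelay as rd
from reportdelay import io

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

for name in ("null", "spatial"):
    data = rd.generate(rd.preset(name, seed=1))
    io.write_events_csv(data.events, OUT / f"{name}_events.csv")
    io.write_areas_geojson(data.tracts, OUT / f"{name}_tracts.geojson", "tract_id")
    io.write_areas_geojson(data.districts, OUT / f"{name}_districts.geojson", "district_id")
    ev = data.events
    print(
        f"{name}: {len(ev)} events over {data.districts.shape[0]} districts | "
        f"median delay {ev.delay_days.median():.0f} d, "
        f"within day/week/month: {ev.d_day.mean():.2f}/{ev.d_week.mean():.2f}/{ev.d_month.mean():.2f}"
    )
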