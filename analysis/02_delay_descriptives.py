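"""Delay descriptives: heavy tail, threshold indicators, district summaries.

Reads the simulated event tables from 01 and writes per-district counts,
reporting proportions and median delays.
"""

from pathlib import Path

import pandas as pd

from reportdelay import delays, io

OUT = Path("results/tables")
OUT.mkdir(parents=True, exist_ok=True)

for name in ("null", "spatial"):
    ev = io.read_events_csv(Path("results/data") / f"{name}_events.csv")
    ev = delays.add_delay_columns(ev)
    districts = io.read_areas_geojson(
        Path("results/data") / f"{name}_districts.geojson", "district_id"
    )
    summary = delays.area_summaries(ev, districts["district_id"])
    summary.to_csv(OUT / f"{name}_district_summary.csv")
    q = ev["delay_days"].quantile([0.5, 0.9, 0.99])
    print(
        f"{name}: delay quantiles 50/90/99% = {q.iloc[0]:.0f}/{q.iloc[1]:.0f}/{q.iloc[2]:.0f} days "
        f"(99th/median ratio {q.iloc[2] / max(q.iloc[0], 1):.0f}x) -> "
        f"{OUT / (name + '_district_summary.csv')}"
    )
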