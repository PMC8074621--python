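"""Global and local Moran's I on district reporting proportions.

Tests whether the share of incidents reported within a day/week/month and
the mean log-delay cluster across neighbouring districts, under queen
contiguity, for both scenarios.
"""

from pathlib import Path

import pandas as pd

from reportdelay import delays, io, moran, weights

OUT = Path("results/tables")
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for name in ("null", "spatial"):
    ev = delays.add_delay_columns(
        io.read_events_csv(Path("results/data") / f"{name}_events.csv")
    )
    districts = io.read_areas_geojson(
        Path("results/data") / f"{name}_districts.geojson", "district_id"
    )
    summary = delays.area_summaries(ev, districts["district_id"])
    qw = weights.queen_weights(
        districts["geometry"], ids=districts["district_id"].to_numpy()
    )
    for col in ("p_day", "p_week", "p_month", "mean_log_delay"):
        res = moran.global_moran(summary[col].to_numpy(), qw, n_perm=999, seed=4)
        rows.append((name, col, res.statistic, res.pseudo_p))
        loc = moran.local_moran(summary[col].to_numpy(), qw, n_perm=199, seed=4)
        n_hot = int((loc.pseudo_p < 0.05).sum())
        print(
            f"{name:7s} {col:15s} global I={res.statistic:+.3f} p={res.pseudo_p:.3f} | "
            f"{n_hot} districts with significant local clustering"
        )

pd.DataFrame(rows, columns=["scenario", "variable", "moran_i", "pseudo_p"]).to_csv(
    OUT / "moran_global.csv", index=False
)
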