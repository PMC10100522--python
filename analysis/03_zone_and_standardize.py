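"""Discretize the study region into elevational and latitudinal zones.

Sturges' rule sets the zone count from the number of lakes; the exact
Fisher-Jenks classification places the natural breaks independently on each
axis.  Writes per-lake zone labels and the break values.

    python analysis/03_zone_and_standardize.py [--dir results/analysis] [--k K]
"""

import argparse

import pandas as pd

from lakediv import io as cio
from lakediv.zoning import assign_zones, sturges_k


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dir", default="results/analysis")
    ap.add_argument("--k", type=int, default=None,
                    help="override Sturges' zone count")
    args = ap.parse_args()

    lakes = cio.read_lake_table(f"{args.dir}/lakes.csv")
    k = args.k or sturges_k(len(lakes))
    zones = assign_zones(lakes, k=k)
    zones.table.to_csv(f"{args.dir}/zones.csv", index=False)
    pd.DataFrame({
        "zone": range(1, k + 1),
        "elev_break": zones.elev_breaks,
        "lat_break": zones.lat_breaks,
    }).to_csv(f"{args.dir}/zone_breaks.csv", index=False)

    print(f"{len(lakes)} lakes -> k = {k} zones per axis (Sturges: "
          f"{sturges_k(len(lakes))})")
    print(f"mean zone width: elevation "
          f"{zones.width_stats['elev_mean_width']:.0f} m, latitude "
          f"{zones.width_stats['lat_mean_width']:.2f} deg")
    counts = zones.table.groupby("elev_zone").size()
    print(f"lakes per elevational zone: min {counts.min()}, max {counts.max()}")


if __name__ == "__main__":
    main()
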