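#!/usr/bin/env python
"""Availability of local vs imported products by sector and product type."""

import pandas as pd

import medsurvey as ms
from medsurvey.model import Origin, ProductType, Sector
from _common import load_country, results_dir

dataset, *_ = load_country()

rows = []
for sector in Sector:
    overall = ms.mean_availability(dataset, sector)
    rows.append({"sector": sector.value, "stratum": "all_products",
                 "mean_availability_pct": round(overall, 1)})
    line = [f"{sector.value}: all products {overall:.0f}%"]
    for origin in Origin:
        pct = ms.mean_availability(dataset, sector, origin=origin)
        rows.append({"sector": sector.value, "stratum": origin.value,
                     "mean_availability_pct": round(pct, 1)})
        line.append(f"{origin.value} {pct:.0f}%")
        for ptype in ProductType:
            tpct = ms.mean_availability(dataset, sector, origin=origin, product_type=ptype)
            rows.append({"sector": sector.value,
                         "stratum": f"{origin.value}_{ptype.value}",
                         "mean_availability_pct": round(tpct, 1)})
    print("; ".join(line))

out = results_dir() / "03_availability.csv"
pd.DataFrame(rows).to_csv(out, index=False)

region = pd.concat(
    [ms.region_availability(dataset, s).assign(sector=s.value) for s in Sector],
    ignore_index=True,
)
region.to_csv(results_dir() / "03_availability_by_region.csv", index=False)
print(f"Tables: {out}, {results_dir() / '03_availability_by_region.csv'}")
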