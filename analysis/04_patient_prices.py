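#!/usr/bin/env python
"""Patient prices: paired local/imported MPRs and procurement-to-patient mark-ups."""

import pandas as pd

import medsurvey as ms
from medsurvey.model import Origin, Sector
from _common import load_country, results_dir

dataset, tenders, truth, _, config = load_country()

paired_rows, markup_rows = [], []
patient_public = None
for sector in Sector:
    result = ms.compute_mpr_summaries(dataset, truth.irp, config, sector)
    if sector is Sector.PUBLIC:
        patient_public = result
    paired = ms.pair_origins(
        [s for s in result.included if s.origin is Origin.LOCAL],
        [s for s in result.included if s.origin is Origin.IMPORTED],
    )
    cmp = ms.paired_patient_comparison(paired, sector)
    paired_rows.append(
        {
            "sector": sector.value,
            "n_paired_medicines": cmp.n_paired_medicines,
            "median_mpr_local": round(cmp.median_mpr_local, 2),
            "median_mpr_imported": round(cmp.median_mpr_imported, 2),
            "pct_difference": cmp.pct_difference,
            "n_excluded_cells": len(result.excluded),
        }
    )
    rel = ms.format_percent_difference(
        round(cmp.median_mpr_local, 2), round(cmp.median_mpr_imported, 2)
    )
    print(f"{sector.value}: median MPR local {cmp.median_mpr_local:.2f} vs "
          f"imported {cmp.median_mpr_imported:.2f} across "
          f"{cmp.n_paired_medicines} paired medicines — patients pay {rel} for local products")

proc = ms.procurement_mpr_summaries(tenders, truth.irp, config)
for origin in Origin:
    mk = ms.markup_summary(list(patient_public.included), list(proc.included), origin)
    markup_rows.append(
        {
            "origin": origin.value,
            "n_paired_medicines": mk.n_paired_medicines,
            "median_patient_to_procurement_ratio": round(mk.median_ratio, 2),
        }
    )
    print(f"public-sector mark-up, {origin.value} products: patients pay "
          f"{mk.median_ratio:.2f}x the procurement price "
          f"({mk.n_paired_medicines} paired medicines)")

pd.DataFrame(paired_rows).to_csv(results_dir() / "04_paired_patient_mpr.csv", index=False)
pd.DataFrame(markup_rows).to_csv(results_dir() / "04_markup.csv", index=False)
print(f"Tables: {results_dir() / '04_paired_patient_mpr.csv'}, "
      f"{results_dir() / '04_markup.csv'}")
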