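#!/usr/bin/env python
"""Generate the synthetic country used throughout the analysis.

Writes the survey CSVs, tender file, reference prices and ground truth under
scratch/synthetica/, and a ground-truth summary table under results/.
"""

import pandas as pd

from _common import SCRATCH, load_country, results_dir

dataset, tenders, truth, tender_truth, config = load_country()

rows = [
    {
        "medicine_id": mid,
        "sector": sector.value,
        "origin": origin.value,
        "target_mpr": mpr,
        "availability_prob": truth.availability_prob[(mid, sector, origin)],
    }
    for (mid, sector, origin), mpr in sorted(truth.target_mpr.items())
]
out = results_dir() / "01_ground_truth.csv"
pd.DataFrame(rows).to_csv(out, index=False)

print(f"Synthetic country written to {SCRATCH}")
print(f"  outlets: {len(dataset.outlets)}  medicines: {len(dataset.medicines)}")
print(f"  price records: {len(dataset.prices)}  tender lines: {len(tenders)}")
print(f"  exchange rate: {truth.exchange_rate} local currency units per USD")
print(f"Ground-truth table: {out}")
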