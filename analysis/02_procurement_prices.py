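#!/usr/bin/env python
"""Tender analysis: landed costs, local-vs-imported comparison, savings.

Adjusts imported quotes to landed cost (FOB/FCA +22%, CFR +7%), compares
per-medicine median landed prices across origins, computes quantity shares,
checks the local-preference policy, and prices the substitution
counterfactual (buy everything at the cheaper origin).
"""

import pandas as pd

import medsurvey as ms
from medsurvey.model import IncoTerm, Origin
from _common import load_country, results_dir

dataset, tenders, truth, tender_truth, config = load_country()
schedule = config.surcharge_schedule

print("Landed-cost factors:",
      f"FOB/FCA x{schedule.factor(IncoTerm.FOB)}, CFR x{schedule.factor(IncoTerm.CFR)}")

comparisons = ms.compare_all(tenders, schedule)
rows = []
for cmp in comparisons:
    recs = [r for r in tenders if r.medicine_id == cmp.medicine_id]
    shares = ms.quantity_share(recs)
    rows.append(
        {
            "medicine_id": cmp.medicine_id,
            "paired": cmp.paired,
            "local_median_landed": round(cmp.local.median_unit_price, 4) if cmp.local else None,
            "imported_median_landed": round(cmp.imported.median_unit_price, 4)
            if cmp.imported else None,
            "cheaper_origin": cmp.cheaper_origin.value if cmp.cheaper_origin else None,
            "pct_local_premium": cmp.pct_local_premium,
            "imported_quantity_share_pct": shares[Origin.IMPORTED],
            "preference_status": ms.preference_check(cmp, config.preference_margin_pct).value,
        }
    )
df = pd.DataFrame(rows)
out = results_dir() / "02_procurement_comparison.csv"
df.to_csv(out, index=False)

paired = df[df["paired"]]
n_import_cheaper = (paired["cheaper_origin"] == "imported").sum()
print(f"{len(paired)} medicines tendered in both origins; "
      f"imports cheaper for {n_import_cheaper} of them")
print(f"Local premium exceeds the {config.preference_margin_pct:.0f}% preference margin for "
      f"{(paired['preference_status'] == 'exceeds_margin').sum()} medicines")

savings = ms.savings_if_cheapest(comparisons, config.exchange_rate)
print(f"Buying each paired medicine at its cheaper origin would have saved "
      f"{savings.local_currency:,.0f} local currency units "
      f"(USD {savings.usd:,.0f}) across {savings.n_medicines} medicines")
pd.DataFrame(
    [{"n_medicines": savings.n_medicines,
      "savings_local_currency": round(savings.local_currency, 2),
      "savings_usd": round(savings.usd, 2)}]
).to_csv(results_dir() / "02_savings.csv", index=False)
print(f"Tables: {out}, {results_dir() / '02_savings.csv'}")
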