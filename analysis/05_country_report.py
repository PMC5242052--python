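#!/usr/bin/env python
"""Assemble the full country report (all summary tables) in one pass."""

import yaml

import medsurvey as ms
from _common import load_country, results_dir

dataset, tenders, truth, _, config = load_country()

report = ms.build_country_report(dataset, tenders, truth.irp, config)
out_dir = results_dir() / "05_country_report"
paths = report.write(out_dir)
report.write(out_dir, fmt="markdown")
with open(out_dir / "run_log.yaml", "w", encoding="utf-8") as fh:
    yaml.safe_dump(report.run_log, fh, sort_keys=True)

print(f"Wrote {len(paths)} tables (CSV + markdown) to {out_dir}")
print(report.tables["paired_comparison"].to_string(index=False))
print(report.tables["markup"].to_string(index=False))
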