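"""Shared setup for the analysis scripts.

One synthetic country ("Synthetica") is generated at the pilot surveys'
structure — 6 regions, ~30 outlets per sector, 25 medicines — with ground
truth set to the Ethiopian-style conditions: local products dearer than
imports in public-sector patient prices (target MPRs 1.44 vs 1.18), far
cheaper than imports in the private sector (1.85 vs 5.42), more available
than imports in both sectors, and a government that marks local products up
less (1.17x) than imports (1.53x).
"""

from __future__ import annotations

from pathlib import Path

import medsurvey as ms
from medsurvey.synthetic import GeneratorSpec

SEED = 20130801  # first day of data collection, as an integer
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synthetica"
RESULTS = ROOT / "results"


def country_spec(seed: int = SEED) -> GeneratorSpec:
    # 6 regions x (6 public + 5 private) outlets ~ the pilot sample sizes.
    return GeneratorSpec(seed=seed)


def load_country(seed: int = SEED):
    """Generate (or re-read from scratch/) the synthetic country."""
    spec = country_spec(seed)
    dataset, truth = ms.generate(spec)
    tenders, tender_truth = ms.generate_procurement(spec)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    ms.io.write_survey(dataset, SCRATCH)
    ms.io.write_procurement(tenders, SCRATCH / "procurement.csv")
    ms.io.write_irp(truth.irp, SCRATCH / "irp.csv")
    truth.to_yaml(SCRATCH / "ground_truth.yaml")
    config = truth.survey_config()
    ms.io.write_config(config, SCRATCH / "config.yaml")
    return dataset, tenders, truth, tender_truth, config


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
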