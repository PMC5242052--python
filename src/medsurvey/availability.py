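"""Availability of medicines by sector, origin, product type and region.

Availability means: the percentage of surveyed outlets in a sector that had
at least one matching product in stock on the day of data collection.  The
denominator is always the full outlet census for the sector — outlets that
stocked none of the survey medicines still count.  "Mean availability" is the
unweighted arithmetic mean over the survey medicine list, with never-stocked
medicines entering at 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    Origin,
    ProductType,
    Sector,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "AvailabilityCell",
    "medicine_availability",
    "mean_availability",
    "availability_table",
    "region_availability",
]


@dataclass(frozen=True)
class AvailabilityCell:
    sector: Sector
    medicine_id: str
    origin: Origin | None
    product_type: ProductType | None
    pct_outlets_with_stock: float


def _sector_outlets(dataset: SurveyDataset, sector: Sector, region: str | None = None) -> set[str]:
    sector = Sector(sector)
    ids = {
        o.outlet_id
        for o in dataset.outlets_in(sector)
        if region is None or o.region == region
    }
    if not ids:
        where = f"sector {sector.value}" + (f", region {region}" if region else "")
        raise ValidationError(f"no surveyed outlets in {where}: availability undefined")
    return ids


def medicine_availability(
    dataset: SurveyDataset,
    medicine_id: str,
    sector: Sector,
    *,
    origin: Origin | None = None,
    product_type: ProductType | None = None,
    region: str | None = None,
) -> float:
    """Percent of the sector's outlets stocking the medicine (stratum-matched)."""
    outlets = _sector_outlets(dataset, sector, region)
    stocked = {
        r.outlet_id
        for r in dataset.prices
        if r.medicine_id == medicine_id
        and r.outlet_id in outlets
        and (origin is None or r.origin is Origin(origin))
        and (product_type is None or r.product_type is ProductType(product_type))
    }
    return 100.0 * len(stocked) / len(outlets)


def mean_availability(
    dataset: SurveyDataset,
    sector: Sector,
    *,
    origin: Origin | None = None,
    product_type: ProductType | None = None,
    region: str | None = None,
) -> float:
    """Unweighted mean of per-medicine availability over the survey list."""
    if not dataset.medicines:
        raise ValidationError("survey medicine list is empty")
    values = [
        medicine_availability(
            dataset,
            m.medicine_id,
            sector,
            origin=origin,
            product_type=product_type,
            region=region,
        )
        for m in dataset.medicines
    ]
    return sum(values) / len(values)


def availability_table(dataset: SurveyDataset, sector: Sector) -> pd.DataFrame:
    """Per-medicine availability: overall, by origin, and origin x type."""
    sector = Sector(sector)
    rows = []
    for m in dataset.medicines:
        row = {
            "medicine_id": m.medicine_id,
            "overall": medicine_availability(dataset, m.medicine_id, sector),
        }
        for origin in Origin:
            row[origin.value] = medicine_availability(
                dataset, m.medicine_id, sector, origin=origin
            )
            for ptype in ProductType:
                row[f"{origin.value}_{ptype.value}"] = medicine_availability(
                    dataset, m.medicine_id, sector, origin=origin, product_type=ptype
                )
        rows.append(row)
    return pd.DataFrame(rows)


def region_availability(
    dataset: SurveyDataset, sector: Sector, *, origin: Origin | None = None
) -> pd.DataFrame:
    """Mean availability per survey region (reported as a breakdown only)."""
    sector = Sector(sector)
    regions = sorted({o.region for o in dataset.outlets_in(sector)})
    rows = [
        {
            "region": region,
            "mean_availability_pct": mean_availability(
                dataset, sector, origin=origin, region=region
            ),
        }
        for region in regions
    ]
    return pd.DataFrame(rows)
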