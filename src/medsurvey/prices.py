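"""Unit prices, outlet medians and median price ratios (MPRs).

The price analysis follows the WHO/HAI convention, stratified by product
origin (local vs imported):

1. every pack price is reduced to a price per dose unit;
2. where an outlet stocks several products of the same medicine and origin,
   they collapse to the outlet's *median unit price* — one "price point";
3. a medicine's price points are summarized as a median price ratio,
   ``MPR = median(price points) / (IRP_usd x exchange_rate)``, with the IQR
   computed on the same ratio scale;
4. patient-price MPRs are reported only when at least four price points were
   recorded in the sector; procurement MPRs need only one.

An MPR of 1 means the country price equals the international reference price.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Literal, Sequence

from .model import (
    ConfigurationError,
    Origin,
    PriceRecord,
    ReferencePriceTable,
    Sector,
    SurveyConfig,
    SurveyDataset,
)
from .stats import iqr, median

__all__ = [
    "MedicineMprSummary",
    "MprExclusion",
    "MprResult",
    "SectorSummary",
    "unit_price",
    "outlet_median_price",
    "medicine_mpr",
    "sector_summary",
    "collect_price_points",
    "compute_mpr_summaries",
]

Context = Literal["patient", "procurement"]


@dataclass(frozen=True)
class MedicineMprSummary:
    """Per medicine x sector x origin price summary.

    ``n_price_points`` counts contributing outlets (after the within-outlet
    median collapse); ``n_products`` counts the underlying product
    observations.  ``iqr_low``/``iqr_high`` are the 25th/75th percentiles of
    the outlet-level price ratios.
    """

    medicine_id: str
    sector: Sector
    origin: Origin
    n_price_points: int
    n_products: int
    median_mpr: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class MprExclusion:
    medicine_id: str
    sector: Sector
    origin: Origin
    n_price_points: int
    reason: str


@dataclass(frozen=True)
class MprResult:
    included: tuple[MedicineMprSummary, ...]
    excluded: tuple[MprExclusion, ...]


@dataclass(frozen=True)
class SectorSummary:
    """Cross-medicine roll-up: median and IQR of the per-medicine median MPRs."""

    sector: Sector
    origin: Origin
    n_medicines: int
    n_products: int
    median_of_median_mpr: float | None
    iqr_across_medicines: tuple[float, float] | None


def unit_price(record: PriceRecord) -> Decimal:
    """Price per dose unit: pack price / pack size, in exact decimal arithmetic."""
    return record.pack_price / Decimal(record.pack_size)


def outlet_median_price(unit_prices: Sequence) -> float:
    """Median unit price for one outlet x medicine x origin cell.

    Linear interpolation at even counts.  Callers must not pass an empty
    sequence — an outlet with no matching product contributes nothing.
    """
    if len(unit_prices) == 0:
        raise ValueError("outlet_median_price needs at least one unit price")
    return median([float(p) for p in unit_prices])


def medicine_mpr(
    outlet_medians: Sequence[float],
    irp_usd: Decimal,
    config: SurveyConfig,
    context: Context = "patient",
    *,
    medicine_id: str = "",
    sector: Sector = Sector.PUBLIC,
    origin: Origin = Origin.LOCAL,
    n_products: int | None = None,
) -> MedicineMprSummary | MprExclusion:
    """Summarize one medicine's price points as an MPR, or exclude it.

    Patient context requires ``config.min_price_points_patient`` (default 4)
    price points; procurement context ``config.min_price_points_procurement``
    (default 1).
    """
    irp_usd = Decimal(str(irp_usd))
    if irp_usd <= 0:
        raise ConfigurationError(f"IRP must be > 0, got {irp_usd}")
    threshold = (
        config.min_price_points_patient
        if context == "patient"
        else config.min_price_points_procurement
    )
    n = len(outlet_medians)
    if n < threshold:
        return MprExclusion(
            medicine_id=medicine_id,
            sector=sector,
            origin=origin,
            n_price_points=n,
            reason=f"fewer than {threshold} price points ({n})",
        )
    denom = float(irp_usd * config.exchange_rate)
    ratios = [m / denom for m in outlet_medians]
    lo, hi = iqr(ratios)
    return MedicineMprSummary(
        medicine_id=medicine_id,
        sector=sector,
        origin=origin,
        n_price_points=n,
        n_products=n if n_products is None else n_products,
        median_mpr=median(ratios),
        iqr_low=lo,
        iqr_high=hi,
    )


def sector_summary(summaries: Sequence[MedicineMprSummary]) -> SectorSummary:
    """Roll per-medicine summaries (one sector, one origin) up to sector level."""
    if not summaries:
        return SectorSummary(
            sector=Sector.PUBLIC,
            origin=Origin.LOCAL,
            n_medicines=0,
            n_products=0,
            median_of_median_mpr=None,
            iqr_across_medicines=None,
        )
    sectors = {s.sector for s in summaries}
    origins = {s.origin for s in summaries}
    if len(sectors) != 1 or len(origins) != 1:
        raise ValueError("sector_summary expects summaries from one sector and origin")
    medians = [s.median_mpr for s in summaries]
    return SectorSummary(
        sector=next(iter(sectors)),
        origin=next(iter(origins)),
        n_medicines=len(summaries),
        n_products=sum(s.n_products for s in summaries),
        median_of_median_mpr=median(medians),
        iqr_across_medicines=iqr(medians),
    )


def collect_price_points(
    dataset: SurveyDataset,
    sector: Sector,
    *,
    product_types: Iterable | None = None,
) -> dict[tuple[str, Origin], tuple[list[float], int]]:
    """Outlet-median price points per (medicine, origin) cell in a sector.

    Returns ``{(medicine_id, origin): (outlet_medians, n_products)}``.
    ``product_types`` restricts the analysis to a subset of product types
    (used for the unpaired by-type tables); the within-outlet median collapse
    is applied after the restriction.
    """
    sector = Sector(sector)
    allowed = None if product_types is None else {pt for pt in product_types}
    sector_outlets = {o.outlet_id for o in dataset.outlets_in(sector)}

    per_cell: dict[tuple[str, Origin, str], list[float]] = {}
    for rec in dataset.prices:
        if rec.outlet_id not in sector_outlets:
            continue
        if allowed is not None and rec.product_type not in allowed:
            continue
        key = (rec.medicine_id, rec.origin, rec.outlet_id)
        per_cell.setdefault(key, []).append(float(unit_price(rec)))

    out: dict[tuple[str, Origin], tuple[list[float], int]] = {}
    for (mid, origin, _outlet), prices in sorted(per_cell.items(), key=lambda kv: kv[0][:3]):
        medians, count = out.setdefault((mid, origin), ([], 0))
        medians.append(outlet_median_price(prices))
        out[(mid, origin)] = (medians, count + len(prices))
    return out


def compute_mpr_summaries(
    dataset: SurveyDataset,
    irp: ReferencePriceTable,
    config: SurveyConfig,
    sector: Sector,
    context: Context = "patient",
    *,
    product_types: Iterable | None = None,
) -> MprResult:
    """Per-medicine MPR summaries for every (medicine, origin) cell with data.

    Cells failing the inclusion threshold come back in ``excluded``; included
    plus excluded always account for every candidate cell.
    """
    sector = Sector(sector)
    irp.check_covers(m.medicine_id for m in dataset.medicines)
    points = collect_price_points(dataset, sector, product_types=product_types)
    included: list[MedicineMprSummary] = []
    excluded: list[MprExclusion] = []
    for (mid, origin), (outlet_medians, n_products) in points.items():
        result = medicine_mpr(
            outlet_medians,
            irp[mid],
            config,
            context,
            medicine_id=mid,
            sector=sector,
            origin=origin,
            n_products=n_products,
        )
        if isinstance(result, MedicineMprSummary):
            included.append(result)
        else:
            excluded.append(result)
    return MprResult(included=tuple(included), excluded=tuple(excluded))
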