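"""Government tender analysis: landed costs, origin comparison, savings.

Imported tender quotes under terms like FOB/FCA or CFR exclude part of the
cost of getting goods to the national medical store.  To compare them fairly
with locally produced products, each quote is scaled to a landed cost by an
additive surcharge schedule (freight, insurance, bank charges, import duty).
The per-medicine comparison then uses the median landed unit price per
origin, expresses the local premium as a percentage, checks it against the
national local-preference margin, and prices a simple substitution
counterfactual: what the buyer would have saved had the full quantity been
bought at the cheaper origin's unit price.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal

from .model import (
    IncoTerm,
    Origin,
    ProcurementRecord,
    ReferencePriceTable,
    SurchargeSchedule,
    SurveyConfig,
    ValidationError,
)
from .prices import MedicineMprSummary, MprExclusion, MprResult, medicine_mpr
from .model import Sector
from .stats import median, round_half_up

__all__ = [
    "OriginStats",
    "ProcurementComparison",
    "PreferenceStatus",
    "SavingsResult",
    "adjust_price",
    "quantity_share",
    "compare_origins",
    "compare_all",
    "savings_if_cheapest",
    "preference_check",
    "procurement_mpr_summaries",
]


def adjust_price(
    quoted: Decimal | str | float, term: IncoTerm, schedule: SurchargeSchedule
) -> Decimal:
    """Landed cost of a quoted price: ``quoted x (1 + sum(surcharges)/100)``.

    Surcharge components add; they are not compounded.  A term of ``none``
    leaves the quote unchanged; a term missing from the schedule is a
    configuration error.
    """
    quoted = quoted if isinstance(quoted, Decimal) else Decimal(str(quoted))
    if quoted <= 0:
        raise ValidationError(f"quoted price must be > 0, got {quoted}")
    return quoted * schedule.factor(IncoTerm(term))


def quantity_share(
    records: list[ProcurementRecord], *, ndigits: int | None = 1
) -> dict[Origin, float]:
    """Percent of a medicine's total tendered quantity per origin.

    Reported to 1 decimal by default; pass ``ndigits=None`` for exact shares.
    """
    total = sum(r.quantity for r in records)
    if total <= 0:
        raise ValidationError("total tendered quantity is zero; shares undefined")
    shares: dict[Origin, float] = {}
    for origin in Origin:
        qty = sum(r.quantity for r in records if r.origin is origin)
        share = 100.0 * qty / total
        shares[origin] = share if ndigits is None else round_half_up(share, ndigits)
    return shares


@dataclass(frozen=True)
class OriginStats:
    median_unit_price: float  # landed, local currency per dose unit
    median_unit_price_quoted: float
    total_quantity: int
    n_products: int


class PreferenceStatus(str, enum.Enum):
    WITHIN_MARGIN = "within_margin"
    EXCEEDS_MARGIN = "exceeds_margin"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class ProcurementComparison:
    medicine_id: str
    local: OriginStats | None
    imported: OriginStats | None
    cheaper_origin: Origin | None  # by landed median; None if unpaired or tied
    pct_local_premium: int | None  # round-half-up integer percent; None if unpaired

    @property
    def paired(self) -> bool:
        return self.local is not None and self.imported is not None


def _origin_stats(records: list[ProcurementRecord], schedule: SurchargeSchedule) -> OriginStats:
    landed = [float(adjust_price(r.unit_price_quoted, r.inco_term, schedule)) for r in records]
    quoted = [float(r.unit_price_quoted) for r in records]
    return OriginStats(
        median_unit_price=median(landed),
        median_unit_price_quoted=median(quoted),
        total_quantity=sum(r.quantity for r in records),
        n_products=len(records),
    )


def compare_origins(
    records: list[ProcurementRecord], schedule: SurchargeSchedule
) -> ProcurementComparison:
    """Local vs imported landed prices for one medicine's tender lines.

    The premium is ``100 x (local/imported - 1)`` on the unrounded landed
    medians, reported to the nearest integer percent.
    """
    if not records:
        raise ValidationError("compare_origins needs at least one record")
    mids = {r.medicine_id for r in records}
    if len(mids) != 1:
        raise ValidationError(f"records span multiple medicines: {sorted(mids)}")
    by_origin = {
        origin: [r for r in records if r.origin is origin] for origin in Origin
    }
    local = _origin_stats(by_origin[Origin.LOCAL], schedule) if by_origin[Origin.LOCAL] else None
    imported = (
        _origin_stats(by_origin[Origin.IMPORTED], schedule) if by_origin[Origin.IMPORTED] else None
    )
    cheaper: Origin | None = None
    premium: int | None = None
    if local is not None and imported is not None:
        if local.median_unit_price < imported.median_unit_price:
            cheaper = Origin.LOCAL
        elif imported.median_unit_price < local.median_unit_price:
            cheaper = Origin.IMPORTED
        premium = round_half_up(
            100.0 * (local.median_unit_price / imported.median_unit_price - 1.0)
        )
    return ProcurementComparison(
        medicine_id=next(iter(mids)),
        local=local,
        imported=imported,
        cheaper_origin=cheaper,
        pct_local_premium=premium,
    )


def compare_all(
    records: list[ProcurementRecord], schedule: SurchargeSchedule
) -> list[ProcurementComparison]:
    by_medicine: dict[str, list[ProcurementRecord]] = {}
    for r in records:
        by_medicine.setdefault(r.medicine_id, []).append(r)
    return [compare_origins(recs, schedule) for _, recs in sorted(by_medicine.items())]


@dataclass(frozen=True)
class SavingsResult:
    local_currency: float
    usd: float
    n_medicines: int  # paired medicines where switching origin saves money
    n_skipped: int  # paired medicines without usable quantities


def savings_if_cheapest(
    comparisons: list[ProcurementComparison],
    exchange_rate: Decimal | float,
    *,
    use_landed: bool = True,
) -> SavingsResult:
    """Hypothetical savings from buying each medicine only at its cheaper origin.

    For every paired medicine whose dearer origin was actually bought, the
    full quantity bought at the dearer origin is repriced at the cheaper
    origin's median unit price (capacity constraints ignored):
    ``savings = q_dearer x (p_dearer - p_cheaper)``.  Landed prices by
    default; ``use_landed=False`` uses the quoted prices.
    """
    total = 0.0
    n_used = 0
    n_skipped = 0
    for cmp in comparisons:
        if not cmp.paired or cmp.cheaper_origin is None:
            continue
        price_of = (
            (lambda s: s.median_unit_price) if use_landed else (lambda s: s.median_unit_price_quoted)
        )
        stats = {Origin.LOCAL: cmp.local, Origin.IMPORTED: cmp.imported}
        dearer = Origin.LOCAL if cmp.cheaper_origin is Origin.IMPORTED else Origin.IMPORTED
        q_dearer = stats[dearer].total_quantity
        if q_dearer <= 0:
            n_skipped += 1
            continue
        total += q_dearer * (price_of(stats[dearer]) - price_of(stats[cmp.cheaper_origin]))
        n_used += 1
    fx = float(exchange_rate)
    return SavingsResult(
        local_currency=total, usd=total / fx, n_medicines=n_used, n_skipped=n_skipped
    )


def preference_check(
    comparison: ProcurementComparison, preference_margin_pct: float
) -> PreferenceStatus:
    """Is the local price premium within the local-preference margin?

    A premium exactly equal to the margin is within policy ("up to N%").
    """
    if not comparison.paired:
        return PreferenceStatus.UNPAIRED
    if comparison.pct_local_premium > preference_margin_pct:
        return PreferenceStatus.EXCEEDS_MARGIN
    return PreferenceStatus.WITHIN_MARGIN


def procurement_mpr_summaries(
    records: list[ProcurementRecord],
    irp: ReferencePriceTable,
    config: SurveyConfig,
    *,
    use_landed: bool = True,
) -> MprResult:
    """Per-medicine procurement MPRs from landed (or quoted) tender prices.

    The tender is treated as a single price source, so the procurement
    inclusion threshold (default: one price) applies; where several products
    of one origin were tendered, their median landed unit price is used.
    """
    schedule = config.surcharge_schedule
    by_cell: dict[tuple[str, Origin], list[ProcurementRecord]] = {}
    for r in records:
        by_cell.setdefault((r.medicine_id, r.origin), []).append(r)
    irp.check_covers(mid for mid, _ in by_cell)
    included: list[MedicineMprSummary] = []
    excluded: list[MprExclusion] = []
    for (mid, origin), recs in sorted(by_cell.items()):
        if use_landed:
            prices = [float(adjust_price(r.unit_price_quoted, r.inco_term, schedule)) for r in recs]
        else:
            prices = [float(r.unit_price_quoted) for r in recs]
        result = medicine_mpr(
            [median(prices)],
            irp[mid],
            config,
            "procurement",
            medicine_id=mid,
            sector=Sector.PUBLIC,
            origin=origin,
            n_products=len(recs),
        )
        (included if isinstance(result, MedicineMprSummary) else excluded).append(result)
    return MprResult(included=tuple(included), excluded=tuple(excluded))
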