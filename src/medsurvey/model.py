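"""Shared data model for medicine price and availability surveys.

The survey records, for a national list of strength- and dosage-form-specific
medicines, every product found in stock in each sampled outlet, together with
its origin (locally manufactured vs imported) and product type (originator
brand, branded generic, INN generic).  Government tender records and an
international reference price (IRP) table complete the inputs.

Monetary amounts are carried as :class:`decimal.Decimal` so that files written
by this package round-trip bit-for-bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Sector",
    "Origin",
    "ProductType",
    "IncoTerm",
    "SurveyError",
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "ConfigurationError",
    "InsufficientDataError",
    "Outlet",
    "Medicine",
    "PriceRecord",
    "ProcurementRecord",
    "ReferencePriceTable",
    "SurchargeSchedule",
    "SurveyConfig",
    "SurveyDataset",
    "as_decimal",
]


class Sector(str, enum.Enum):
    PUBLIC = "public"
    PRIVATE = "private"


class Origin(str, enum.Enum):
    LOCAL = "local"
    IMPORTED = "imported"


class ProductType(str, enum.Enum):
    ORIGINATOR_BRAND = "originator_brand"
    BRANDED_GENERIC = "branded_generic"
    INN_GENERIC = "inn_generic"


class IncoTerm(str, enum.Enum):
    """International commercial terms attached to tender quotes.

    ``NONE`` marks quotes that need no landed-cost adjustment (all locally
    produced products, and imports quoted delivered to the national store).
    """

    FOB = "FOB"
    FCA = "FCA"
    CFR = "CFR"
    CIF = "CIF"
    DDP = "DDP"
    NONE = "none"


class SurveyError(Exception):
    """Base class for all survey data errors."""


class SchemaError(SurveyError):
    """A file does not match the documented header contract."""


class ValidationError(SurveyError):
    """A field value violates a domain invariant."""


class IntegrityError(SurveyError):
    """A record references an outlet or medicine that does not exist."""


class ConfigurationError(SurveyError):
    """Country configuration (exchange rate, surcharges, ...) is invalid."""


class InsufficientDataError(SurveyError):
    """No medicine passed the inclusion rules; nothing to report."""


def as_decimal(value, *, what: str = "value") -> Decimal:
    """Coerce ``value`` to Decimal, raising :class:`ValidationError` on junk."""
    if isinstance(value, Decimal):
        return value
    try:
        return Decimal(str(value))
    except InvalidOperation as exc:  # pragma: no cover - message path
        raise ValidationError(f"{what} is not a decimal number: {value!r}") from exc


@dataclass(frozen=True)
class Outlet:
    outlet_id: str
    sector: Sector
    region: str
    country: str

    def __post_init__(self) -> None:
        if not self.outlet_id:
            raise ValidationError("outlet_id must be non-empty")
        if not self.region:
            raise ValidationError(f"outlet {self.outlet_id}: region must be non-empty")
        object.__setattr__(self, "sector", Sector(self.sector))


@dataclass(frozen=True)
class Medicine:
    medicine_id: str
    name: str
    strength: str
    dosage_form: str

    def __post_init__(self) -> None:
        if not self.medicine_id or not self.name:
            raise ValidationError("medicine_id and name must be non-empty")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.name, self.strength, self.dosage_form)


@dataclass(frozen=True)
class PriceRecord:
    """One product found in stock in one outlet on the survey day.

    Availability is encoded by presence: an (outlet, medicine) pair with no
    record means the medicine was out of stock there.
    """

    outlet_id: str
    medicine_id: str
    product_label: str
    origin: Origin
    product_type: ProductType
    country_of_manufacture: str
    pack_price: Decimal
    pack_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", Origin(self.origin))
        object.__setattr__(self, "product_type", ProductType(self.product_type))
        object.__setattr__(self, "pack_price", as_decimal(self.pack_price, what="pack_price"))
        if self.pack_price <= 0:
            raise ValidationError(
                f"pack_price must be > 0 (outlet {self.outlet_id}, "
                f"medicine {self.medicine_id}, got {self.pack_price})"
            )
        if int(self.pack_size) < 1:
            raise ValidationError(
                f"pack_size must be >= 1 (outlet {self.outlet_id}, "
                f"medicine {self.medicine_id}, got {self.pack_size})"
            )
        object.__setattr__(self, "pack_size", int(self.pack_size))


@dataclass(frozen=True)
class ProcurementRecord:
    """One tendered product: quoted unit price, quantity, INCO term."""

    medicine_id: str
    product_label: str
    origin: Origin
    unit_price_quoted: Decimal
    quantity: int
    inco_term: IncoTerm = IncoTerm.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", Origin(self.origin))
        object.__setattr__(self, "inco_term", IncoTerm(self.inco_term))
        object.__setattr__(
            self, "unit_price_quoted", as_decimal(self.unit_price_quoted, what="unit_price_quoted")
        )
        if self.unit_price_quoted <= 0:
            raise ValidationError(
                f"unit_price_quoted must be > 0 (medicine {self.medicine_id})"
            )
        if int(self.quantity) < 0:
            raise ValidationError(f"quantity must be >= 0 (medicine {self.medicine_id})")
        object.__setattr__(self, "quantity", int(self.quantity))
        if self.origin is Origin.LOCAL and self.inco_term is not IncoTerm.NONE:
            raise ValidationError(
                f"locally produced products carry no INCO term "
                f"(medicine {self.medicine_id}, got {self.inco_term.value})"
            )


class ReferencePriceTable:
    """Per-medicine international reference prices, USD per dose unit."""

    def __init__(self, prices: Mapping[str, Decimal | str | float]):
        self._prices: dict[str, Decimal] = {}
        for mid, value in prices.items():
            dec = as_decimal(value, what=f"IRP for {mid}")
            if dec <= 0:
                raise ValidationError(f"IRP for {mid} must be > 0, got {dec}")
            self._prices[str(mid)] = dec

    def __getitem__(self, medicine_id: str) -> Decimal:
        try:
            return self._prices[medicine_id]
        except KeyError:
            raise IntegrityError(f"no reference price for medicine {medicine_id!r}") from None

    def __contains__(self, medicine_id: str) -> bool:
        return medicine_id in self._prices

    def __iter__(self) -> Iterator[str]:
        return iter(self._prices)

    def __len__(self) -> int:
        return len(self._prices)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferencePriceTable) and self._prices == other._prices

    def items(self):
        return self._prices.items()

    def check_covers(self, medicine_ids: Iterable[str]) -> None:
        missing = sorted(set(medicine_ids) - set(self._prices))
        if missing:
            raise IntegrityError(f"reference price table missing medicines: {missing}")


@dataclass(frozen=True)
class SurchargeSchedule:
    """Additive landed-cost surcharges per INCO term.

    Each term maps to named percentage components (freight, insurance, bank
    charges, import duty ...).  The landed-cost factor for a term is
    ``1 + sum(percents)/100`` — components add, they do not compound.
    """

    components: Mapping[IncoTerm, tuple[tuple[str, Decimal], ...]]

    def __post_init__(self) -> None:
        normalized: dict[IncoTerm, tuple[tuple[str, Decimal], ...]] = {}
        for term, comps in dict(self.components).items():
            term = IncoTerm(term)
            items = tuple((str(name), as_decimal(pct, what=f"{term.value} surcharge {name}"))
                          for name, pct in comps)
            for name, pct in items:
                if pct < 0:
                    raise ConfigurationError(
                        f"surcharge {name} for {term.value} must be >= 0, got {pct}"
                    )
            normalized[term] = items
        object.__setattr__(self, "components", normalized)

    def total_percent(self, term: IncoTerm) -> Decimal:
        term = IncoTerm(term)
        if term is IncoTerm.NONE:
            return Decimal(0)
        if term not in self.components:
            raise ConfigurationError(f"no surcharge schedule for INCO term {term.value!r}")
        return sum((pct for _, pct in self.components[term]), Decimal(0))

    def factor(self, term: IncoTerm) -> Decimal:
        """Multiplicative landed-cost factor, e.g. 1.22 for a 22% surcharge."""
        return Decimal(1) + self.total_percent(term) / Decimal(100)


#: Surcharge schedule used for the Ethiopian tender analysis: quotes that
#: exclude freight (FOB/FCA) attract 15% freight + 0.5% insurance + 1.5% bank
#: charges + 5% import duty (22% total); quotes including freight (CFR)
#: attract the remaining 7%.
ETHIOPIA_SCHEDULE = SurchargeSchedule(
    {
        IncoTerm.FOB: (
            ("freight", Decimal("15")),
            ("insurance", Decimal("0.5")),
            ("bank_charges", Decimal("1.5")),
            ("import_duty", Decimal("5")),
        ),
        IncoTerm.FCA: (
            ("freight", Decimal("15")),
            ("insurance", Decimal("0.5")),
            ("bank_charges", Decimal("1.5")),
            ("import_duty", Decimal("5")),
        ),
        IncoTerm.CFR: (
            ("insurance", Decimal("0.5")),
            ("bank_charges", Decimal("1.5")),
            ("import_duty", Decimal("5")),
        ),
    }
)


@dataclass(frozen=True)
class SurveyConfig:
    """Country parameters needed by every analysis stage.

    exchange_rate
        Local currency units per USD on the first day of data collection;
        used to convert IRPs (USD per unit) to local currency.
    surcharge_schedule
        INCO-term landed-cost surcharges for tender quotes.
    preference_margin_pct
        Maximum percentage by which a local bid may exceed the lowest import
        bid under the national local-preference procurement policy.
    min_price_points_patient / min_price_points_procurement
        Minimum number of outlet price points required before a median price
        ratio is reported (4 for patient prices, 1 for tenders).
    """

    exchange_rate: Decimal
    surcharge_schedule: SurchargeSchedule = ETHIOPIA_SCHEDULE
    preference_margin_pct: float = 25.0
    min_price_points_patient: int = 4
    min_price_points_procurement: int = 1
    country: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "exchange_rate", as_decimal(self.exchange_rate, what="exchange_rate"))
        if self.exchange_rate <= 0:
            raise ConfigurationError(f"exchange_rate must be > 0, got {self.exchange_rate}")
        if self.min_price_points_patient < 1 or self.min_price_points_procurement < 1:
            raise ConfigurationError("inclusion thresholds must be >= 1")
        if self.preference_margin_pct < 0:
            raise ConfigurationError("preference_margin_pct must be >= 0")


@dataclass(frozen=True)
class SurveyDataset:
    """A validated survey: outlet census, medicine list and price records.

    Referential integrity is checked eagerly at construction so downstream
    stages never see a dangling reference.
    """

    outlets: tuple[Outlet, ...]
    medicines: tuple[Medicine, ...]
    prices: tuple[PriceRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlets", tuple(self.outlets))
        object.__setattr__(self, "medicines", tuple(self.medicines))
        object.__setattr__(self, "prices", tuple(self.prices))
        self._validate()

    def _validate(self) -> None:
        outlet_ids = [o.outlet_id for o in self.outlets]
        if len(set(outlet_ids)) != len(outlet_ids):
            dupes = sorted({x for x in outlet_ids if outlet_ids.count(x) > 1})
            raise ValidationError(f"duplicate outlet_id values: {dupes}")
        med_ids = [m.medicine_id for m in self.medicines]
        if len(set(med_ids)) != len(med_ids):
            dupes = sorted({x for x in med_ids if med_ids.count(x) > 1})
            raise ValidationError(f"duplicate medicine_id values: {dupes}")
        med_keys = [m.key for m in self.medicines]
        if len(set(med_keys)) != len(med_keys):
            raise ValidationError("duplicate (name, strength, dosage_form) medicine keys")

        outlet_by_id = {o.outlet_id: o for o in self.outlets}
        known_meds = set(med_ids)
        bad_rows = [
            i for i, r in enumerate(self.prices)
            if r.outlet_id not in outlet_by_id or r.medicine_id not in known_meds
        ]
        if bad_rows:
            raise IntegrityError(
                f"price records reference unknown outlets/medicines at rows {bad_rows}"
            )
        bad_local = [
            i for i, r in enumerate(self.prices)
            if r.origin is Origin.LOCAL
            and r.country_of_manufacture != outlet_by_id[r.outlet_id].country
        ]
        if bad_local:
            raise ValidationError(
                "locally produced products must be manufactured in the survey "
                f"country; offending price rows: {bad_local}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def outlet_by_id(self) -> dict[str, Outlet]:
        return {o.outlet_id: o for o in self.outlets}

    @property
    def medicine_by_id(self) -> dict[str, Medicine]:
        return {m.medicine_id: m for m in self.medicines}

    def outlets_in(self, sector: Sector) -> list[Outlet]:
        sector = Sector(sector)
        return [o for o in self.outlets if o.sector is sector]

    def prices_frame(self) -> pd.DataFrame:
        """Price records as a DataFrame (prices as floats, for analysis)."""
        sectors = {o.outlet_id: o.sector.value for o in self.outlets}
        regions = {o.outlet_id: o.region for o in self.outlets}
        return pd.DataFrame(
            {
                "outlet_id": [r.outlet_id for r in self.prices],
                "sector": [sectors[r.outlet_id] for r in self.prices],
                "region": [regions[r.outlet_id] for r in self.prices],
                "medicine_id": [r.medicine_id for r in self.prices],
                "product_label": [r.product_label for r in self.prices],
                "origin": [r.origin.value for r in self.prices],
                "product_type": [r.product_type.value for r in self.prices],
                "unit_price": [float(r.pack_price) / r.pack_size for r in self.prices],
            }
        )

    def subset_sector(self, sector: Sector) -> "SurveyDataset":
        sector = Sector(sector)
        keep = {o.outlet_id for o in self.outlets_in(sector)}
        return SurveyDataset(
            outlets=tuple(o for o in self.outlets if o.outlet_id in keep),
            medicines=self.medicines,
            prices=tuple(r for r in self.prices if r.outlet_id in keep),
        )
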