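"""Synthetic survey generator with known ground truth.

The original field datasets behind this kind of survey are rarely deposited,
so every analysis stage here is exercised against synthetic countries whose
true parameters are known.  The generator emulates the survey structure: six
regions per country, a few dozen outlets per sector, a national list of 25
strength-specific medicines, and — per outlet, medicine and origin — zero or
more products in stock, each with a pack price and a product type.

Model
-----
* A product of a given origin is present in an outlet with probability
  ``availability_prob`` (independent across outlets and medicines).
* When present, the number of distinct same-origin products is drawn from
  {1, 2, 3} with configurable weights, exercising the within-outlet
  median-unit-price rule.
* Unit prices are log-normal around a median of
  ``target_mpr x IRP_usd x exchange_rate`` with a given coefficient of
  variation; prices are positive and right-skewed, and the median — the
  quantity the analysis estimates — is parameterised directly.
* Tender prices are generated per origin around procurement MPR targets
  derived from the public patient targets and configurable mark-up targets
  (patient MPR = mark-up x procurement MPR); imported tender lines carry
  INCO terms and are quoted such that their *landed* price hits the target.

A single integer seed determines everything; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model import (
    IncoTerm,
    Medicine,
    Origin,
    Outlet,
    PriceRecord,
    ProcurementRecord,
    ProductType,
    ReferencePriceTable,
    Sector,
    SurveyConfig,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "StratumParams",
    "GeneratorSpec",
    "GroundTruth",
    "ProcurementTruth",
    "generate",
    "generate_procurement",
    "SURVEY_MEDICINES",
]

# The 25-medicine national survey list (Ethiopian list): INN, strength, form.
SURVEY_MEDICINES: tuple[tuple[str, str, str], ...] = (
    ("Acetyl salicylic acid", "300 mg", "tab/cap"),
    ("Albendazole", "100 mg/5 ml", "suspension"),
    ("Amoxicillin", "250 mg", "tab/cap"),
    ("Amoxicillin", "500 mg", "tab/cap"),
    ("Chloramphenicol", "250 mg", "tab/cap"),
    ("Ciprofloxacin", "500 mg", "tab/cap"),
    ("Diclofenac", "50 mg", "tab/cap"),
    ("Doxycycline", "100 mg", "tab/cap"),
    ("Erythromycin", "250 mg", "tab/cap"),
    ("Paracetamol", "120 mg/5 ml", "suspension"),
    ("Paracetamol", "500 mg", "tab/cap"),
    ("Sulfamethoxazole + Trimethoprim", "400 mg + 80 mg", "tab/cap"),
    ("Tetracycline", "250 mg", "tab/cap"),
    ("Amitriptyline", "25 mg", "tab/cap"),
    ("Benzathine penicillin", "2.4 MIU", "injection"),
    ("Chloroquine", "50 mg/5 ml", "syrup"),
    ("Enalapril", "10 mg", "tab/cap"),
    ("Fluoxetine", "20 mg", "tab/cap"),
    ("Furosemide", "40 mg", "tab/cap"),
    ("Glibenclamide", "5 mg", "tab/cap"),
    ("Ibuprofen", "400 mg", "tab/cap"),
    ("Metoclopramide", "5 mg/5 ml", "syrup"),
    ("Metronidazole", "250 mg", "tab/cap"),
    ("Phenobarbitone", "100 mg", "tab/cap"),
    ("Sodium chloride", "0.9% 1 L", "IV solution"),
)


@dataclass(frozen=True)
class StratumParams:
    """Per (sector, origin) generating parameters.

    target_mpr
        True median price ratio: median unit price / (IRP x exchange rate).
    price_cv
        Coefficient of variation of the log-normal unit-price noise.
    availability_prob
        Probability an outlet stocks >= 1 product of this origin.
    product_type_mix
        Probabilities of (originator brand, branded generic, INN generic).
    """

    target_mpr: float
    price_cv: float = 0.15
    availability_prob: float = 0.5
    product_type_mix: tuple[float, float, float] = (0.0, 0.7, 0.3)

    def validate(self, where: str) -> None:
        if self.target_mpr <= 0:
            raise ValidationError(f"{where}: target_mpr must be > 0")
        if self.price_cv < 0:
            raise ValidationError(f"{where}: price_cv must be >= 0")
        if not 0.0 <= self.availability_prob <= 1.0:
            raise ValidationError(f"{where}: availability_prob must be in [0, 1]")
        if any(p < 0 for p in self.product_type_mix):
            raise ValidationError(f"{where}: product_type_mix must be non-negative")
        if abs(sum(self.product_type_mix) - 1.0) > 1e-9:
            raise ValidationError(f"{where}: product_type_mix must sum to 1")


def _default_params() -> dict[tuple[Sector, Origin], StratumParams]:
    # Defaults emulate the Ethiopian survey conditions: local products dearer
    # but more available in the public sector; imports far dearer in the
    # private sector.  Type mixes follow the observed dominance of branded
    # generics; originator brands appear only among private-sector imports.
    return {
        (Sector.PUBLIC, Origin.LOCAL): StratumParams(1.44, 0.15, 0.48, (0.0, 0.73, 0.27)),
        (Sector.PUBLIC, Origin.IMPORTED): StratumParams(1.18, 0.15, 0.19, (0.0, 0.5, 0.5)),
        (Sector.PRIVATE, Origin.LOCAL): StratumParams(1.85, 0.15, 0.54, (0.0, 0.76, 0.24)),
        (Sector.PRIVATE, Origin.IMPORTED): StratumParams(5.42, 0.15, 0.35, (0.22, 0.71, 0.07)),
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one synthetic country."""

    seed: int = 0
    n_regions: int = 6
    outlets_per_sector_per_region: Mapping[Sector, int] = field(
        default_factory=lambda: {Sector.PUBLIC: 6, Sector.PRIVATE: 5}
    )
    n_medicines: int = 25
    country: str = "Synthetica"
    exchange_rate: Decimal = Decimal("18.73")  # local currency per USD
    params: Mapping[tuple[Sector, Origin], StratumParams] = field(default_factory=_default_params)
    medicine_overrides: Mapping[tuple[str, Sector, Origin], StratumParams] = field(
        default_factory=dict
    )
    multiplicity_weights: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1), P(2), P(3) products
    pack_sizes: tuple[int, ...] = (10, 20, 30, 100)
    irp_usd: Mapping[str, Decimal] | None = None  # drawn log-uniformly if absent
    # Tender generation.
    markup_target: Mapping[Origin, float] = field(
        default_factory=lambda: {Origin.LOCAL: 1.17, Origin.IMPORTED: 1.53}
    )
    procurement_target_mpr: Mapping[Origin, float] | None = None
    procurement_price_cv: float = 0.05
    procurement_prob: Mapping[Origin, float] = field(
        default_factory=lambda: {Origin.LOCAL: 21 / 25, Origin.IMPORTED: 12 / 25}
    )
    local_line_weights: tuple[float, ...] = (0.25, 0.30, 0.25, 0.12, 0.08)  # 1..5 products
    import_inco_weights: Mapping[IncoTerm, float] = field(
        default_factory=lambda: {IncoTerm.FOB: 0.45, IncoTerm.FCA: 0.25, IncoTerm.CFR: 0.30}
    )
    quantity_range: tuple[int, int] = (100_000, 50_000_000)

    def validate(self) -> None:
        if self.n_regions < 1 or self.n_medicines < 1:
            raise ValidationError("n_regions and n_medicines must be >= 1")
        if self.n_medicines > len(SURVEY_MEDICINES):
            raise ValidationError(
                f"n_medicines must be <= {len(SURVEY_MEDICINES)} (the survey list length)"
            )
        if Decimal(str(self.exchange_rate)) <= 0:
            raise ValidationError("exchange_rate must be > 0")
        for key, params in {**dict(self.params), **dict(self.medicine_overrides)}.items():
            params.validate(where=str(key))
        for name, weights in (
            ("multiplicity_weights", self.multiplicity_weights),
            ("local_line_weights", self.local_line_weights),
            ("import_inco_weights", tuple(self.import_inco_weights.values())),
        ):
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
        for origin, p in self.procurement_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"procurement_prob[{origin}] must be in [0, 1]")
        for origin, m in self.markup_target.items():
            if m <= 0:
                raise ValidationError(f"markup_target[{origin}] must be > 0")

    # -- derived configuration -------------------------------------------------

    def stratum(self, medicine_id: str, sector: Sector, origin: Origin) -> StratumParams:
        override = dict(self.medicine_overrides).get((medicine_id, sector, origin))
        return override if override is not None else dict(self.params)[(sector, origin)]

    def procurement_targets(self) -> dict[Origin, float]:
        if self.procurement_target_mpr is not None:
            return dict(self.procurement_target_mpr)
        return {
            origin: dict(self.params)[(Sector.PUBLIC, origin)].target_mpr
            / dict(self.markup_target)[origin]
            for origin in Origin
        }


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a generated dataset."""

    exchange_rate: Decimal
    country: str
    irp: ReferencePriceTable
    target_mpr: Mapping[tuple[str, Sector, Origin], float]
    availability_prob: Mapping[tuple[str, Sector, Origin], float]
    markup_target: Mapping[Origin, float]
    procurement_target_mpr: Mapping[Origin, float]

    def survey_config(self, **overrides) -> SurveyConfig:
        kwargs = dict(exchange_rate=self.exchange_rate, country=self.country)
        kwargs.update(overrides)
        return SurveyConfig(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        payload = {
            "country": self.country,
            "exchange_rate": str(self.exchange_rate),
            "irp_usd_per_unit": {m: str(p) for m, p in self.irp.items()},
            "target_mpr": {
                f"{mid}/{sec.value}/{orig.value}": v
                for (mid, sec, orig), v in self.target_mpr.items()
            },
            "availability_prob": {
                f"{mid}/{sec.value}/{orig.value}": v
                for (mid, sec, orig), v in self.availability_prob.items()
            },
            "markup_target": {o.value: v for o, v in self.markup_target.items()},
            "procurement_target_mpr": {
                o.value: v for o, v in self.procurement_target_mpr.items()
            },
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
        return path


@dataclass(frozen=True)
class ProcurementTruth:
    """Known cheapest origin (by landed median price) per paired medicine."""

    target_mpr: Mapping[Origin, float]
    cheaper_origin: Mapping[str, Origin | None]
    n_paired: int


SIX_DP = Decimal("0.000001")
FOUR_DP = Decimal("0.0001")


def _sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _medicines(spec: GeneratorSpec) -> tuple[Medicine, ...]:
    return tuple(
        Medicine(f"M{i + 1:02d}", name, strength, form)
        for i, (name, strength, form) in enumerate(SURVEY_MEDICINES[: spec.n_medicines])
    )


def _irp(spec: GeneratorSpec, medicines: Sequence[Medicine]) -> ReferencePriceTable:
    if spec.irp_usd is not None:
        table = ReferencePriceTable(dict(spec.irp_usd))
        table.check_covers(m.medicine_id for m in medicines)
        return table
    # Reference prices are drawn once per seed, log-uniform over a realistic
    # per-unit range for essential generics (0.01-0.50 USD per dose unit).
    rng = np.random.default_rng([int(spec.seed), 7])
    prices = {}
    for m in medicines:
        usd = math.exp(rng.uniform(math.log(0.01), math.log(0.5)))
        prices[m.medicine_id] = Decimal(repr(usd)).quantize(FOUR_DP)
    return ReferencePriceTable(prices)


def _weighted_index(u: float, weights: Sequence[float]) -> int:
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1


_IMPORT_COUNTRIES = ("India", "China", "Kenya")


def generate(spec: GeneratorSpec) -> tuple[SurveyDataset, GroundTruth]:
    """Generate one synthetic country survey and its ground truth."""
    spec.validate()
    medicines = _medicines(spec)
    irp = _irp(spec, medicines)
    fx = Decimal(str(spec.exchange_rate))
    rng = np.random.default_rng([int(spec.seed), 0])

    outlets: list[Outlet] = []
    per_region = dict(spec.outlets_per_sector_per_region)
    for sector in Sector:
        n_per = int(per_region.get(sector, per_region.get(sector.value, 0)))
        for region_i in range(1, spec.n_regions + 1):
            for k in range(1, n_per + 1):
                outlets.append(
                    Outlet(
                        outlet_id=f"{sector.value[:3].upper()}-R{region_i}-{k:02d}",
                        sector=sector,
                        region=f"Region-{region_i}",
                        country=spec.country,
                    )
                )

    prices: list[PriceRecord] = []
    target_mpr: dict[tuple[str, Sector, Origin], float] = {}
    avail_prob: dict[tuple[str, Sector, Origin], float] = {}
    for med in medicines:
        for sector in Sector:
            for origin in Origin:
                p = spec.stratum(med.medicine_id, sector, origin)
                target_mpr[(med.medicine_id, sector, origin)] = p.target_mpr
                avail_prob[(med.medicine_id, sector, origin)] = p.availability_prob

    types = tuple(ProductType)
    for outlet in outlets:
        for med in medicines:
            for origin in Origin:
                p = spec.stratum(med.medicine_id, outlet.sector, origin)
                if rng.random() >= p.availability_prob:
                    continue
                n_products = 1 + _weighted_index(rng.random(), spec.multiplicity_weights)
                base = Decimal(str(p.target_mpr)) * irp[med.medicine_id] * fx
                sigma = _sigma(p.price_cv)
                for j in range(1, n_products + 1):
                    ptype = types[_weighted_index(rng.random(), p.product_type_mix)]
                    pack_size = spec.pack_sizes[int(rng.integers(len(spec.pack_sizes)))]
                    if origin is Origin.LOCAL:
                        made_in = spec.country
                    else:
                        made_in = _IMPORT_COUNTRIES[int(rng.integers(len(_IMPORT_COUNTRIES)))]
                    if sigma > 0:
                        noise = Decimal(repr(math.exp(sigma * rng.standard_normal())))
                    else:
                        noise = Decimal(1)
                    pack_price = (base * noise * pack_size).quantize(
                        SIX_DP, rounding=ROUND_HALF_EVEN
                    )
                    prices.append(
                        PriceRecord(
                            outlet_id=outlet.outlet_id,
                            medicine_id=med.medicine_id,
                            product_label=f"{med.medicine_id}-{origin.value}-{j}",
                            origin=origin,
                            product_type=ptype,
                            country_of_manufacture=made_in,
                            pack_price=pack_price,
                            pack_size=pack_size,
                        )
                    )

    dataset = SurveyDataset(outlets=tuple(outlets), medicines=medicines, prices=tuple(prices))
    truth = GroundTruth(
        exchange_rate=fx,
        country=spec.country,
        irp=irp,
        target_mpr=target_mpr,
        availability_prob=avail_prob,
        markup_target=dict(spec.markup_target),
        procurement_target_mpr=spec.procurement_targets(),
    )
    return dataset, truth


def generate_procurement(
    spec: GeneratorSpec,
) -> tuple[list[ProcurementRecord], ProcurementTruth]:
    """Generate government tender records consistent with ``generate``.

    Imported lines are quoted under an INCO term such that the *landed* price
    (after the standard surcharge schedule) is log-normal around the
    procurement target median; local lines need no adjustment.  The returned
    truth records which origin was actually cheaper (landed medians) for each
    medicine tendered in both origins.
    """
    from .model import ETHIOPIA_SCHEDULE

    spec.validate()
    medicines = _medicines(spec)
    irp = _irp(spec, medicines)
    fx = Decimal(str(spec.exchange_rate))
    rng = np.random.default_rng([int(spec.seed), 1])
    targets = spec.procurement_targets()
    sigma = _sigma(spec.procurement_price_cv)
    q_lo, q_hi = spec.quantity_range
    inco_terms = tuple(spec.import_inco_weights)
    inco_weights = tuple(spec.import_inco_weights.values())

    records: list[ProcurementRecord] = []
    cheaper: dict[str, Origin | None] = {}
    for med in medicines:
        landed_by_origin: dict[Origin, list[float]] = {}
        for origin in Origin:
            if rng.random() >= dict(spec.procurement_prob)[origin]:
                continue
            if origin is Origin.LOCAL:
                n_lines = 1 + _weighted_index(rng.random(), spec.local_line_weights)
            else:
                n_lines = 1
            base = Decimal(str(targets[origin])) * irp[med.medicine_id] * fx
            landed: list[float] = []
            for j in range(1, n_lines + 1):
                noise = (
                    Decimal(repr(math.exp(sigma * rng.standard_normal())))
                    if sigma > 0
                    else Decimal(1)
                )
                landed_price = base * noise
                if origin is Origin.IMPORTED:
                    term = inco_terms[_weighted_index(rng.random(), inco_weights)]
                    quoted = (landed_price / ETHIOPIA_SCHEDULE.factor(term)).quantize(FOUR_DP)
                else:
                    term = IncoTerm.NONE
                    quoted = landed_price.quantize(FOUR_DP)
                quantity = int(
                    round(math.exp(rng.uniform(math.log(q_lo), math.log(q_hi))))
                )
                records.append(
                    ProcurementRecord(
                        medicine_id=med.medicine_id,
                        product_label=f"{med.medicine_id}-tender-{origin.value}-{j}",
                        origin=origin,
                        unit_price_quoted=quoted,
                        quantity=quantity,
                        inco_term=term,
                    )
                )
                landed.append(float(quoted * ETHIOPIA_SCHEDULE.factor(term)))
            landed_by_origin[origin] = landed
        if len(landed_by_origin) == 2:
            med_local = float(np.median(landed_by_origin[Origin.LOCAL]))
            med_imp = float(np.median(landed_by_origin[Origin.IMPORTED]))
            if med_local < med_imp:
                cheaper[med.medicine_id] = Origin.LOCAL
            elif med_imp < med_local:
                cheaper[med.medicine_id] = Origin.IMPORTED
            else:
                cheaper[med.medicine_id] = None

    truth = ProcurementTruth(
        target_mpr=targets, cheaper_origin=cheaper, n_paired=len(cheaper)
    )
    return records, truth
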