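"""Reading and writing the survey's tabular formats.

All files are UTF-8, comma-separated CSV with a mandatory header row and "."
as the decimal mark.  Monetary columns are serialized as decimal strings so a
write/read cycle reproduces every field bit-for-bit.

File contracts
--------------
outlets.csv       outlet_id,sector,region,country
medicines.csv     medicine_id,name,strength,dosage_form
prices.csv        outlet_id,medicine_id,product_label,origin,product_type,
                  country_of_manufacture,pack_price,pack_size
procurement.csv   medicine_id,product_label,origin,unit_price_quoted,quantity,inco_term
irp.csv           medicine_id,irp_usd_per_unit
config.yaml       exchange_rate, surcharge_schedule, preference_margin_pct,
                  min_price_points_patient, min_price_points_procurement
"""

from __future__ import annotations

from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Sequence

import pandas as pd
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
    SchemaError,
    Sector,
    SurchargeSchedule,
    SurveyConfig,
    SurveyDataset,
    ValidationError,
)

OUTLET_COLUMNS = ["outlet_id", "sector", "region", "country"]
MEDICINE_COLUMNS = ["medicine_id", "name", "strength", "dosage_form"]
PRICE_COLUMNS = [
    "outlet_id",
    "medicine_id",
    "product_label",
    "origin",
    "product_type",
    "country_of_manufacture",
    "pack_price",
    "pack_size",
]
PROCUREMENT_COLUMNS = [
    "medicine_id",
    "product_label",
    "origin",
    "unit_price_quoted",
    "quantity",
    "inco_term",
]
IRP_COLUMNS = ["medicine_id", "irp_usd_per_unit"]


def _read_frame(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _decimal(value: str, *, where: str) -> Decimal:
    try:
        return Decimal(value)
    except InvalidOperation:
        raise ValidationError(f"{where}: not a decimal number: {value!r}") from None


def _int(value: str, *, where: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{where}: not an integer: {value!r}") from None


def _enum(cls, value: str, *, where: str):
    try:
        return cls(value)
    except ValueError:
        allowed = [e.value for e in cls]
        raise ValidationError(f"{where}: {value!r} not one of {allowed}") from None


def read_survey(price_csv, outlet_csv, medicine_csv) -> SurveyDataset:
    """Read and validate a survey; referential integrity is enforced."""
    outlets_df = _read_frame(outlet_csv, OUTLET_COLUMNS)
    meds_df = _read_frame(medicine_csv, MEDICINE_COLUMNS)
    prices_df = _read_frame(price_csv, PRICE_COLUMNS)

    outlets = tuple(
        Outlet(r.outlet_id, _enum(Sector, r.sector, where=f"outlets.csv row {i}"),
               r.region, r.country)
        for i, r in enumerate(outlets_df.itertuples(index=False))
    )
    medicines = tuple(
        Medicine(r.medicine_id, r.name, r.strength, r.dosage_form)
        for r in meds_df.itertuples(index=False)
    )
    prices = []
    for i, r in enumerate(prices_df.itertuples(index=False)):
        where = f"prices.csv row {i}"
        prices.append(
            PriceRecord(
                outlet_id=r.outlet_id,
                medicine_id=r.medicine_id,
                product_label=r.product_label,
                origin=_enum(Origin, r.origin, where=where),
                product_type=_enum(ProductType, r.product_type, where=where),
                country_of_manufacture=r.country_of_manufacture,
                pack_price=_decimal(r.pack_price, where=where),
                pack_size=_int(r.pack_size, where=where),
            )
        )
    return SurveyDataset(outlets=outlets, medicines=tuple(medicines), prices=tuple(prices))


def read_procurement(csv_path) -> list[ProcurementRecord]:
    """Read government tender records; unknown INCO terms are rejected."""
    df = _read_frame(csv_path, PROCUREMENT_COLUMNS)
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        where = f"procurement.csv row {i}"
        records.append(
            ProcurementRecord(
                medicine_id=r.medicine_id,
                product_label=r.product_label,
                origin=_enum(Origin, r.origin, where=where),
                unit_price_quoted=_decimal(r.unit_price_quoted, where=where),
                quantity=_int(r.quantity, where=where),
                inco_term=_enum(IncoTerm, r.inco_term, where=where),
            )
        )
    return records


def read_irp(csv_path) -> ReferencePriceTable:
    df = _read_frame(csv_path, IRP_COLUMNS)
    return ReferencePriceTable(
        {
            r.medicine_id: _decimal(r.irp_usd_per_unit, where=f"irp.csv row {i}")
            for i, r in enumerate(df.itertuples(index=False))
        }
    )


def write_survey(dataset: SurveyDataset, out_dir) -> dict[str, Path]:
    """Write outlets.csv, medicines.csv and prices.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "outlets": out / "outlets.csv",
        "medicines": out / "medicines.csv",
        "prices": out / "prices.csv",
    }
    pd.DataFrame(
        [(o.outlet_id, o.sector.value, o.region, o.country) for o in dataset.outlets],
        columns=OUTLET_COLUMNS,
    ).to_csv(paths["outlets"], index=False)
    pd.DataFrame(
        [(m.medicine_id, m.name, m.strength, m.dosage_form) for m in dataset.medicines],
        columns=MEDICINE_COLUMNS,
    ).to_csv(paths["medicines"], index=False)
    pd.DataFrame(
        [
            (
                r.outlet_id,
                r.medicine_id,
                r.product_label,
                r.origin.value,
                r.product_type.value,
                r.country_of_manufacture,
                str(r.pack_price),
                r.pack_size,
            )
            for r in dataset.prices
        ],
        columns=PRICE_COLUMNS,
    ).to_csv(paths["prices"], index=False)
    return paths


def write_procurement(records: Sequence[ProcurementRecord], csv_path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (
                r.medicine_id,
                r.product_label,
                r.origin.value,
                str(r.unit_price_quoted),
                r.quantity,
                r.inco_term.value,
            )
            for r in records
        ],
        columns=PROCUREMENT_COLUMNS,
    ).to_csv(csv_path, index=False)
    return csv_path


def write_irp(irp: ReferencePriceTable, csv_path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(mid, str(price)) for mid, price in irp.items()], columns=IRP_COLUMNS
    ).to_csv(csv_path, index=False)
    return csv_path


def read_config(yaml_path) -> SurveyConfig:
    with open(yaml_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "exchange_rate" not in raw:
        raise SchemaError(f"{yaml_path}: config must define exchange_rate")
    schedule_raw = raw.get("surcharge_schedule", {})
    schedule = SurchargeSchedule(
        {
            IncoTerm(term): tuple((name, Decimal(str(pct))) for name, pct in comps)
            for term, comps in schedule_raw.items()
        }
    )
    return SurveyConfig(
        exchange_rate=Decimal(str(raw["exchange_rate"])),
        surcharge_schedule=schedule,
        preference_margin_pct=float(raw.get("preference_margin_pct", 25.0)),
        min_price_points_patient=int(raw.get("min_price_points_patient", 4)),
        min_price_points_procurement=int(raw.get("min_price_points_procurement", 1)),
        country=str(raw.get("country", "")),
    )


def write_config(config: SurveyConfig, yaml_path) -> Path:
    yaml_path = Path(yaml_path)
    yaml_path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "country": config.country,
        "exchange_rate": str(config.exchange_rate),
        "preference_margin_pct": config.preference_margin_pct,
        "min_price_points_patient": config.min_price_points_patient,
        "min_price_points_procurement": config.min_price_points_procurement,
        "surcharge_schedule": {
            term.value: [[name, float(pct)] for name, pct in comps]
            for term, comps in config.surcharge_schedule.components.items()
        },
    }
    with open(yaml_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return yaml_path


def write_table(df: pd.DataFrame, path, fmt: str = "csv") -> Path:
    """Write a report table as CSV or a GitHub-style markdown pipe table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "markdown":
        cols = [str(c) for c in df.columns]
        lines = ["| " + " | ".join(cols) + " |",
                 "| " + " | ".join("---" for _ in cols) + " |"]
        for row in df.itertuples(index=False):
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return path
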