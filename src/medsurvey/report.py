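"""Paired local/imported comparisons, mark-ups and country report tables.

The headline questions — do patients pay more for locally produced products,
and how much of the patient price is government mark-up? — are answered by
pairing: a medicine enters a paired comparison only when both its local and
its imported products passed the MPR inclusion rules in that sector.  Percent
differences are computed from the 2-decimal MPRs as they appear in report
tables (the unrounded engine values remain available), and a mark-up ratio is
the patient-price MPR over the procurement-price MPR for the same medicine
and origin, summarized as the median across paired medicines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import availability as avail
from .model import (
    Origin,
    ProductType,
    ReferencePriceTable,
    Sector,
    SurveyConfig,
    SurveyDataset,
    ProcurementRecord,
    ValidationError,
)
from .prices import (
    MedicineMprSummary,
    MprResult,
    compute_mpr_summaries,
    sector_summary,
)
from .procurement import (
    compare_all,
    preference_check,
    procurement_mpr_summaries,
    savings_if_cheapest,
)
from .stats import median, round_half_up

__all__ = [
    "PairedOrigins",
    "PairedPatientComparison",
    "MarkupSummary",
    "pair_origins",
    "percent_difference",
    "format_percent_difference",
    "paired_patient_comparison",
    "markup_ratio",
    "markup_summary",
    "CountryReport",
    "build_country_report",
]


@dataclass(frozen=True)
class PairedOrigins:
    pairs: tuple[tuple[MedicineMprSummary, MedicineMprSummary], ...]  # (local, imported)
    only_local: tuple[MedicineMprSummary, ...]
    only_imported: tuple[MedicineMprSummary, ...]

    @property
    def n_paired(self) -> int:
        return len(self.pairs)


def pair_origins(
    local: list[MedicineMprSummary], imported: list[MedicineMprSummary]
) -> PairedOrigins:
    """Match local and imported summaries on medicine; annotate the unpaired."""
    loc = {s.medicine_id: s for s in local}
    imp = {s.medicine_id: s for s in imported}
    shared = sorted(set(loc) & set(imp))
    return PairedOrigins(
        pairs=tuple((loc[m], imp[m]) for m in shared),
        only_local=tuple(loc[m] for m in sorted(set(loc) - set(imp))),
        only_imported=tuple(imp[m] for m in sorted(set(imp) - set(loc))),
    )


def percent_difference(mpr_a: float, mpr_b: float) -> int:
    """Signed integer percent difference of ``a`` relative to ``b``.

    ``round_half_up(100 x (a/b - 1))``; a value of +22 reads "a is 22% more
    than b", -20 reads "a is 20% lower".  Rounding is half-up with ties away
    from zero, so the rendered magnitude of a negative difference equals
    ``round_half_up(100 x (1 - a/b))``.
    """
    if mpr_b <= 0:
        raise ValidationError(f"reference MPR must be > 0, got {mpr_b}")
    return round_half_up(100.0 * (mpr_a / mpr_b - 1.0))


def format_percent_difference(mpr_a: float, mpr_b: float) -> str:
    diff = percent_difference(mpr_a, mpr_b)
    if diff > 0:
        return f"{diff}% more"
    if diff < 0:
        return f"{-diff}% lower"
    return "no difference"


@dataclass(frozen=True)
class PairedPatientComparison:
    sector: Sector
    n_paired_medicines: int
    median_mpr_local: float | None
    median_mpr_imported: float | None
    pct_difference: int | None  # local relative to imported


def paired_patient_comparison(
    paired: PairedOrigins, sector: Sector, *, rounded: bool = True
) -> PairedPatientComparison:
    """Median MPR per origin across the paired medicines, and their gap.

    With ``rounded=True`` (the reporting default) the percent difference is
    taken on the 2-decimal medians as printed in the tables.
    """
    if paired.n_paired == 0:
        return PairedPatientComparison(Sector(sector), 0, None, None, None)
    med_local = median([p[0].median_mpr for p in paired.pairs])
    med_imported = median([p[1].median_mpr for p in paired.pairs])
    a, b = (
        (round_half_up(med_local, 2), round_half_up(med_imported, 2))
        if rounded
        else (med_local, med_imported)
    )
    return PairedPatientComparison(
        sector=Sector(sector),
        n_paired_medicines=paired.n_paired,
        median_mpr_local=med_local,
        median_mpr_imported=med_imported,
        pct_difference=percent_difference(a, b),
    )


@dataclass(frozen=True)
class MarkupSummary:
    origin: Origin
    n_paired_medicines: int
    median_ratio: float | None  # patient MPR / procurement MPR
    n_excluded: int


def markup_ratio(patient: MedicineMprSummary, procurement: MedicineMprSummary) -> float:
    """Patient-price MPR over procurement-price MPR for one medicine+origin."""
    if patient.medicine_id != procurement.medicine_id or patient.origin is not procurement.origin:
        raise ValidationError("markup_ratio requires the same medicine and origin")
    if procurement.median_mpr <= 0:
        raise ValidationError("procurement MPR must be > 0")
    return patient.median_mpr / procurement.median_mpr


def markup_summary(
    patient: list[MedicineMprSummary],
    procurement: list[MedicineMprSummary],
    origin: Origin,
) -> MarkupSummary:
    """Median across medicines of the patient/procurement MPR ratio."""
    origin = Origin(origin)
    pat = {s.medicine_id: s for s in patient if s.origin is origin}
    proc = {s.medicine_id: s for s in procurement if s.origin is origin}
    shared = sorted(set(pat) & set(proc))
    ratios = [markup_ratio(pat[m], proc[m]) for m in shared]
    n_excluded = len(set(pat) ^ set(proc))
    return MarkupSummary(
        origin=origin,
        n_paired_medicines=len(shared),
        median_ratio=median(ratios) if ratios else None,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Country report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountryReport:
    """Deterministic table set for one country's survey.

    tables
        name -> DataFrame; every cell traces to an engine call.  MPRs are
        printed to 2 decimals, availability and percent differences to
        integers, mark-up ratios to 2 decimals.
    """

    tables: dict[str, pd.DataFrame]
    run_log: dict

    def write(self, out_dir, fmt: str = "csv") -> dict[str, Path]:
        from .io import write_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ext = "csv" if fmt == "csv" else "md"
        paths = {}
        for name, df in self.tables.items():
            paths[name] = write_table(df, out / f"{name}.{ext}", fmt=fmt)
        return paths


def _r2(x: float | None):
    return None if x is None else round_half_up(x, 2)


def _mpr_block(result: MprResult, sector: Sector) -> pd.DataFrame:
    rows = []
    for origin in Origin:
        summ = sector_summary([s for s in result.included if s.origin is origin])
        lo, hi = summ.iqr_across_medicines or (None, None)
        rows.append(
            {
                "sector": sector.value,
                "origin": origin.value,
                "n_medicines": summ.n_medicines,
                "n_products": summ.n_products,
                "median_mpr": _r2(summ.median_of_median_mpr),
                "iqr_low": _r2(lo),
                "iqr_high": _r2(hi),
            }
        )
    return pd.DataFrame(rows)


def _availability_block(dataset: SurveyDataset, sector: Sector) -> pd.DataFrame:
    rows = [
        {
            "sector": sector.value,
            "stratum": "all_products",
            "mean_availability_pct": round_half_up(avail.mean_availability(dataset, sector)),
        }
    ]
    for origin in Origin:
        rows.append(
            {
                "sector": sector.value,
                "stratum": origin.value,
                "mean_availability_pct": round_half_up(
                    avail.mean_availability(dataset, sector, origin=origin)
                ),
            }
        )
        for ptype in ProductType:
            rows.append(
                {
                    "sector": sector.value,
                    "stratum": f"{origin.value}_{ptype.value}",
                    "mean_availability_pct": round_half_up(
                        avail.mean_availability(dataset, sector, origin=origin, product_type=ptype)
                    ),
                }
            )
    return pd.DataFrame(rows)


def _by_type_block(
    dataset: SurveyDataset, irp: ReferencePriceTable, config: SurveyConfig, sector: Sector
) -> pd.DataFrame:
    """Unpaired analysis of prices by product type (table footnote style)."""
    rows = []
    for ptype in ProductType:
        result = compute_mpr_summaries(
            dataset, irp, config, sector, "patient", product_types=[ptype]
        )
        for origin in Origin:
            summ = sector_summary([s for s in result.included if s.origin is origin])
            rows.append(
                {
                    "sector": sector.value,
                    "analysis": "unpaired_by_product_type",
                    "product_type": ptype.value,
                    "origin": origin.value,
                    "n_medicines": summ.n_medicines,
                    "n_products": summ.n_products,
                    "median_mpr": _r2(summ.median_of_median_mpr),
                }
            )
    return pd.DataFrame(rows)


def build_country_report(
    dataset: SurveyDataset,
    procurement: list[ProcurementRecord],
    irp: ReferencePriceTable,
    config: SurveyConfig,
) -> CountryReport:
    """Assemble the full country summary from the analysis engines.

    Produces: a procurement MPR block; availability by origin and product
    type per sector; paired patient-price MPRs with the local/imported
    percent difference; the unpaired by-product-type price analysis; the
    patient-vs-procurement mark-up table; and the procurement origin
    comparison with quantity shares, hypothetical savings and the
    local-preference policy check.
    """
    tables: dict[str, pd.DataFrame] = {}
    log: dict = {"exclusions": {}}

    # Procurement price block (public tenders).
    proc_result = procurement_mpr_summaries(procurement, irp, config)
    tables["procurement_mpr"] = _mpr_block(proc_result, Sector.PUBLIC)
    log["exclusions"]["procurement"] = len(proc_result.excluded)

    # Availability and patient prices per sector.
    patient_included: dict[Sector, MprResult] = {}
    avail_rows, paired_rows, type_rows, patient_rows = [], [], [], []
    for sector in Sector:
        avail_rows.append(_availability_block(dataset, sector))
        result = compute_mpr_summaries(dataset, irp, config, sector, "patient")
        patient_included[sector] = result
        log["exclusions"][f"patient_{sector.value}"] = len(result.excluded)
        paired = pair_origins(
            [s for s in result.included if s.origin is Origin.LOCAL],
            [s for s in result.included if s.origin is Origin.IMPORTED],
        )
        paired_meds = {p[0].medicine_id for p in paired.pairs}
        comparison = paired_patient_comparison(paired, sector)
        for origin, stats in (
            (Origin.LOCAL, [p[0] for p in paired.pairs]),
            (Origin.IMPORTED, [p[1] for p in paired.pairs]),
        ):
            summ = sector_summary(stats) if stats else None
            per_med_iqr = (
                (_r2(median([s.iqr_low for s in stats])), _r2(median([s.iqr_high for s in stats])))
                if stats
                else (None, None)
            )
            patient_rows.append(
                {
                    "sector": sector.value,
                    "origin": origin.value,
                    "analysis": "paired",
                    "n_medicines": len(stats),
                    "n_products": sum(s.n_products for s in stats),
                    "median_mpr": _r2(
                        comparison.median_mpr_local
                        if origin is Origin.LOCAL
                        else comparison.median_mpr_imported
                    ),
                    "median_iqr_low": per_med_iqr[0],
                    "median_iqr_high": per_med_iqr[1],
                }
            )
        paired_rows.append(
            {
                "sector": sector.value,
                "n_paired_medicines": comparison.n_paired_medicines,
                "median_mpr_local": _r2(comparison.median_mpr_local),
                "median_mpr_imported": _r2(comparison.median_mpr_imported),
                "pct_difference_local_vs_imported": comparison.pct_difference,
                "n_only_local": len(paired.only_local),
                "n_only_imported": len(paired.only_imported),
            }
        )
        log.setdefault("paired_medicines", {})[sector.value] = sorted(paired_meds)
        type_rows.append(_by_type_block(dataset, irp, config, sector))

    tables["availability"] = pd.concat(avail_rows, ignore_index=True)
    tables["patient_mpr_paired"] = pd.DataFrame(patient_rows)
    tables["paired_comparison"] = pd.DataFrame(paired_rows)
    tables["patient_mpr_by_type"] = pd.concat(type_rows, ignore_index=True)

    # Mark-up: public patient prices vs procurement prices, per origin.
    markup_rows = []
    for origin in Origin:
        summ = markup_summary(
            list(patient_included[Sector.PUBLIC].included),
            list(proc_result.included),
            origin,
        )
        markup_rows.append(
            {
                "origin": origin.value,
                "n_paired_medicines": summ.n_paired_medicines,
                "median_patient_to_procurement_ratio": _r2(summ.median_ratio),
            }
        )
    tables["markup"] = pd.DataFrame(markup_rows)

    # Procurement origin comparison, savings and policy check.
    comparisons = compare_all(procurement, config.surcharge_schedule)
    comp_rows = []
    for cmp in comparisons:
        from .procurement import quantity_share

        recs = [r for r in procurement if r.medicine_id == cmp.medicine_id]
        shares = (
            quantity_share(recs) if sum(r.quantity for r in recs) > 0 else {o: None for o in Origin}
        )
        comp_rows.append(
            {
                "medicine_id": cmp.medicine_id,
                "paired": cmp.paired,
                "local_median_landed": _r2(cmp.local.median_unit_price) if cmp.local else None,
                "imported_median_landed": _r2(cmp.imported.median_unit_price)
                if cmp.imported
                else None,
                "cheaper_origin": cmp.cheaper_origin.value if cmp.cheaper_origin else None,
                "pct_local_premium": cmp.pct_local_premium,
                "local_quantity_share_pct": shares[Origin.LOCAL],
                "imported_quantity_share_pct": shares[Origin.IMPORTED],
                "preference_status": preference_check(cmp, config.preference_margin_pct).value,
            }
        )
    tables["procurement_comparison"] = pd.DataFrame(comp_rows)

    savings = savings_if_cheapest(comparisons, config.exchange_rate)
    tables["procurement_savings"] = pd.DataFrame(
        [
            {
                "n_medicines_with_savings": savings.n_medicines,
                "n_skipped": savings.n_skipped,
                "savings_local_currency": round_half_up(savings.local_currency, 2),
                "savings_usd": round_half_up(savings.usd, 2),
            }
        ]
    )

    log["n_outlets"] = {s.value: len(dataset.outlets_in(s)) for s in Sector}
    log["n_medicines"] = len(dataset.medicines)
    log["n_price_records"] = len(dataset.prices)
    log["n_procurement_records"] = len(procurement)
    return CountryReport(tables=tables, run_log=log)
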