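"""Pairing, percent differences, mark-ups and country report assembly."""

import pytest

import medsurvey as ms
from medsurvey.model import Origin, Sector
from medsurvey.prices import MedicineMprSummary
from medsurvey.report import (
    format_percent_difference,
    markup_ratio,
    markup_summary,
    pair_origins,
    paired_patient_comparison,
    percent_difference,
)


def summ(mid, mpr, origin=Origin.LOCAL, sector=Sector.PUBLIC, n_products=5):
    return MedicineMprSummary(mid, sector, origin, 4, n_products, mpr, mpr * 0.9, mpr * 1.1)


def test_pair_origins_identical_sets_all_paired():
    local = [summ(f"M{i:02d}", 1.2) for i in range(5)]
    imported = [summ(f"M{i:02d}", 1.1, origin=Origin.IMPORTED) for i in range(5)]
    paired = pair_origins(local, imported)
    assert paired.n_paired == 5
    assert not paired.only_local and not paired.only_imported


def test_pair_origins_disjoint_sets_zero_paired():
    local = [summ("M01", 1.2)]
    imported = [summ("M02", 1.1, origin=Origin.IMPORTED)]
    paired = pair_origins(local, imported)
    assert paired.n_paired == 0
    assert len(paired.only_local) == 1 and len(paired.only_imported) == 1


def test_pair_origins_accounts_for_every_input_medicine():
    """25 medicines, 10 co-available: 10 pairs and no silent drops."""
    local = [summ(f"M{i:02d}", 1.4) for i in range(1, 19)]  # M01..M18
    imported = [summ(f"M{i:02d}", 1.2, origin=Origin.IMPORTED) for i in range(9, 26)]  # M09..M25
    paired = pair_origins(local, imported)
    assert paired.n_paired == 10
    assert paired.n_paired + len(paired.only_local) == len(local)
    assert paired.n_paired + len(paired.only_imported) == len(imported)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (1.44, 1.18, 22),
        (5.42, 1.85, 193),
        (1.44, 1.35, 7),
        (4.33, 1.71, 153),
        (2.97, 2.01, 48),
        (2.38, 2.97, -20),
        (2.38, 2.07, 15),
        (1.67, 2.20, -24),
        (1.0, 1.0, 0),
    ],
)
def test_percent_difference_on_printed_ratios(a, b, expected):
    assert percent_difference(a, b) == expected


def test_percent_difference_rendering():
    assert format_percent_difference(1.44, 1.18) == "22% more"
    assert format_percent_difference(2.38, 2.97) == "20% lower"
    assert format_percent_difference(2.0, 2.0) == "no difference"


def test_percent_difference_requires_positive_reference():
    with pytest.raises(ms.ValidationError):
        percent_difference(1.0, 0.0)


def test_paired_patient_comparison_medians_and_gap():
    local = [summ(f"M{i}", v) for i, v in enumerate([1.40, 1.44, 1.50])]
    imported = [summ(f"M{i}", v, origin=Origin.IMPORTED) for i, v in enumerate([1.10, 1.18, 1.30])]
    cmp = paired_patient_comparison(pair_origins(local, imported), Sector.PUBLIC)
    assert cmp.median_mpr_local == pytest.approx(1.44)
    assert cmp.median_mpr_imported == pytest.approx(1.18)
    assert cmp.pct_difference == 22


def test_markup_ratio_examples():
    patient = summ("M01", 1.17)
    proc = summ("M01", 1.00)
    assert markup_ratio(patient, proc) == pytest.approx(1.17)
    assert markup_ratio(patient, patient) == pytest.approx(1.0)
    with pytest.raises(ms.ValidationError):
        markup_ratio(summ("M01", 1.0), summ("M02", 1.0))


def test_markup_summary_is_median_of_ratios_over_shared_medicines():
    patient = [summ(f"M{i}", v) for i, v in enumerate([2.0, 3.0, 4.0, 9.9])]
    proc = [summ(f"M{i}", 2.0) for i in range(3)]  # M3 has no procurement side
    out = markup_summary(patient, proc, Origin.LOCAL)
    assert out.n_paired_medicines == 3
    assert out.median_ratio == pytest.approx(1.5)  # median of 1.0, 1.5, 2.0
    assert out.n_excluded == 1


def _small_country(seed=21):
    spec = ms.GeneratorSpec(seed=seed, n_medicines=8)
    ds, truth = ms.generate(spec)
    tenders, _ = ms.generate_procurement(spec)
    return ds, tenders, truth


def test_country_report_is_deterministic(tmp_path):
    outputs = []
    for sub in ("x", "y"):
        ds, tenders, truth = _small_country()
        report = ms.build_country_report(ds, tenders, truth.irp, truth.survey_config())
        paths = report.write(tmp_path / sub)
        outputs.append({name: p.read_bytes() for name, p in paths.items()})
    assert outputs[0] == outputs[1]


def test_noiseless_country_report_hits_configured_targets():
    """With no price noise the report's MPR cells equal the configured targets."""
    from medsurvey.synthetic import StratumParams

    params = {
        (s, o): StratumParams(
            target_mpr={Origin.LOCAL: 1.44, Origin.IMPORTED: 1.18}[o],
            price_cv=0.0,
            availability_prob=1.0,
            product_type_mix=(0, 1, 0),
        )
        for s in Sector
        for o in Origin
    }
    spec = ms.GeneratorSpec(
        seed=4, n_medicines=5, params=params, multiplicity_weights=(1.0, 0.0, 0.0)
    )
    ds, truth = ms.generate(spec)
    tenders, _ = ms.generate_procurement(spec)
    report = ms.build_country_report(ds, tenders, truth.irp, truth.survey_config())
    paired = report.tables["paired_comparison"]
    for _, row in paired.iterrows():
        assert row["median_mpr_local"] == pytest.approx(1.44, abs=0.005)
        assert row["median_mpr_imported"] == pytest.approx(1.18, abs=0.005)
        assert row["pct_difference_local_vs_imported"] == 22
    avail = report.tables["availability"]
    all_products = avail[avail["stratum"] == "all_products"]
    assert (all_products["mean_availability_pct"] == 100).all()


def test_report_run_log_counts_inputs():
    ds, tenders, truth = _small_country(seed=22)
    report = ms.build_country_report(ds, tenders, truth.irp, truth.survey_config())
    assert report.run_log["n_price_records"] == len(ds.prices)
    assert report.run_log["n_procurement_records"] == len(tenders)
    assert set(report.run_log["n_outlets"]) == {"public", "private"}
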