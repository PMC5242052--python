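"""Unit prices, outlet medians and MPR inclusion rules."""

from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

import medsurvey as ms
from medsurvey.model import Origin, Sector
from medsurvey.prices import (
    MedicineMprSummary,
    MprExclusion,
    medicine_mpr,
    outlet_median_price,
    sector_summary,
    unit_price,
)
from conftest import make_price
from oracles import sorted_median, type7_quantile


@pytest.mark.parametrize(
    "pack_price,pack_size,expected",
    [("10.00", 10, "1"), ("7.30", 10, "0.73"), ("0.6580", 1, "0.6580")],
)
def test_unit_price_examples(pack_price, pack_size, expected):
    rec = make_price(pack_price=pack_price, pack_size=pack_size)
    assert unit_price(rec) == Decimal(expected)


@given(
    price=st.decimals(min_value=Decimal("0.01"), max_value=Decimal("9999"), places=4),
    size=st.integers(1, 1000),
)
def test_unit_price_times_pack_size_recovers_pack_price(price, size):
    rec = make_price(pack_price=str(price), pack_size=size)
    back = unit_price(rec) * size
    assert abs(back - price) <= Decimal("1e-20") * price


@pytest.mark.parametrize(
    "values,expected",
    [([1.0], 1.0), ([1.0, 2.0, 4.0], 2.0), ([1.0, 2.0], 1.5), ([4.0, 1.0, 2.0, 3.0], 2.5)],
)
def test_outlet_median_interpolates_even_counts(values, expected):
    assert outlet_median_price(values) == expected


def test_outlet_median_rejects_empty():
    with pytest.raises(ValueError):
        outlet_median_price([])


def test_mpr_of_one_means_price_equals_reference(config):
    fx_price = float(Decimal("0.05") * config.exchange_rate)
    result = medicine_mpr([fx_price] * 4, Decimal("0.05"), config, "patient")
    assert isinstance(result, MedicineMprSummary)
    assert result.median_mpr == pytest.approx(1.0)
    assert result.iqr_low == pytest.approx(1.0)
    assert result.n_price_points == 4


def test_patient_context_requires_four_price_points(config):
    result = medicine_mpr([1.0, 2.0, 3.0], Decimal("0.05"), config, "patient")
    assert isinstance(result, MprExclusion)
    assert "4" in result.reason


def test_procurement_context_accepts_a_single_price(config):
    result = medicine_mpr([1.0], Decimal("0.05"), config, "procurement")
    assert isinstance(result, MedicineMprSummary)
    assert result.n_price_points == 1


def test_nonpositive_irp_is_a_configuration_error(config):
    with pytest.raises(ms.ConfigurationError):
        medicine_mpr([1.0] * 4, Decimal("0"), config)


@pytest.mark.parametrize("k", ["0.01", "1", "137"])
def test_mpr_invariant_under_joint_currency_rescaling(k, config):
    """Multiplying all prices and the exchange rate by k leaves MPRs unchanged."""
    k_dec = Decimal(k)
    medians = [1.1, 2.3, 3.7, 4.1, 8.9]
    base = medicine_mpr(medians, Decimal("0.07"), config, "patient")
    scaled_cfg = ms.SurveyConfig(
        exchange_rate=config.exchange_rate * k_dec, country=config.country
    )
    scaled = medicine_mpr(
        [m * float(k_dec) for m in medians], Decimal("0.07"), scaled_cfg, "patient"
    )
    assert scaled.median_mpr == pytest.approx(base.median_mpr, rel=1e-12)
    assert scaled.iqr_low == pytest.approx(base.iqr_low, rel=1e-12)
    assert scaled.iqr_high == pytest.approx(base.iqr_high, rel=1e-12)


@given(
    outlet_prices=st.lists(
        st.lists(st.floats(0.1, 100.0), min_size=1, max_size=4), min_size=4, max_size=6
    ),
    bump=st.floats(0.1, 50.0),
    data=st.data(),
)
def test_raising_any_single_price_never_decreases_the_mpr(config, outlet_prices, bump, data):
    irp = Decimal("0.10")

    def mpr_from_raw(lists):
        medians = [outlet_median_price(p) for p in lists]
        return medicine_mpr(medians, irp, config, "patient").median_mpr

    i = data.draw(st.integers(0, len(outlet_prices) - 1))
    j = data.draw(st.integers(0, len(outlet_prices[i]) - 1))
    raised = [list(p) for p in outlet_prices]
    raised[i][j] += bump
    assert mpr_from_raw(raised) >= mpr_from_raw(outlet_prices) - 1e-12


@given(
    outlet_prices=st.lists(
        st.lists(st.floats(0.1, 100.0), min_size=1, max_size=4), min_size=1, max_size=6
    )
)
def test_median_of_medians_matches_brute_force(config, outlet_prices):
    irp = Decimal("0.10")
    denom = float(irp * config.exchange_rate)
    medians = [outlet_median_price(p) for p in outlet_prices]
    got = medicine_mpr(medians, irp, config, "procurement").median_mpr
    expected = sorted_median([sorted_median(p) for p in outlet_prices]) / denom
    assert got == pytest.approx(expected, rel=1e-12)


def _summary(mid, mpr, n_products=3, sector=Sector.PUBLIC, origin=Origin.LOCAL):
    return MedicineMprSummary(mid, sector, origin, 4, n_products, mpr, mpr, mpr)


def test_sector_summary_single_medicine_degenerate_iqr():
    summ = sector_summary([_summary("M01", 1.2)])
    assert summ.median_of_median_mpr == 1.2
    assert summ.iqr_across_medicines == (1.2, 1.2)
    assert summ.n_medicines == 1


def test_sector_summary_matches_percentile_oracle():
    mprs = [1.1, 0.8, 2.3, 1.9, 1.4, 0.7, 3.1, 1.05, 1.65, 2.8]
    summaries = [_summary(f"M{i:02d}", v) for i, v in enumerate(mprs)]
    summ = sector_summary(summaries)
    assert summ.median_of_median_mpr == pytest.approx(sorted_median(mprs))
    assert summ.iqr_across_medicines[0] == pytest.approx(type7_quantile(mprs, 0.25))
    assert summ.iqr_across_medicines[1] == pytest.approx(type7_quantile(mprs, 0.75))
    assert summ.n_products == 30


def test_sector_summary_empty_sentinel():
    summ = sector_summary([])
    assert summ.n_medicines == 0 and summ.median_of_median_mpr is None


def test_exclusion_accounting_covers_every_candidate_cell(tiny_dataset, config):
    irp = ms.ReferencePriceTable({"M01": "0.05", "M02": "0.03"})
    result = ms.compute_mpr_summaries(tiny_dataset, irp, config, Sector.PUBLIC, "patient")
    candidates = {
        (r.medicine_id, r.origin)
        for r in tiny_dataset.prices
        if r.outlet_id in {o.outlet_id for o in tiny_dataset.outlets_in(Sector.PUBLIC)}
    }
    assert len(result.included) + len(result.excluded) == len(candidates)
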