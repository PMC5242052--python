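"""Landed-cost adjustment, origin comparison, savings and the preference policy."""

from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

import medsurvey as ms
from medsurvey.model import IncoTerm, Origin
from medsurvey.procurement import (
    PreferenceStatus,
    adjust_price,
    compare_origins,
    preference_check,
    quantity_share,
    savings_if_cheapest,
)


def rec(mid="M01", origin=Origin.LOCAL, price="1.00", qty=1000, term=IncoTerm.NONE, label=None):
    return ms.ProcurementRecord(
        mid, label or f"{origin.value}-{price}-{qty}", origin, Decimal(price), qty, term
    )


def test_adjustment_is_additive_not_compounded(schedule):
    assert adjust_price(Decimal("100"), IncoTerm.FOB, schedule) == Decimal("122.00")
    assert adjust_price(Decimal("100"), IncoTerm.FCA, schedule) == Decimal("122.00")
    assert adjust_price(Decimal("100"), IncoTerm.CFR, schedule) == Decimal("107.00")
    assert adjust_price(Decimal("3.1415"), IncoTerm.NONE, schedule) == Decimal("3.1415")


def test_adjustment_is_linear_in_the_quote(schedule):
    a = adjust_price(Decimal("7"), IncoTerm.FOB, schedule)
    b = adjust_price(Decimal("14"), IncoTerm.FOB, schedule)
    assert b == 2 * a


def test_unknown_term_is_a_configuration_error(schedule):
    with pytest.raises(ms.ConfigurationError):
        adjust_price(Decimal("1"), IncoTerm.DDP, schedule)


def test_quantity_share_single_origin_is_all_or_nothing():
    shares = quantity_share([rec(qty=5000)])
    assert shares[Origin.LOCAL] == 100.0
    assert shares[Origin.IMPORTED] == 0.0


def test_quantity_share_zero_total_is_an_error():
    with pytest.raises(ms.ValidationError):
        quantity_share([rec(qty=0)])


@given(st.lists(st.integers(0, 10**8), min_size=2, max_size=6).filter(lambda q: sum(q) > 0))
def test_quantity_shares_conserve_100_percent(quantities):
    records = [
        rec(origin=Origin.LOCAL if i % 2 == 0 else Origin.IMPORTED, qty=q, label=f"x{i}")
        for i, q in enumerate(quantities)
    ]
    exact = quantity_share(records, ndigits=None)
    assert sum(exact.values()) == pytest.approx(100.0)
    rounded = quantity_share(records)
    assert sum(rounded.values()) == pytest.approx(100.0, abs=0.1)


def test_compare_origins_premium_and_direction(schedule):
    cmp = compare_origins([rec(price="2.00"), rec(origin=Origin.IMPORTED, price="1.00")], schedule)
    assert cmp.pct_local_premium == 100
    assert cmp.cheaper_origin is Origin.IMPORTED


def test_local_at_a_third_of_the_import_price_has_negative_premium(schedule):
    cmp = compare_origins(
        [rec(price="1.00"), rec(origin=Origin.IMPORTED, price="3.00")], schedule
    )
    assert cmp.cheaper_origin is Origin.LOCAL
    assert cmp.pct_local_premium == -67  # 100 x (1/3 - 1) rounded half-up


def test_compare_applies_landed_adjustment_before_comparing(schedule):
    # Quoted import 0.95 FOB lands at 1.159 > local 1.00.
    cmp = compare_origins(
        [rec(price="1.00"), rec(origin=Origin.IMPORTED, price="0.95", term=IncoTerm.FOB)],
        schedule,
    )
    assert cmp.cheaper_origin is Origin.LOCAL
    assert cmp.imported.median_unit_price == pytest.approx(float(Decimal("0.95") * Decimal("1.22")))


def test_single_origin_medicine_is_unpaired(schedule):
    cmp = compare_origins([rec()], schedule)
    assert not cmp.paired and cmp.cheaper_origin is None and cmp.pct_local_premium is None


def test_cheaper_origin_counts_match_brute_force_recount(schedule):
    records = []
    # 9 medicines: 8 with dearer local product, 1 with cheaper local product.
    for i in range(1, 9):
        records += [
            rec(mid=f"M{i:02d}", price="2.00", qty=1000),
            rec(mid=f"M{i:02d}", origin=Origin.IMPORTED, price="1.00", qty=500),
        ]
    records += [
        rec(mid="M09", price="1.00", qty=1000),
        rec(mid="M09", origin=Origin.IMPORTED, price="3.00", qty=500),
    ]
    comparisons = ms.compare_all(records, schedule)
    n_import_cheaper = sum(c.cheaper_origin is Origin.IMPORTED for c in comparisons)
    # brute force straight off the records
    by_med = {}
    for r in records:
        by_med.setdefault(r.medicine_id, {})[r.origin] = float(r.unit_price_quoted)
    brute = sum(p[Origin.IMPORTED] < p[Origin.LOCAL] for p in by_med.values())
    assert n_import_cheaper == brute == 8
    savings = savings_if_cheapest(comparisons, exchange_rate=Decimal("18.73"))
    assert savings.n_medicines == 9  # switching saves on all nine (one in each direction)


def test_savings_zero_when_prices_tie(schedule):
    comparisons = ms.compare_all(
        [rec(price="1.00", qty=100), rec(origin=Origin.IMPORTED, price="1.00", qty=100)],
        schedule,
    )
    savings = savings_if_cheapest(comparisons, exchange_rate=1)
    assert savings.local_currency == 0.0 and savings.n_medicines == 0


def test_savings_arithmetic_one_million_units(schedule):
    comparisons = ms.compare_all(
        [
            rec(price="1.10", qty=1_000_000),
            rec(origin=Origin.IMPORTED, price="1.00", qty=200_000),
        ],
        schedule,
    )
    savings = savings_if_cheapest(comparisons, exchange_rate=Decimal("10"))
    assert savings.local_currency == pytest.approx(100_000.0)
    assert savings.usd == pytest.approx(10_000.0)


def test_savings_invariant_to_splitting_a_line(schedule):
    whole = ms.compare_all(
        [rec(price="1.50", qty=600), rec(origin=Origin.IMPORTED, price="1.00", qty=300)],
        schedule,
    )
    split = ms.compare_all(
        [
            rec(price="1.50", qty=250, label="a"),
            rec(price="1.50", qty=350, label="b"),
            rec(origin=Origin.IMPORTED, price="1.00", qty=300),
        ],
        schedule,
    )
    assert savings_if_cheapest(whole, 1).local_currency == pytest.approx(
        savings_if_cheapest(split, 1).local_currency
    )


@pytest.mark.parametrize(
    "premium,margin,expected",
    [
        (45, 25, PreferenceStatus.EXCEEDS_MARGIN),
        (25, 25, PreferenceStatus.WITHIN_MARGIN),  # "up to 25%" is inclusive
        (-10, 25, PreferenceStatus.WITHIN_MARGIN),
        (16, 15, PreferenceStatus.EXCEEDS_MARGIN),
    ],
)
def test_preference_policy_boundary(schedule, premium, margin, expected):
    local_price = Decimal("1.00") * (1 + Decimal(premium) / 100)
    cmp = compare_origins(
        [rec(price=str(local_price)), rec(origin=Origin.IMPORTED, price="1.00")], schedule
    )
    assert preference_check(cmp, margin) is expected


def test_unpaired_preference_status(schedule):
    cmp = compare_origins([rec()], schedule)
    assert preference_check(cmp, 25) is PreferenceStatus.UNPAIRED


def test_procurement_mpr_uses_landed_prices(config):
    irp = ms.ReferencePriceTable({"M01": "0.10"})
    # quoted 0.10*fx per unit FOB -> landed MPR 1.22
    fx = config.exchange_rate
    records = [
        ms.ProcurementRecord(
            "M01", "x", Origin.IMPORTED, Decimal("0.10") * fx, 1000, IncoTerm.FOB
        )
    ]
    result = ms.procurement_mpr_summaries(records, irp, config)
    assert len(result.included) == 1
    assert result.included[0].median_mpr == pytest.approx(1.22)
    quoted = ms.procurement_mpr_summaries(records, irp, config, use_landed=False)
    assert quoted.included[0].median_mpr == pytest.approx(1.0)
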