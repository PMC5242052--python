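from __future__ import annotations

from decimal import Decimal

import pytest
from hypothesis import HealthCheck, settings

import medsurvey as ms
from medsurvey.model import Origin, ProductType, Sector

# function_scoped_fixture is safe to suppress here: the fixtures involved are
# frozen dataclasses that hypothesis examples cannot mutate.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> ms.SurveyConfig:
    return ms.SurveyConfig(exchange_rate=Decimal("18.73"), country="Synthetica")


@pytest.fixture
def schedule() -> ms.SurchargeSchedule:
    return ms.ETHIOPIA_SCHEDULE


def make_outlet(i: int, sector=Sector.PUBLIC, region="Region-1", country="Synthetica"):
    return ms.Outlet(f"O{i:02d}", sector, region, country)


def make_medicine(i: int):
    return ms.Medicine(f"M{i:02d}", f"medicine-{i}", "500 mg", "tab/cap")


def make_price(
    outlet="O01",
    medicine="M01",
    label="p1",
    origin=Origin.LOCAL,
    ptype=ProductType.BRANDED_GENERIC,
    made_in="Synthetica",
    pack_price="10.00",
    pack_size=10,
):
    return ms.PriceRecord(
        outlet_id=outlet,
        medicine_id=medicine,
        product_label=label,
        origin=origin,
        product_type=ptype,
        country_of_manufacture=made_in,
        pack_price=Decimal(pack_price),
        pack_size=pack_size,
    )


@pytest.fixture
def tiny_dataset() -> ms.SurveyDataset:
    """Four public outlets, two medicines, a handful of products."""
    outlets = [make_outlet(i) for i in range(1, 5)] + [
        make_outlet(i, sector=Sector.PRIVATE) for i in range(5, 8)
    ]
    medicines = [make_medicine(1), make_medicine(2)]
    prices = [
        make_price(outlet="O01", medicine="M01", label="a", pack_price="10.00"),
        make_price(outlet="O01", medicine="M01", label="b", pack_price="14.00"),
        make_price(
            outlet="O02", medicine="M01", label="c", origin=Origin.IMPORTED,
            made_in="India", pack_price="12.00",
        ),
        make_price(outlet="O03", medicine="M02", label="d", pack_price="5.00"),
        make_price(outlet="O05", medicine="M01", label="e", pack_price="20.00"),
    ]
    return ms.SurveyDataset(outlets=tuple(outlets), medicines=tuple(medicines), prices=tuple(prices))
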