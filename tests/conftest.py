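"""Shared fixtures: the default synthetic village, its calibration, and the
solved baseline / program states reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import villagecge as v
from villagecge.census import HouseholdRecord, VillageCensus


@pytest.fixture(scope="session")
def default_profile() -> v.CensusProfile:
    return v.CensusProfile()


@pytest.fixture(scope="session")
def census(default_profile) -> v.VillageCensus:
    return v.generate_census(default_profile, seed=42)


@pytest.fixture(scope="session")
def params(census):
    return v.calibrate(census)


@pytest.fixture(scope="session")
def flexible() -> v.ClosureRules:
    return v.ClosureRules("flexible")


@pytest.fixture(scope="session")
def fixed_wage() -> v.ClosureRules:
    return v.ClosureRules("fixed")


@pytest.fixture(scope="session")
def baseline(census, params, flexible) -> v.EquilibriumState:
    return v.solve_equilibrium(census, params, flexible, None)


@pytest.fixture(scope="session")
def scenario1(census, params, flexible):
    """Cost-effective 10% program under the flexible-wage closure."""
    pi, state = v.find_cost_effective_premium(census, params, flexible, 0.10)
    return pi, state


@pytest.fixture(scope="session")
def scenario2(census, params, fixed_wage):
    """Cost-effective 10% program under the fixed-wage closure."""
    pi, state = v.find_cost_effective_premium(census, params, fixed_wage, 0.10)
    return pi, state


def make_toy_village() -> VillageCensus:
    """Two-household village: one landlord-employer, one landless
    tenant-worker.  Baseline markets clear exactly by construction."""
    w0, r0, pm = 1.0, 18.0, 1.0
    nu, wedge = 0.70, 0.20
    shadow0 = (1 + wedge) * pm

    def record(i, land, fam, cult, rent_net, farm_lab, hired, off, transfer, flags):
        cost = r0 * cult + w0 * farm_lab
        output = cost / (nu * shadow0)
        cash = w0 * (off - hired) + r0 * (-rent_net) + transfer
        assert cash > 0
        return HouseholdRecord(
            id=i,
            land_owned=land,
            family_labor=fam,
            flags={name: name in flags for name in v.census.FLAG_NAMES},
            baseline_land_cultivated=cult,
            baseline_land_rented_net=rent_net,
            baseline_labor_hired_net=hired - off,
            baseline_farm_labor=farm_lab,
            baseline_hired_labor=hired,
            baseline_offfarm_labor=off,
            baseline_output=output,
            baseline_onfarm_consumption=output,
            baseline_market_maize=0.2 * cash / pm,
            baseline_transfer=transfer,
        )

    hh0 = record(
        0, land=5.0, fam=300.0, cult=2.0, rent_net=-3.0, farm_lab=200.0,
        hired=80.0, off=0.0, transfer=60.0,
        flags=("landholder", "maize_farmer", "subsistence", "landlord", "employer"),
    )
    hh1 = record(
        1, land=0.0, fam=460.0, cult=3.0, rent_net=3.0, farm_lab=300.0,
        hired=0.0, off=80.0, transfer=30.0,
        flags=("landless", "maize_farmer", "subsistence", "tenant", "employee"),
    )
    census = VillageCensus(
        households=[hh0, hh1],
        absentee_land=0.0,
        maize_price=pm,
        market_good_price=1.0,
        baseline_wage=w0,
        baseline_rent=r0,
    )
    census.validate()
    return census


@pytest.fixture(scope="session")
def toy_village() -> VillageCensus:
    return make_toy_village()


@pytest.fixture(scope="session")
def toy_params(toy_village):
    return v.calibrate(toy_village)
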