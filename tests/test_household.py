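"""Household decision model: optimality against brute-force oracles,
separability, shadow pricing, homogeneity, and the income effect on
subsistence production."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import villagecge as v
from villagecge.household import (
    PriceVector,
    optimal_allocation,
    shadow_price,
    net_factor_supply,
    utility,
)


def _records(census, flag):
    return [
        (i, h) for i, h in enumerate(census.households) if h.flags[flag]
    ]


def _prices(census, **kw):
    return PriceVector(
        wage=kw.get("wage", census.baseline_wage),
        rent=kw.get("rent", census.baseline_rent),
        maize_price=kw.get("maize_price", census.maize_price),
        market_good_price=kw.get("market_good_price", census.market_good_price),
        pes_rate=kw.get("pes_rate", 0.0),
    )


# ---------------------------------------------------------------------------
# separable (commercial) behaviour
# ---------------------------------------------------------------------------


def test_separable_factor_demand_slopes_down(census, params):
    i, h = _records(census, "commercial")[0]
    base = optimal_allocation(h, params[i], _prices(census))
    double = optimal_allocation(h, params[i], _prices(census, wage=2 * census.baseline_wage))
    assert double.labor_commercial < base.labor_commercial


def test_separable_production_ignores_transfers(census, params):
    """Profit-maximizing production is independent of preferences and income:
    the income effect on separable farms is exactly zero."""
    i, h = _records(census, "commercial")[0]
    a = optimal_allocation(h, params[i], _prices(census), transfer=0.0)
    b = optimal_allocation(h, params[i], _prices(census), transfer=0.3 * a.income)
    assert b.land_commercial == pytest.approx(a.land_commercial, rel=1e-12)
    assert b.labor_commercial == pytest.approx(a.labor_commercial, rel=1e-12)


def test_income_effect_on_subsistence_land_is_positive(census, params):
    """A lump-sum transfer raises a nonseparable household's demand for home
    maize and hence its land in subsistence production."""
    checked = 0
    for i, h in _records(census, "subsistence")[:10]:
        a = optimal_allocation(h, params[i], _prices(census))
        b = optimal_allocation(h, params[i], _prices(census), transfer=0.1 * a.income)
        assert b.land_subsistence >= a.land_subsistence
        assert b.land_subsistence > a.land_subsistence * (1 + 1e-8)
        checked += 1
    assert checked == 10


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.25, 4.0), idx=st.integers(0, 48))
def test_homogeneity_degree_zero(census, params, scale, idx):
    """Scaling all nominal magnitudes (wage, rent, both goods prices, the
    transfer) leaves the real allocation unchanged."""
    h = census.households[idx]
    p1 = _prices(census)
    p2 = PriceVector(
        wage=p1.wage * scale,
        rent=p1.rent * scale,
        maize_price=p1.maize_price * scale,
        market_good_price=p1.market_good_price * scale,
    )
    a = optimal_allocation(h, params[idx], p1, transfer=0.0)
    # baseline transfers scale through the record: compare at a scaled copy
    b = optimal_allocation(
        h, params[idx], p2, transfer=(scale - 1.0) * h.baseline_transfer
    )
    for field in ("land_subsistence", "labor_subsistence", "consumption_home_maize",
                  "consumption_market_maize", "consumption_market_good", "leisure"):
        assert getattr(b, field) == pytest.approx(getattr(a, field), rel=1e-9)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _grid_best_utility(h, p, prices, resolution):
    """Enumerate (land, labor) on a grid; consumption conditional on the farm
    plan is a closed-form Stone-Geary split of the residual budget."""
    t = p.tech_subsistence
    a_w, b_w, d_w, e_w = p.preferences.weights
    gamma = p.preferences.gamma
    Y = (
        prices.wage * h.family_labor
        + prices.rent * h.land_owned
        + h.baseline_transfer
    )
    land = np.arange(resolution, 3.0 * h.baseline_land_cultivated, resolution)
    labor = np.arange(
        resolution * h.family_labor,
        2.0 * h.family_labor,
        resolution * h.family_labor,
    )
    L, N = np.meshgrid(land, labor, indexing="ij")
    Q = t.A * L**t.alpha * N**t.beta
    rest = Y - prices.rent * L - prices.wage * N
    wrest = b_w + d_w + e_w
    ok = (rest > 0) & (Q > gamma)
    with np.errstate(all="ignore"):
        m = b_w * rest / (wrest * prices.maize_price)
        x = d_w * rest / (wrest * prices.market_good_price)
        leis = e_w * rest / (wrest * prices.wage)
        u = (
            a_w * np.log(Q - gamma)
            + b_w * np.log(m)
            + d_w * np.log(x)
            + e_w * np.log(leis)
        )
    u = np.where(ok & (leis <= h.family_labor), u, -np.inf)
    return float(u.max())


def test_optimizer_beats_coarse_grid(census, params):
    """Spec'd sanity oracle: on a coarse grid (5% resolution) of feasible farm
    plans the optimizer's utility is at least the best grid point."""
    i, h = _records(census, "subsistence")[0]
    prices = _prices(census)
    alloc = optimal_allocation(h, params[i], prices)
    u_opt = utility(
        params[i], alloc.consumption_home_maize, alloc.consumption_market_maize,
        alloc.consumption_market_good, alloc.leisure,
    )
    u_grid = _grid_best_utility(h, params[i], prices, resolution=0.05)
    assert u_opt >= u_grid - 1e-12


def test_optimizer_matches_fine_grid_50_trials(census, params):
    """Fine brute-force search (1% resolution) over 50 randomly perturbed
    price situations: optimizer utility within 1e-4 of the grid optimum."""
    rng = np.random.default_rng(0)
    subsistence = _records(census, "subsistence")
    for trial in range(50):
        i, h = subsistence[trial % len(subsistence)]
        f = rng.uniform(0.7, 1.3, size=3)
        prices = _prices(
            census,
            wage=census.baseline_wage * f[0],
            rent=census.baseline_rent * f[1],
            maize_price=census.maize_price * f[2],
        )
        alloc = optimal_allocation(h, params[i], prices)
        u_opt = utility(
            params[i], alloc.consumption_home_maize, alloc.consumption_market_maize,
            alloc.consumption_market_good, alloc.leisure,
        )
        u_grid = _grid_best_utility(h, params[i], prices, resolution=0.01)
        assert u_opt >= u_grid - 1e-4 * max(1.0, abs(u_grid))


def test_first_order_conditions_at_interior_optimum(census, params):
    """The home-good margin satisfies its first-order condition to 1e-8
    relative and the budget binds exactly."""
    prices = _prices(census)
    for i, h in _records(census, "subsistence")[:8]:
        p = params[i]
        alloc = optimal_allocation(h, p, prices)
        t = p.tech_subsistence
        a_w, b_w, d_w, e_w = p.preferences.weights
        q = alloc.consumption_home_maize
        cost = prices.rent * alloc.land_subsistence + prices.wage * alloc.labor_subsistence
        Y = prices.wage * h.family_labor + prices.rent * h.land_owned + h.baseline_transfer
        lhs = a_w * (Y - cost)
        rhs = (b_w + d_w + e_w) * (q - p.preferences.gamma) * cost / (t.nu * q)
        assert lhs == pytest.approx(rhs, rel=1e-8)
        spent = (
            cost
            + prices.maize_price * alloc.consumption_market_maize
            + prices.market_good_price * alloc.consumption_market_good
            + prices.wage * alloc.leisure
        )
        assert spent == pytest.approx(Y, rel=1e-10)


# ---------------------------------------------------------------------------
# shadow prices
# ---------------------------------------------------------------------------


def test_shadow_price_separable_equals_market_price(census, params):
    i, h = _records(census, "commercial")[0]
    assert shadow_price(h, params[i], _prices(census)) == census.maize_price


def test_shadow_price_rises_with_transfers(census, params):
    """Higher income raises demand for the home good and pushes its marginal
    production cost -- the shadow price -- strictly up."""
    i, h = _records(census, "subsistence")[0]
    prices = _prices(census)
    base_income = optimal_allocation(h, params[i], prices).income
    p0 = shadow_price(h, params[i], prices)
    p1 = shadow_price(h, params[i], prices, transfer=0.1 * base_income)
    assert p1 > p0


def test_shadow_price_degenerate_preferences(census, params):
    """With no utility weight on home maize (and gamma 0) the convention is
    the market maize price."""
    i, h = _records(census, "subsistence")[0]
    p = params[i]
    degenerate = v.HouseholdParams(
        regime="nonseparable",
        preferences=v.Preferences(
            (0.0,) + tuple(np.array(p.preferences.weights[1:]) /
                           sum(p.preferences.weights[1:])),
            0.0,
        ),
        tech_subsistence=p.tech_subsistence,
    )
    assert shadow_price(h, degenerate, _prices(census)) == census.maize_price


def test_calibrated_shadow_prices_exceed_market_price(census, params):
    """Net-buying subsistence households value home maize at a premium over
    the market price at the calibrated baseline."""
    prices = _prices(census)
    for i, h in _records(census, "subsistence")[:10]:
        if h.baseline_market_maize > 0:
            assert shadow_price(h, params[i], prices) >= census.maize_price


# ---------------------------------------------------------------------------
# net factor supply accounting
# ---------------------------------------------------------------------------


def test_net_factor_supply_landless_employee(census, params):
    i, h = next(
        (i, h) for i, h in _records(census, "landless") if h.flags["employee"]
    )
    alloc = optimal_allocation(h, params[i], _prices(census))
    net_land, net_labor, net_maize = net_factor_supply(alloc, h)
    assert net_land <= 0.0
    assert net_labor > 0.0


def test_net_factor_supply_autarkic_household(census):
    """A household that neither rents nor hires at the baseline has zero net
    factor supplies at its calibrated optimum."""
    from villagecge.census import HouseholdRecord, FLAG_NAMES
    from villagecge.markets import _calibrate_one

    w0, r0, pm = census.baseline_wage, census.baseline_rent, census.maize_price
    cult, farm_lab = 1.5, 180.0
    cost = r0 * cult + w0 * farm_lab
    output = cost / (0.7 * 1.2 * pm)
    h = HouseholdRecord(
        id=0, land_owned=cult, family_labor=400.0,
        flags={f: f in ("landholder", "maize_farmer", "subsistence") for f in FLAG_NAMES},
        baseline_land_cultivated=cult, baseline_land_rented_net=0.0,
        baseline_labor_hired_net=0.0, baseline_farm_labor=farm_lab,
        baseline_hired_labor=0.0, baseline_offfarm_labor=0.0,
        baseline_output=output, baseline_onfarm_consumption=output,
        baseline_market_maize=20.0, baseline_transfer=120.0,
    )
    p = _calibrate_one(h, w0, r0, pm, census.market_good_price, 0.7, 0.6)
    alloc = optimal_allocation(h, p, _prices(census))
    net_land, net_labor, _ = net_factor_supply(alloc, h)
    assert net_land == pytest.approx(0.0, abs=1e-8 * max(1.0, h.land_owned))
    assert net_labor == pytest.approx(0.0, abs=1e-8 * h.family_labor)


def test_aggregate_net_supplies_reproduce_census_balances(census, params):
    """Summing net factor supplies at the baseline optimum reproduces the
    census's rental and labor market balances."""
    prices = _prices(census)
    net_land = net_labor = 0.0
    for i, h in enumerate(census.households):
        alloc = optimal_allocation(h, params[i], prices)
        nl, nn, _ = net_factor_supply(alloc, h)
        net_land += nl
        net_labor += nn
    # local households jointly demand exactly the absentee rental supply
    assert net_land == pytest.approx(-census.absentee_land, rel=1e-9)
    assert net_labor == pytest.approx(0.0, abs=1e-7 * census.n)
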