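"""Program mechanics: voluntary enrollment, cost-effective price discovery,
and compensation variants."""

import numpy as np
import pytest

import villagecge as v
from villagecge.household import PriceVector
from villagecge.program import (
    InfeasibleTargetError,
    ProgramSpec,
    apply_compensation,
    enrollment_supply,
    find_cost_effective_premium,
)
from villagecge.accounting import real_income_change


def _baseline_prices(census):
    return PriceVector(
        wage=census.baseline_wage, rent=census.baseline_rent,
        maize_price=census.maize_price,
    )


def test_zero_premium_zero_enrollment(census, params):
    """At a payment equal to the market rent nobody enrolls: participation
    requires a strict gain over renting out."""
    res = enrollment_supply(census, params, _baseline_prices(census), premium=0.0)
    assert res.total == 0.0
    assert res.participant_count == 0


def test_negative_premium_empty_enrollment(census, params):
    res = enrollment_supply(census, params, _baseline_prices(census), premium=-0.5)
    assert res.total == 0.0


def test_saturating_premium_enrolls_all_spare_land(census, params):
    """Far above any marginal land value, all spare land of pure landlords
    and all absentee land is offered (up to the cap)."""
    res = enrollment_supply(
        census, params, _baseline_prices(census), premium=5.0, area_target=1.0
    )
    landlord = next(i for i, h in enumerate(census.households) if h.flags["landlord"])
    h = census.households[landlord]
    spare = h.land_owned - h.baseline_land_cultivated
    assert res.enrolled_local[landlord] == pytest.approx(spare, rel=0.2)
    assert res.enrolled_absentee == pytest.approx(census.absentee_land, rel=1e-6)


def test_zero_target_zero_premium(census, params, flexible):
    pi, state = find_cost_effective_premium(census, params, flexible, 0.0)
    assert pi == 0.0
    assert state.total_enrolled == 0.0


def test_cost_effective_program_leaves_no_economic_rent(census, params, flexible, scenario1):
    """At the discovered premium, the payment equals the post-program
    equilibrium rent to well under 0.1% -- participants are indifferent."""
    pi, state = scenario1
    payment = (1 + pi) * census.baseline_rent
    assert abs(payment - state.prices.rent) / state.prices.rent < 1e-3
    assert state.total_enrolled == pytest.approx(
        0.10 * census.arable_land, rel=1e-6
    )


def test_local_priority_and_landlord_participation(census, params, scenario1):
    """Local landowners contribute the bulk of the target; the landlord
    household participates with its rented-out land."""
    _, state = scenario1
    local_share = state.enrolled_local.sum() / state.enrollment_target
    assert local_share > 0.8
    landlord = next(i for i, h in enumerate(census.households) if h.flags["landlord"])
    assert state.enrolled_local[landlord] > 0


def test_premium_grid_verifies_bisection(census, params, flexible, scenario1):
    """Sweep premiums at 1e-4 resolution around the bisection solution: the
    smallest premium whose payment covers the equilibrium rent matches."""
    pi_star, _ = scenario1
    spec = ProgramSpec(area_target=0.10, price_mode="cost_effective")
    r0 = census.baseline_rent
    grid = np.arange(pi_star - 0.0015, pi_star + 0.0015, 1e-4)
    covered = []
    for p in grid:
        st = v.solve_equilibrium(census, params, flexible, spec, premium=float(p))
        covered.append((1 + p) * r0 >= st.prices.rent)
    covered = np.array(covered)
    assert covered.any() and not covered.all()
    first = grid[int(np.argmax(covered))]
    assert abs(first - pi_star) <= 2e-4


def test_supply_curve_weakly_increasing(census, params, flexible, scenario1):
    """Enrolling more land requires a weakly higher premium: the (theta,
    premium) locus is the locality's carbon-supply curve."""
    pi_10, _ = scenario1
    pi_20, _ = find_cost_effective_premium(census, params, flexible, 0.20)
    assert pi_20 >= pi_10


def test_fixed_wage_premium_not_above_flexible(census, params, scenario1, scenario2):
    """Perfectly elastic off-farm labor demand lowers the opportunity cost of
    enrollment, so the cost-effective premium is weakly smaller."""
    assert scenario2[0] <= scenario1[0]


def test_infeasible_target_raises(census, params, flexible):
    with pytest.raises(InfeasibleTargetError):
        find_cost_effective_premium(census, params, flexible, 0.95)


def test_compensation_none_when_nobody_loses(census, params, flexible, baseline):
    prog = ProgramSpec(area_target=0.0, compensation="lump_sum_to_losers")
    comp = apply_compensation(
        census, params, flexible, prog, baseline, baseline
    )
    assert comp.added_public_cost == 0.0
    assert np.all(comp.transfers == 0.0)


def test_employer_of_last_resort_holds_wage(census, params, flexible, baseline, scenario1):
    pi, state = scenario1
    prog = ProgramSpec(
        area_target=0.10, price_mode="cost_effective",
        compensation="employer_of_last_resort",
    )
    comp = apply_compensation(census, params, flexible, prog, baseline, state)
    assert comp.state.prices.wage == census.baseline_wage
    assert comp.wage_bill > 0
    assert comp.wage_bill == pytest.approx(
        census.baseline_wage * comp.state.offfarm_absorption
    )


def test_lump_sum_compensation_eliminates_losses(census, params, flexible, baseline, scenario1):
    pi, state = scenario1
    prog = ProgramSpec(
        area_target=0.10, price_mode="cost_effective",
        compensation="lump_sum_to_losers",
    )
    comp = apply_compensation(census, params, flexible, prog, baseline, state)
    change = real_income_change(census, baseline, comp.state)
    assert np.nanmin(change.currency_real) >= -1e-4 * np.abs(
        baseline.solution.income
    ).mean()
    assert comp.added_public_cost > 0


def test_incumbent_retention_under_rent_crossover(census, params, flexible, scenario1):
    """When expansion pushes market rents above the fixed payment, committed
    incumbent land stays enrolled (economic rents turn negative) rather than
    exiting mid-reform."""
    _, s1 = scenario1
    incumbents = {"local": s1.enrolled_local.copy(), "absentee": s1.enrolled_absentee}
    prog = ProgramSpec(area_target=0.16, price_mode="fixed_premium", premium=0.08)
    state = v.solve_equilibrium(
        census, params, flexible, prog, incumbents=incumbents
    )
    assert state.prices.rent > (1 + 0.08) * census.baseline_rent  # crossover
    assert state.enrolled_local.sum() > 0  # incumbents retained
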