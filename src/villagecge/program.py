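"""PES/REDD+ program mechanics.

A program sets aside arable land for forest recovery against a per-area
payment.  Landowners enroll land voluntarily whenever the payment strictly
exceeds what the land earns in its best alternative use -- the market rent
for spare (non-cultivated) owned land.  Subsistence demands bind enrollment
from below: a household never enrolls land its own optimal cultivation plan
uses, and rising incomes (including the program's own payments) pull land
back into subsistence farming.

Local landowners have priority over absentee landowners; when local supply
exceeds the target at the offered premium, local enrollments are scaled
proportionally and absentee land only fills the residual.  Within a scenario
path, incumbent participants keep committed land even if market rents later
overtake the payment (enrollment then carries negative economic rent).

``find_cost_effective_premium`` is the administrator's price discovery: the
smallest premium over the baseline rent at which the joint
enrollment/equilibrium fixed point delivers the area target.  At that price
the post-program market rent equals the payment, so economic rents vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .census import VillageCensus
from .household import HouseholdParams, PriceVector, StackedHouseholds
from .markets import (
    ClosureRules,
    EquilibriumError,
    EquilibriumState,
    _enrollment_pass,
    solve_equilibrium,
)

__all__ = [
    "ProgramSpec",
    "EnrollmentResult",
    "CompensationResult",
    "InfeasibleTargetError",
    "enrollment_supply",
    "find_cost_effective_premium",
    "apply_compensation",
]

PRICE_MODES = ("cost_effective", "fixed_premium")
PARTICIPATION = ("open", "incumbents_only")
COMPENSATION = ("none", "lump_sum_to_losers", "employer_of_last_resort")


class InfeasibleTargetError(ValueError):
    """The area target exceeds the land enrollable at any premium."""


@dataclass(frozen=True)
class ProgramSpec:
    """PES program design.

    ``area_target`` is a fraction of the village arable area (local plus
    absentee holdings); the payment rate is ``(1 + premium) * baseline rent``.
    """

    area_target: float
    price_mode: str = "cost_effective"
    premium: Optional[float] = None
    participation: str = "open"
    local_priority: bool = True
    compensation: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_target <= 1.0:
            raise ValueError("area_target must be in [0, 1]")
        if self.price_mode not in PRICE_MODES:
            raise ValueError(f"unknown price mode {self.price_mode!r}")
        if self.participation not in PARTICIPATION:
            raise ValueError(f"unknown participation rule {self.participation!r}")
        if self.compensation not in COMPENSATION:
            raise ValueError(f"unknown compensation mode {self.compensation!r}")
        if self.premium is not None and self.premium < -1.0:
            raise ValueError("premium must be >= -1")
        if self.price_mode == "fixed_premium" and self.premium is None:
            raise ValueError("fixed_premium programs must state a premium")


@dataclass
class EnrollmentResult:
    """Who supplies the program's land, and how much."""

    enrolled_local: np.ndarray  # ha per local household
    enrolled_absentee: float
    target: float
    desired_local: float  # voluntary local supply before rationing

    @property
    def total(self) -> float:
        return float(self.enrolled_local.sum() + self.enrolled_absentee)

    @property
    def participant_count(self) -> int:
        return int(np.count_nonzero(self.enrolled_local > 1e-12))

    @property
    def local_share_of_target(self) -> float:
        return float(self.enrolled_local.sum()) / self.target if self.target > 0 else 0.0


def enrollment_supply(
    census: VillageCensus,
    params: list[HouseholdParams],
    prices: PriceVector,
    premium: float,
    restriction: str = "open",
    *,
    area_target: float = 1.0,
    incumbents: Optional[dict] = None,
) -> EnrollmentResult:
    """Enrollment offered at equilibrium-consistent ``prices`` and ``premium``.

    A negative premium (payment below the market rent) yields an empty
    enrollment unless incumbents hold committed land.
    """
    spec = ProgramSpec(
        area_target=area_target,
        price_mode="fixed_premium",
        premium=premium,
        participation=restriction,
    )
    R = (1.0 + premium) * census.baseline_rent
    prices = replace_prices(prices, pes_rate=max(R, 0.0))
    sv = StackedHouseholds.from_params(census.households, params)
    _, e_loc, e_abs, info = _enrollment_pass(
        sv, prices, census, spec, np.zeros(sv.n), np.zeros(sv.n), incumbents
    )
    return EnrollmentResult(
        enrolled_local=e_loc,
        enrolled_absentee=e_abs,
        target=info.get("target", area_target * census.arable_land),
        desired_local=info.get("desired_local", 0.0),
    )


def replace_prices(prices: PriceVector, **kw) -> PriceVector:
    return PriceVector(
        wage=kw.get("wage", prices.wage),
        rent=kw.get("rent", prices.rent),
        maize_price=kw.get("maize_price", prices.maize_price),
        market_good_price=kw.get("market_good_price", prices.market_good_price),
        pes_rate=kw.get("pes_rate", prices.pes_rate),
    )


def find_cost_effective_premium(
    census: VillageCensus,
    params: list[HouseholdParams],
    closure: ClosureRules,
    area_target: float,
    *,
    tol: float = 1e-6,
    transfers: Optional[np.ndarray] = None,
    incumbents: Optional[dict] = None,
) -> tuple[float, EquilibriumState]:
    """Smallest premium at which joint equilibrium enrollment meets the area
    target.

    The search bisects on the premium: a candidate is sufficient when the
    program rate covers the post-program equilibrium rent (landowners then
    willingly supply the target, with local priority).  At the solution the
    payment equals the equilibrium rent to within the bisection tolerance, so
    economic rents are approximately zero.
    """
    if area_target <= 0:
        state = solve_equilibrium(
            census, params, closure,
            ProgramSpec(area_target=0.0), transfers=transfers,
        )
        return 0.0, state
    target_ha = area_target * census.arable_land
    spec = ProgramSpec(area_target=area_target, price_mode="cost_effective")
    r0 = census.baseline_rent

    def solve_at(pi: float) -> EquilibriumState:
        return solve_equilibrium(
            census, params, closure, spec,
            premium=pi, transfers=transfers, incumbents=incumbents,
        )

    def gap(state: EquilibriumState, pi: float) -> float:
        # positive when the payment covers the equilibrium rent
        return (1.0 + pi) * r0 - state.prices.rent

    lo, hi = 0.0, 0.25
    state_hi = solve_at(hi)
    expand = 0
    while gap(state_hi, hi) < 0 or state_hi.total_enrolled < target_ha * (1 - 1e-9):
        hi *= 2.0
        expand += 1
        if hi > 20.0 or expand > 12:
            raise InfeasibleTargetError(
                f"area target {area_target:.3f} cannot be enrolled at any premium "
                f"up to {hi:.1f}"
            )
        state_hi = solve_at(hi)
    state_lo = solve_at(lo)
    if gap(state_lo, lo) >= 0 and state_lo.total_enrolled >= target_ha * (1 - 1e-9):
        return 0.0, state_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        st = solve_at(mid)
        if gap(st, mid) >= 0:
            hi, state_hi = mid, st
        else:
            lo = mid
    return hi, state_hi


@dataclass
class CompensationResult:
    transfers: np.ndarray
    added_public_cost: float
    wage_bill: float
    state: EquilibriumState
    iterations: int = 0


def apply_compensation(
    census: VillageCensus,
    params: list[HouseholdParams],
    closure: ClosureRules,
    program: ProgramSpec,
    baseline_state: EquilibriumState,
    post_state: EquilibriumState,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CompensationResult:
    """Apply the program's compensation mode to a solved post-program state.

    ``lump_sum_to_losers`` pays every household its real-income loss as an
    unconditional transfer, iterating to a fixed point because transfers shift
    subsistence demand and hence prices.  ``employer_of_last_resort`` re-solves
    under the fixed-wage closure and charges the absorbed labor to the program
    at the baseline wage.
    """
    from . import accounting  # local import to avoid a cycle

    if program.compensation == "none":
        return CompensationResult(
            transfers=np.zeros(len(census.households)),
            added_public_cost=0.0,
            wage_bill=0.0,
            state=post_state,
        )
    if program.compensation == "employer_of_last_resort":
        state = solve_equilibrium(
            census, params, ClosureRules("fixed"), program,
            premium=post_state.premium,
        )
        wage_bill = census.baseline_wage * max(0.0, state.offfarm_absorption)
        return CompensationResult(
            transfers=np.zeros(len(census.households)),
            added_public_cost=wage_bill,
            wage_bill=wage_bill,
            state=state,
        )

    # lump_sum_to_losers: top up transfers until no household shows a
    # remaining real loss (transfers shift demand, so prices re-solve)
    n = len(census.households)
    transfers = np.zeros(n)
    state = post_state
    income_scale = float(np.abs(baseline_state.solution.income).sum()) / max(n, 1)
    residual = np.inf
    for it in range(1, max_iter + 1):
        real = accounting.real_income_change(census, baseline_state, state)
        losses = np.maximum(0.0, -real.currency_real)
        residual = float(losses.max(initial=0.0))
        if residual < tol * income_scale:
            return CompensationResult(
                transfers=transfers,
                added_public_cost=float(transfers.sum()),
                wage_bill=0.0,
                state=state,
                iterations=it,
            )
        transfers = transfers + 0.8 * losses
        state = solve_equilibrium(
            census, params, closure, program,
            premium=post_state.premium, transfers=transfers,
        )
    raise EquilibriumError(
        f"compensation fixed point did not settle after {max_iter} iterations; "
        f"largest remaining real loss {residual:.3e}"
    )
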