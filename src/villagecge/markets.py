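"""Calibration and village general equilibrium.

``calibrate`` inverts each household's first-order conditions at the baseline
prices so that the baseline census allocation is the exact optimum of the
fitted model -- the standard fixed-point construction used to calibrate
village CGE models to a household survey.

``solve_equilibrium`` clears the village factor markets.  Land always clears
locally (the arable area is fixed); the labor market clears locally under the
``flexible`` wage closure or faces a perfectly elastic outside labor demand
under the ``fixed`` closure, in which case residual labor is absorbed
off-village at the baseline wage.  Maize and the market good are traded with
the outside economy at exogenous prices, so the value of factor-market excess
demands plus the village's external account is identically zero at every
iterate (Walras' law); the solver records that residual as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .census import VillageCensus, HouseholdRecord
from .household import (
    Allocation,
    HouseholdParams,
    Preferences,
    PriceVector,
    StackedHouseholds,
    Technology,
    VillageSolution,
    solve_households,
    _to_allocation,
)

__all__ = [
    "ClosureRules",
    "EquilibriumState",
    "CalibrationError",
    "EquilibriumError",
    "calibrate",
    "solve_equilibrium",
]

#: relative excess-demand tolerance at convergence
EXCESS_TOL = 1e-8


class CalibrationError(ValueError):
    """The baseline census is inconsistent with the household model."""


class EquilibriumError(RuntimeError):
    """The market solver failed to converge; carries last residuals."""


@dataclass(frozen=True)
class ClosureRules:
    """Market closure: exactly one wage regime; land always clears locally;
    maize is always tradable at the exogenous price."""

    wage_regime: str = "flexible"  # 'flexible' | 'fixed'

    def __post_init__(self) -> None:
        if self.wage_regime not in ("flexible", "fixed"):
            raise ValueError("wage_regime must be 'flexible' or 'fixed'")


@dataclass
class EquilibriumState:
    """A cleared-market state of the village economy."""

    prices: PriceVector
    solution: VillageSolution
    closure: ClosureRules
    premium: float  # PES premium over the baseline rent (fraction)
    enrolled_local: np.ndarray
    enrolled_absentee: float
    enrollment_target: float
    excess_land: float
    excess_labor: float
    offfarm_absorption: float  # labor absorbed outside the village (fixed wage)
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def total_enrolled(self) -> float:
        return float(self.enrolled_local.sum() + self.enrolled_absentee)

    @property
    def absentee_income(self) -> float:
        return float(self.diagnostics["absentee_income"])

    def allocations(self, census: VillageCensus, params: list[HouseholdParams]) -> list[Allocation]:
        return [
            _to_allocation(h, p, self.prices, self.solution, i)
            for i, (h, p) in enumerate(zip(census.households, params))
        ]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate(
    census: VillageCensus,
    *,
    nu_subsistence: Optional[float] = None,
    gamma_fraction: float = 0.6,
) -> list[HouseholdParams]:
    """Fit per-household technology and preference parameters to the baseline.

    For subsistence (nonseparable) farms the returns to scale ``nu`` are not
    identified from a single cross-section, so they are pinned (from the
    census profile when present); the baseline shadow price then follows from
    the observed factor bill.  Commercial returns to scale are identified by
    the observed profit margin.  ``gamma_fraction`` places the Stone-Geary
    subsistence minimum at that fraction of baseline home consumption.

    Raises :class:`CalibrationError` naming the household and the violated
    constraint whenever the census is inconsistent with the model.
    """
    w0, r0 = census.baseline_wage, census.baseline_rent
    pm, px = census.maize_price, census.market_good_price
    if nu_subsistence is None:
        nu_subsistence = (
            census.profile.returns_to_scale_subsistence if census.profile else 0.70
        )
    params: list[HouseholdParams] = []
    for h in census.households:
        params.append(
            _calibrate_one(h, w0, r0, pm, px, nu_subsistence, gamma_fraction)
        )
    return params


def _calibrate_one(
    h: HouseholdRecord,
    w0: float,
    r0: float,
    pm: float,
    px: float,
    nu_s: float,
    gamma_fraction: float,
) -> HouseholdParams:
    l0 = h.baseline_land_cultivated
    n0 = h.baseline_farm_labor
    q0 = h.baseline_output
    fam_on_farm = n0 - h.baseline_hired_labor
    if fam_on_farm > h.family_labor + 1e-9:
        raise CalibrationError(
            f"household {h.id}: farm labor {n0:.1f} exceeds family endowment "
            f"plus hired labor"
        )
    leis0 = h.baseline_leisure
    if leis0 <= 0:
        raise CalibrationError(f"household {h.id}: non-positive baseline leisure")

    cash = (
        w0 * (h.baseline_offfarm_labor - h.baseline_hired_labor)
        + r0 * (-h.baseline_land_rented_net)
        + h.baseline_transfer
    )

    if l0 <= 0:  # landless non-farmer: pure consumer
        x0 = cash - pm * h.baseline_market_maize
        if x0 <= 0:
            raise CalibrationError(
                f"household {h.id}: negative market-good consumption implied by budget"
            )
        raw = np.array([0.0, pm * h.baseline_market_maize, x0, w0 * leis0])
        return HouseholdParams(
            regime="consumer",
            preferences=Preferences(tuple(raw / raw.sum()), 0.0),
        )

    cost0 = r0 * l0 + w0 * n0
    if h.flags["commercial"]:
        nu = cost0 / (pm * q0)
        if not 0 < nu < 1:
            raise CalibrationError(
                f"household {h.id}: implied returns to scale {nu:.3f} outside (0,1) "
                "(baseline commercial profit must be positive)"
            )
        alpha = nu * r0 * l0 / cost0
        beta = nu * w0 * n0 / cost0
        tech = Technology(q0 / (l0**alpha * n0**beta), alpha, beta)
        q_cons = h.baseline_onfarm_consumption
        x0 = cash + pm * (q0 - q_cons)  # sales finance purchases
        if x0 <= 0:
            raise CalibrationError(
                f"household {h.id}: negative market-good consumption implied by budget"
            )
        raw = np.array([pm * q_cons, 0.0, x0, w0 * leis0])
        return HouseholdParams(
            regime="separable",
            preferences=Preferences(tuple(raw / raw.sum()), 0.0),
            tech_commercial=tech,
        )

    # nonseparable subsistence farm
    nu = nu_s
    shadow0 = cost0 / (nu * q0)
    if shadow0 <= 0:
        raise CalibrationError(f"household {h.id}: non-positive shadow price")
    alpha = nu * r0 * l0 / cost0
    beta = nu * w0 * n0 / cost0
    tech = Technology(q0 / (l0**alpha * n0**beta), alpha, beta)
    gamma = gamma_fraction * q0
    x0 = cash - pm * h.baseline_market_maize
    if x0 <= 0:
        raise CalibrationError(
            f"household {h.id}: negative market-good consumption implied by budget"
        )
    raw = np.array(
        [shadow0 * (q0 - gamma), pm * h.baseline_market_maize, x0, w0 * leis0]
    )
    if np.any(raw < 0):
        raise CalibrationError(
            f"household {h.id}: negative utility weight implied by baseline bundle"
        )
    return HouseholdParams(
        regime="nonseparable",
        preferences=Preferences(tuple(raw / raw.sum()), gamma),
        tech_subsistence=tech,
    )


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------


def _enrollment_pass(
    sv: StackedHouseholds,
    prices: PriceVector,
    census: VillageCensus,
    program,
    transfers: np.ndarray,
    e_start: np.ndarray,
    incumbents: Optional[dict],
) -> tuple[VillageSolution, np.ndarray, float, dict]:
    """Joint fixed point of household optima and the enrollment allocation at
    fixed prices.  Returns (solution, local enrollment, absentee enrollment,
    info)."""
    n = sv.n
    r, R = prices.rent, prices.pes_rate
    if program is None or program.area_target <= 0 or R <= 0:
        sol = solve_households(sv, prices, np.zeros(n), transfers)
        return sol, np.zeros(n), 0.0, {"desired_local": 0.0, "shortfall": 0.0}

    target = program.area_target * census.arable_land
    forced = getattr(program, "price_mode", "fixed_premium") == "cost_effective"
    restricted = getattr(program, "participation", "open") == "incumbents_only"
    inc_local = (
        incumbents["local"].copy() if incumbents is not None else np.zeros(n)
    )
    strict_gain = R > r * (1.0 + 1e-12)

    e = e_start.copy()
    scale = max(1.0, census.arable_land)
    desired = np.zeros(n)
    for _ in range(120):
        sol = solve_households(sv, prices, e, transfers)
        spare = np.maximum(0.0, sv.land_owned - sol.land)
        if forced:
            desired = spare
        elif strict_gain:
            desired = spare if not restricted else np.where(inc_local > 0, spare, 0.0)
        else:
            # no strict gain: only committed (incumbent) land stays enrolled
            desired = np.minimum(inc_local, spare)
        local_total = float(desired.sum())
        inc_abs = incumbents["absentee"] if incumbents is not None else 0.0
        # absentee owners are the program's elastic fringe: whenever the
        # program pays a strictly positive premium they cover any residual
        # target; with no premium only committed absentee land stays in
        program_pays = R > census.baseline_rent * (1.0 + 1e-12)
        absentee_cap = (
            census.absentee_land if (forced or strict_gain or program_pays)
            else min(inc_abs, census.absentee_land)
        )
        if program.local_priority:
            used = min(local_total, target)
            e_new = desired * (used / local_total) if local_total > 0 else np.zeros(n)
            absentee = min(absentee_cap, target - used)
        else:
            supply = local_total + absentee_cap
            frac = min(1.0, target / supply) if supply > 0 else 0.0
            e_new = desired * frac
            absentee = absentee_cap * frac
        if np.max(np.abs(e_new - e)) < 1e-12 * scale:
            e = e_new
            break
        e = 0.5 * e + 0.5 * e_new
    sol = solve_households(sv, prices, e, transfers)
    total = float(e.sum()) + absentee
    info = {
        "desired_local": float(desired.sum()),
        "shortfall": max(0.0, target - total),
        "target": target,
    }
    return sol, e, absentee, info


def _external_account(
    census: VillageCensus,
    prices: PriceVector,
    sol: VillageSolution,
    absentee_enrolled: float,
) -> tuple[float, float]:
    """(external-good excess demand, absentee income).  Completes Walras' law:
    w*Z_labor + r*Z_land + Z_ext == 0 when every budget holds."""
    r, R = prices.rent, prices.pes_rate
    absentee_income = (
        r * (census.absentee_land - absentee_enrolled) + R * absentee_enrolled
    )
    program_outlay = R * (float(sol.enrolled.sum()) + absentee_enrolled)
    injections = program_outlay + float(
        (sol.transfer + np.asarray([h.baseline_transfer for h in census.households])).sum()
    )
    imports = (
        prices.maize_price * float(sol.m.sum() - sol.sales.sum())
        + prices.market_good_price * float(sol.x.sum())
    )
    z_ext = imports + absentee_income - injections
    return z_ext, absentee_income


def solve_equilibrium(
    census: VillageCensus,
    params: list[HouseholdParams],
    closure: ClosureRules,
    program=None,
    *,
    premium: Optional[float] = None,
    transfers: Optional[np.ndarray] = None,
    incumbents: Optional[dict] = None,
    max_iter: int = 500,
) -> EquilibriumState:
    """Solve the village equilibrium under ``closure`` and an optional PES
    program.

    ``program`` is a :class:`villagecge.program.ProgramSpec` (or None for the
    no-policy economy).  For ``fixed_premium`` programs the premium comes from
    the spec; ``premium`` overrides it (used by the cost-effective search).
    ``transfers`` are per-household lump-sum compensations; ``incumbents``
    carries enrollment commitments along a scenario path.

    Raises :class:`EquilibriumError` with the last residuals on
    non-convergence.
    """
    sv = StackedHouseholds.from_params(census.households, params)
    n = sv.n
    w0, r0 = census.baseline_wage, census.baseline_rent
    pm, px = census.maize_price, census.market_good_price
    if transfers is None:
        transfers = np.zeros(n)
    pi = 0.0
    if program is not None and program.area_target > 0:
        pi = premium if premium is not None else program.premium
        if pi is None:
            raise ValueError("fixed-premium program requires a premium")
    R = (1.0 + pi) * r0 if (program is not None and program.area_target > 0) else 0.0

    arable = census.arable_land
    total_time = float(sv.family_labor.sum())
    e_cache = {"e": np.zeros(n)}
    walras_max = {"v": 0.0}
    evals = {"n": 0}

    def evaluate(r: float, w: float):
        prices = PriceVector(wage=w, rent=r, maize_price=pm, market_good_price=px, pes_rate=R)
        sol, e_loc, e_abs, info = _enrollment_pass(
            sv, prices, census, program, transfers, e_cache["e"], incumbents
        )
        e_cache["e"] = e_loc
        total_enrolled = float(e_loc.sum()) + e_abs
        z_land = float(sol.land.sum()) + total_enrolled - arable
        z_labor = float(sol.labor.sum()) - float((sv.family_labor - sol.leisure).sum())
        z_ext, absentee_income = _external_account(census, prices, sol, e_abs)
        walras = abs(w * z_labor + r * z_land + z_ext)
        scale = abs(w0 * total_time) + abs(r0 * arable)
        walras_max["v"] = max(walras_max["v"], walras / scale)
        evals["n"] += 1
        return z_land, z_labor, sol, e_loc, e_abs, info, absentee_income, prices

    fixed_wage = closure.wage_regime == "fixed"

    # fast path: check whether the baseline already clears (no-policy economy)
    z_land, z_labor, *_ = evaluate(r0, w0)
    if abs(z_land) / arable < EXCESS_TOL and (
        fixed_wage or abs(z_labor) / total_time < EXCESS_TOL
    ):
        r_star, w_star = r0, w0
    elif fixed_wage:
        r_star = _brent_root(
            lambda r: evaluate(r, w0)[0], r0, lo=0.05 * r0, hi=20.0 * r0, max_iter=max_iter
        )
        w_star = w0
    else:

        def system(x):
            r, w = r0 * np.exp(x[0]), w0 * np.exp(x[1])
            zl, zn, *_ = evaluate(r, w)
            return [zl / arable, zn / total_time]

        res = optimize.root(system, [0.0, 0.0], method="hybr", options={"xtol": 1e-13})
        r_star, w_star = r0 * float(np.exp(res.x[0])), w0 * float(np.exp(res.x[1]))
        zl, zn, *_ = evaluate(r_star, w_star)
        if max(abs(zl) / arable, abs(zn) / total_time) > EXCESS_TOL:
            # robust fallback: nested bracketing (labor market inside land)
            def z_land_of_r(r):
                w_in = _brent_root(
                    lambda w: evaluate(r, w)[1], w0, lo=0.05 * w0, hi=20.0 * w0,
                    max_iter=max_iter,
                )
                return evaluate(r, w_in)[0], w_in

            r_star = _brent_root(
                lambda r: z_land_of_r(r)[0], r0, lo=0.05 * r0, hi=20.0 * r0,
                max_iter=max_iter,
            )
            _, w_star = z_land_of_r(r_star)

    z_land, z_labor, sol, e_loc, e_abs, info, absentee_income, prices = evaluate(
        r_star, w_star
    )
    rel_land = abs(z_land) / arable
    rel_labor = abs(z_labor) / total_time
    offfarm_absorption = 0.0
    if fixed_wage:
        offfarm_absorption = -z_labor  # absorbed by the outside labor market
        rel_labor = 0.0
    converged = max(rel_land, rel_labor) < EXCESS_TOL
    if not converged:
        raise EquilibriumError(
            f"market solver did not converge: relative excess demands "
            f"land={rel_land:.2e}, labor={rel_labor:.2e} after {evals['n']} evaluations"
        )
    return EquilibriumState(
        prices=prices,
        solution=sol,
        closure=closure,
        premium=pi,
        enrolled_local=e_loc,
        enrolled_absentee=e_abs,
        enrollment_target=info.get("target", 0.0),
        excess_land=z_land,
        excess_labor=z_labor if not fixed_wage else -offfarm_absorption,
        offfarm_absorption=offfarm_absorption,
        diagnostics={
            "converged": converged,
            "evaluations": evals["n"],
            "residual_norm": float(np.hypot(rel_land, rel_labor)),
            "walras_max": walras_max["v"],
            "enrollment_shortfall": info.get("shortfall", 0.0),
            "desired_local": info.get("desired_local", 0.0),
            "absentee_income": absentee_income,
        },
    )


def _brent_root(
    f: Callable[[float], float],
    x0: float,
    *,
    lo: float,
    hi: float,
    max_iter: int = 500,
) -> float:
    """Bracketing root finder started at ``x0`` for a decreasing market
    excess-demand function; expands the bracket geometrically if needed."""
    a, b = 0.75 * x0, 1.25 * x0
    fa, fb = f(a), f(b)
    it = 0
    while fa * fb > 0 and it < 80:
        if abs(fa) < abs(fb):
            a = max(lo, a * 0.7)
            fa = f(a)
        else:
            b = min(hi, b * 1.4)
            fb = f(b)
        if (a <= lo and b >= hi) and fa * fb > 0:
            break
        it += 1
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        raise EquilibriumError(
            f"could not bracket a market-clearing price in [{a:.4g}, {b:.4g}]; "
            f"residuals ({fa:.3e}, {fb:.3e})"
        )
    return float(
        optimize.brentq(f, a, b, xtol=1e-13 * x0, rtol=8.9e-16, maxiter=max_iter)
    )
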