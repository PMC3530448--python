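"""Farm-household decision model.

Each household maximizes utility over home-produced maize, open-market maize,
a market-purchased consumption good (the numeraire) and leisure, subject to a
full-income budget and, for farming households, a Cobb-Douglas production
technology with decreasing returns to scale (land exponent + labor exponent
< 1).

Two regimes are distinguished:

``separable`` (commercial farms)
    Maize is fully tradable at the exogenous market price, so production
    decisions are pure profit maximization and are independent of the
    household's preferences (the textbook two-stage farm-household model).

``nonseparable`` (subsistence farms)
    Home-produced maize is a household-specific non-tradable: it cannot be
    sold, and purchased maize is an imperfect substitute for it.  The
    household effectively "buys" home maize along its own convex cost curve,
    and the marginal cost at the optimum is the endogenous *shadow price* of
    subsistence output.  Because that margin moves with income, lump-sum
    transfers raise subsistence production -- the income effect that drives
    all of the policy results in this package.

Landless households are a degenerate case with no production (``consumer``
behaviour); commercial households place no separate weight on market maize
because for them home and market maize are the same good.

All functions are exact-arithmetic homogeneous of degree zero in
(wage, rent, maize price, numeraire price, PES rate, transfer): scaling all
nominal magnitudes leaves the real allocation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .census import HouseholdRecord

__all__ = [
    "Technology",
    "Preferences",
    "HouseholdParams",
    "PriceVector",
    "Allocation",
    "optimal_allocation",
    "shadow_price",
    "net_factor_supply",
    "SubsistenceInfeasibleError",
    "solve_households",
    "StackedHouseholds",
]

REGIMES = ("separable", "nonseparable", "consumer")


class SubsistenceInfeasibleError(ValueError):
    """The subsistence minimum cannot be produced within the budget."""


@dataclass(frozen=True)
class Technology:
    """Cobb-Douglas technology Q = A * land**alpha * labor**beta."""

    A: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("technology parameters must be positive")
        if self.alpha + self.beta >= 1:
            raise ValueError("alpha + beta must be < 1 (decreasing returns)")

    @property
    def nu(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class Preferences:
    """Stone-Geary log utility weights and the subsistence minimum gamma.

    ``weights`` order: (home maize, market maize, market good, leisure).
    """

    weights: tuple[float, float, float, float]
    gamma: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < 0):
            raise ValueError("utility weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("utility weights must sum to 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class HouseholdParams:
    """Calibrated technology and preferences for one household."""

    regime: str
    preferences: Preferences
    tech_subsistence: Optional[Technology] = None
    tech_commercial: Optional[Technology] = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "nonseparable" and self.tech_subsistence is None:
            raise ValueError("nonseparable household needs a subsistence technology")
        if self.regime == "separable" and self.tech_commercial is None:
            raise ValueError("separable household needs a commercial technology")

    @property
    def tech(self) -> Optional[Technology]:
        return self.tech_commercial if self.regime == "separable" else self.tech_subsistence

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HouseholdParams":
        prefs = Preferences(tuple(d["preferences"]["weights"]), d["preferences"]["gamma"])
        techs = {}
        for key in ("tech_subsistence", "tech_commercial"):
            techs[key] = Technology(**d[key]) if d.get(key) else None
        return cls(regime=d["regime"], preferences=prefs, **techs)


@dataclass(frozen=True)
class PriceVector:
    """Village prices: wage and rent are local; maize and the market good are
    exogenous; ``pes_rate`` is the program payment per enrolled ha."""

    wage: float
    rent: float
    maize_price: float
    market_good_price: float = 1.0
    pes_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wage", "rent", "maize_price", "market_good_price"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pes_rate < 0:
            raise ValueError("pes_rate must be >= 0")


@dataclass
class Allocation:
    """A household's optimal plan at given prices.

    Labor hired vs. supplied off-farm follows the net convention: a household
    either hires or supplies off-farm labor, never both (the two are perfect
    substitutes at the single village wage, so only the net position is
    determined).
    """

    land_subsistence: float
    land_commercial: float
    land_enrolled: float
    land_rented_net: float  # positive = rented in
    labor_subsistence: float
    labor_commercial: float
    labor_offfarm: float
    labor_hired: float
    consumption_home_maize: float
    consumption_market_maize: float
    consumption_market_good: float
    leisure: float
    output: float
    maize_sales: float
    shadow_price: float
    income: float  # full income valued at the household's shadow prices
    transfer: float = 0.0

    @property
    def land_cultivated(self) -> float:
        return self.land_subsistence + self.land_commercial

    @property
    def farm_labor(self) -> float:
        return self.labor_subsistence + self.labor_commercial


# ---------------------------------------------------------------------------
# stacked (vectorized) representation
# ---------------------------------------------------------------------------

_REGIME_CODE = {"consumer": 0, "nonseparable": 1, "separable": 2}


@dataclass
class StackedHouseholds:
    """Array-of-structs view of a village used by the equilibrium solver."""

    regime: np.ndarray  # int codes per _REGIME_CODE
    A: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    w_home: np.ndarray
    w_mm: np.ndarray
    w_x: np.ndarray
    w_leis: np.ndarray
    land_owned: np.ndarray
    family_labor: np.ndarray
    base_transfer: np.ndarray

    @property
    def n(self) -> int:
        return self.regime.size

    @property
    def nu(self) -> np.ndarray:
        return self.alpha + self.beta

    @classmethod
    def from_params(
        cls, records: list[HouseholdRecord], params: list[HouseholdParams]
    ) -> "StackedHouseholds":
        n = len(records)
        out = cls(
            regime=np.zeros(n, int),
            A=np.ones(n),
            alpha=np.full(n, 0.25),
            beta=np.full(n, 0.25),
            gamma=np.zeros(n),
            w_home=np.zeros(n),
            w_mm=np.zeros(n),
            w_x=np.zeros(n),
            w_leis=np.zeros(n),
            land_owned=np.array([h.land_owned for h in records], float),
            family_labor=np.array([h.family_labor for h in records], float),
            base_transfer=np.array([h.baseline_transfer for h in records], float),
        )
        for i, p in enumerate(params):
            out.regime[i] = _REGIME_CODE[p.regime]
            t = p.tech
            if t is not None:
                out.A[i], out.alpha[i], out.beta[i] = t.A, t.alpha, t.beta
            out.gamma[i] = p.preferences.gamma
            out.w_home[i], out.w_mm[i], out.w_x[i], out.w_leis[i] = p.preferences.weights
        return out


@dataclass
class VillageSolution:
    """Per-household optimum arrays at one price vector."""

    q: np.ndarray  # home/retained maize consumption
    land: np.ndarray
    labor: np.ndarray
    m: np.ndarray  # market maize purchases
    x: np.ndarray  # market good
    leisure: np.ndarray
    shadow: np.ndarray
    output: np.ndarray
    sales: np.ndarray
    profit: np.ndarray  # farm surplus valued at the household's output price
    income: np.ndarray  # full income at shadow prices (welfare metric)
    enrolled: np.ndarray
    transfer: np.ndarray


def _cd_unit_cost(alpha, beta, r, w):
    """kappa such that cost of q is kappa * (q/A)**(1/nu)."""
    nu = alpha + beta
    return nu * (r / alpha) ** (alpha / nu) * (w / beta) ** (beta / nu)


def solve_households(
    sv: StackedHouseholds,
    prices: PriceVector,
    enrolled: np.ndarray,
    transfers: np.ndarray,
    *,
    bisect_iter: int = 78,
) -> VillageSolution:
    """Solve every household's optimum at ``prices``.

    ``enrolled`` is the per-household PES-enrolled area (decided at the
    program level and entering here only through income), ``transfers`` any
    lump-sum compensation on top of the baseline non-farm transfer.
    """
    r, w, pm, px, R = (
        prices.rent,
        prices.wage,
        prices.maize_price,
        prices.market_good_price,
        prices.pes_rate,
    )
    n = sv.n
    nu = sv.nu
    tau = sv.base_transfer + transfers
    nonsep = sv.regime == 1
    sep = sv.regime == 2

    # full income; enrolled land earns R instead of r
    income = w * sv.family_labor + r * sv.land_owned + (R - r) * enrolled + tau
    land = np.zeros(n)
    labor = np.zeros(n)
    output = np.zeros(n)
    profit = np.zeros(n)
    spent_home = np.zeros(n)  # budget absorbed by home production / maize at pm
    shadow = np.full(n, pm)
    q = np.zeros(n)

    # --- separable farms: profit max, then consumption ---------------------
    if np.any(sep):
        a_, b_, A_ = sv.alpha[sep], sv.beta[sep], sv.A[sep]
        rho = 1.0 / (1.0 - a_ - b_)
        logl = rho * (
            np.log(A_ * pm) + (1.0 - b_) * np.log(a_ / r) + b_ * np.log(b_ / w)
        )
        land[sep] = np.exp(logl)
        labor[sep] = (b_ / a_) * (r / w) * land[sep]
        output[sep] = A_ * land[sep] ** a_ * labor[sep] ** b_
        profit[sep] = pm * output[sep] - r * land[sep] - w * labor[sep]
        income[sep] += profit[sep]

    # --- nonseparable farms: home-good demand along the cost curve ---------
    if np.any(nonsep):
        ns = np.where(nonsep & (sv.w_home > 0))[0]
        deg = np.where(nonsep & (sv.w_home == 0))[0]  # degenerate preferences
        if deg.size:
            shadow[deg] = pm
        if ns.size:
            kap = _cd_unit_cost(sv.alpha[ns], sv.beta[ns], r, w)
            nu_ns = nu[ns]
            A_ns = sv.A[ns]
            gam = sv.gamma[ns]
            Y = income[ns]
            a_w = sv.w_home[ns]
            rest_w = sv.w_mm[ns] + sv.w_x[ns] + sv.w_leis[ns]

            def cost(qq):
                return kap * (qq / A_ns) ** (1.0 / nu_ns)

            c_gam = np.where(gam > 0, kap * (np.maximum(gam, 0) / A_ns) ** (1.0 / nu_ns), 0.0)
            feas = Y > c_gam
            if not np.all(feas):
                bad = ns[~feas][0]
                raise SubsistenceInfeasibleError(
                    f"household {bad}: subsistence minimum unattainable at these prices"
                )
            q_hi = A_ns * (Y * (1 - 1e-12) / kap) ** nu_ns
            lo = gam * (1 + 1e-14) + 1e-300
            hi = q_hi

            def g(qq):
                c = cost(qq)
                return a_w * (Y - c) - rest_w * (qq - gam) * c / (nu_ns * qq)

            for _ in range(bisect_iter):
                mid = 0.5 * (lo + hi)
                pos = g(mid) > 0
                lo = np.where(pos, mid, lo)
                hi = np.where(pos, hi, mid)
            q_ns = 0.5 * (lo + hi)
            c_ns = cost(q_ns)
            q[ns] = q_ns
            spent_home[ns] = c_ns
            shadow[ns] = c_ns / (nu_ns * q_ns)
            land[ns] = (sv.alpha[ns] / nu_ns) * c_ns / r
            labor[ns] = (sv.beta[ns] / nu_ns) * c_ns / w
            output[ns] = q_ns
            profit[ns] = shadow[ns] * q_ns - c_ns

    # --- separable/consumer maize demand is linear at pm -------------------
    lin = ~nonsep
    if np.any(lin & (sv.w_home > 0)):
        li = np.where(lin & (sv.w_home > 0))[0]
        wtot = sv.w_home[li] + sv.w_mm[li] + sv.w_x[li] + sv.w_leis[li]
        supern = income[li] - pm * sv.gamma[li]
        if np.any(supern <= 0):
            bad = li[supern <= 0][0]
            raise SubsistenceInfeasibleError(
                f"household {bad}: subsistence minimum unattainable at these prices"
            )
        q[li] = sv.gamma[li] + sv.w_home[li] * supern / (wtot * pm)
        spent_home[li] = pm * q[li]

    # --- residual budget shares -------------------------------------------
    rest_weight = sv.w_mm + sv.w_x + sv.w_leis
    supern_rest = income - spent_home
    # guard: for nonseparable, g()=0 guarantees positivity of the residual
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(rest_weight > 0, supern_rest / rest_weight, 0.0)
    m = sv.w_mm * share / pm
    x = sv.w_x * share / px
    leisure = sv.w_leis * share / w

    # --- leisure corner: cap at the time endowment -------------------------
    over = leisure > sv.family_labor
    if np.any(over):
        idx = np.where(over)[0]
        for i in idx:
            # re-solve with leisure pinned at T-bar
            Yi = income[i] - w * sv.family_labor[i]
            leisure[i] = sv.family_labor[i]
            wr = sv.w_mm[i] + sv.w_x[i]
            if sv.regime[i] == 1 and sv.w_home[i] > 0:
                kap = float(_cd_unit_cost(sv.alpha[i], sv.beta[i], r, w))
                nui, Ai, gi = float(nu[i]), float(sv.A[i]), float(sv.gamma[i])
                aw = sv.w_home[i]

                def gs(qq):
                    c = kap * (qq / Ai) ** (1.0 / nui)
                    return aw * (Yi - c) - wr * (qq - gi) * c / (nui * qq)

                lo_s, hi_s = gi + 1e-300, Ai * (max(Yi, 1e-300) / kap) ** nui
                if Yi <= kap * (max(gi, 0) / Ai) ** (1.0 / nui):
                    raise SubsistenceInfeasibleError(
                        f"household {i}: subsistence minimum unattainable at these prices"
                    )
                for _ in range(bisect_iter):
                    mid = 0.5 * (lo_s + hi_s)
                    if gs(mid) > 0:
                        lo_s = mid
                    else:
                        hi_s = mid
                qi = 0.5 * (lo_s + hi_s)
                ci = kap * (qi / Ai) ** (1.0 / nui)
                q[i], spent_home[i] = qi, ci
                shadow[i] = ci / (nui * qi)
                land[i] = (sv.alpha[i] / nui) * ci / r
                labor[i] = (sv.beta[i] / nui) * ci / w
                output[i] = qi
                profit[i] = shadow[i] * qi - ci
            elif sv.w_home[i] > 0:
                wtot = sv.w_home[i] + wr
                supern = Yi - pm * sv.gamma[i]
                q[i] = sv.gamma[i] + sv.w_home[i] * supern / (wtot * pm)
                spent_home[i] = pm * q[i]
            rest = Yi - spent_home[i]
            wr_tot = max(wr, 1e-300)
            m[i] = sv.w_mm[i] * rest / (wr_tot * pm)
            x[i] = sv.w_x[i] * rest / (wr_tot * px)

    sales = np.where(sep, output - q, 0.0)
    welfare_income = income + np.where(nonsep, profit, 0.0)
    return VillageSolution(
        q=q,
        land=land,
        labor=labor,
        m=m,
        x=x,
        leisure=leisure,
        shadow=shadow,
        output=output,
        sales=sales,
        profit=profit,
        income=welfare_income,
        enrolled=enrolled.copy(),
        transfer=transfers.copy(),
    )


# ---------------------------------------------------------------------------
# single-household convenience API
# ---------------------------------------------------------------------------


def _single_stack(record: HouseholdRecord, params: HouseholdParams) -> StackedHouseholds:
    return StackedHouseholds.from_params([record], [params])


def optimal_allocation(
    record: HouseholdRecord,
    params: HouseholdParams,
    prices: PriceVector,
    transfer: float = 0.0,
    enrollment_cap: float = 0.0,
) -> Allocation:
    """Optimal plan for one household at ``prices``.

    ``enrollment_cap`` bounds PES enrollment from above; the household enrolls
    spare owned land (land owned but not cultivated) up to the cap whenever
    the program rate strictly exceeds the market rent, solving the small fixed
    point between enrollment income and land use.
    """
    sv = _single_stack(record, params)
    e = np.zeros(1)
    tr = np.array([float(transfer)])
    sol = solve_households(sv, prices, e, tr)
    if enrollment_cap > 0 and prices.pes_rate > prices.rent:
        for _ in range(200):
            spare = max(0.0, record.land_owned - float(sol.land[0]))
            e_new = min(enrollment_cap, spare)
            if abs(e_new - e[0]) < 1e-13 * max(1.0, record.land_owned):
                e[0] = e_new
                break
            e[0] = 0.5 * e[0] + 0.5 * e_new
            sol = solve_households(sv, prices, e, tr)
        sol = solve_households(sv, prices, e, tr)
    return _to_allocation(record, params, prices, sol)


def _to_allocation(
    record: HouseholdRecord,
    params: HouseholdParams,
    prices: PriceVector,
    sol: VillageSolution,
    i: int = 0,
) -> Allocation:
    land = float(sol.land[i])
    labor = float(sol.labor[i])
    e = float(sol.enrolled[i])
    net_labor = (record.family_labor - float(sol.leisure[i])) - labor
    commercial = params.regime == "separable"
    return Allocation(
        land_subsistence=0.0 if commercial else land,
        land_commercial=land if commercial else 0.0,
        land_enrolled=e,
        land_rented_net=land + e - record.land_owned,
        labor_subsistence=0.0 if commercial else labor,
        labor_commercial=labor if commercial else 0.0,
        labor_offfarm=max(0.0, net_labor),
        labor_hired=max(0.0, -net_labor),
        consumption_home_maize=float(sol.q[i]) if not commercial else float(sol.q[i]),
        consumption_market_maize=float(sol.m[i]),
        consumption_market_good=float(sol.x[i]),
        leisure=float(sol.leisure[i]),
        output=float(sol.output[i]),
        maize_sales=float(sol.sales[i]),
        shadow_price=float(sol.shadow[i]),
        income=float(sol.income[i]),
        transfer=float(sol.transfer[i]),
    )


def shadow_price(
    record: HouseholdRecord,
    params: HouseholdParams,
    prices: PriceVector,
    transfer: float = 0.0,
) -> float:
    """Internal valuation of home-produced maize at the household optimum.

    For separable households (and degenerate preferences with no home-maize
    demand) this is the market maize price by convention.
    """
    if params.regime != "nonseparable" or params.preferences.weights[0] == 0:
        return prices.maize_price
    return optimal_allocation(record, params, prices, transfer).shadow_price


def net_factor_supply(allocation: Allocation, record: HouseholdRecord) -> tuple[float, float, float]:
    """(net land supplied to the rental market [ha], net labor supplied
    [person-days], net maize purchased [maize units])."""
    net_land = record.land_owned - allocation.land_enrolled - allocation.land_cultivated
    net_labor = allocation.labor_offfarm - allocation.labor_hired
    net_maize = allocation.consumption_market_maize - allocation.maize_sales
    return net_land, net_labor, net_maize


def utility(params: HouseholdParams, q: float, m: float, x: float, leisure: float) -> float:
    """Stone-Geary log utility; -inf outside the domain (used by test oracles)."""
    a, b, d, e = params.preferences.weights
    gamma = params.preferences.gamma
    terms = []
    for wt, val, floor in ((a, q, gamma), (b, m, 0.0), (d, x, 0.0), (e, leisure, 0.0)):
        if wt > 0:
            if val <= floor:
                return -np.inf
            terms.append(wt * np.log(val - floor))
    return float(sum(terms))
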