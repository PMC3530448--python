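"""Outcome accounting: rents, real incomes, and the program cost ledger.

Percentage changes are reported against the pre-program baseline.  "Real"
income changes deflate each household's full income by a household-specific
cost-of-living index whose items are the market good, open-market maize,
home-produced maize at the household's shadow price, leisure at the wage, and
rented-in land services at the rent -- a Törnqvist (average-share geometric)
index.  The nominal-vs-real gap matters here because wage and shadow-price
declines lower the cost of living exactly when nominal incomes fall.

Output aggregates are quantity indices: subsistence output is valued at
baseline shadow prices, commercial output at the exogenous maize price, so a
reported "output change" is a quantity change, not a value change.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from .census import VillageCensus
from .markets import EquilibriumState

__all__ = [
    "OutcomeReport",
    "RealIncomeChange",
    "CostLedger",
    "economic_rent_pct",
    "real_income_change",
    "cost_ledger",
    "build_report",
    "derived_ratio_checks",
]


def economic_rent_pct(premium_pct: float, rent_change_pct: float) -> float:
    """Economic rent earned by participants, in percent of the *current*
    rental rate.

    The program pays ``(1 + premium) * baseline rent``; the market rent moves
    to ``(1 + rent_change) * baseline rent``; the excess of the payment over
    the prevailing rent, relative to the prevailing rent, is the economic
    rent.
    """
    if rent_change_pct <= -100.0:
        raise ValueError("rent_change_pct must exceed -100")
    return ((1.0 + premium_pct / 100.0) / (1.0 + rent_change_pct / 100.0) - 1.0) * 100.0


# ---------------------------------------------------------------------------
# real incomes
# ---------------------------------------------------------------------------


@dataclass
class RealIncomeChange:
    pct_nominal: np.ndarray
    pct_real: np.ndarray
    currency_nominal: np.ndarray
    currency_real: np.ndarray
    deflator: np.ndarray
    included: np.ndarray  # households with a valid baseline income


def _expenditures(census: VillageCensus, state: EquilibriumState) -> np.ndarray:
    """Per-household expenditure matrix over the deflator items
    (market good, market maize, home maize, leisure, rented-in land)."""
    sol = state.solution
    p = state.prices
    owned = np.array([h.land_owned for h in census.households])
    rented_in = np.maximum(0.0, sol.land - (owned - sol.enrolled))
    return np.column_stack(
        [
            p.market_good_price * sol.x,
            p.maize_price * sol.m,
            sol.shadow * sol.q,
            p.wage * sol.leisure,
            p.rent * rented_in,
        ]
    )


def real_income_change(
    census: VillageCensus,
    baseline: EquilibriumState,
    post: EquilibriumState,
) -> RealIncomeChange:
    """Household-level nominal and real (deflated) full-income changes."""
    y0 = baseline.solution.income
    y1 = post.solution.income
    included = y0 > 0
    if not np.all(included):
        warnings.warn(
            f"{int((~included).sum())} household(s) with zero baseline income "
            "excluded from income-change statistics",
            stacklevel=2,
        )
    e0 = _expenditures(census, baseline)
    e1 = _expenditures(census, post)
    p0 = np.column_stack(
        [
            np.full(census.n, baseline.prices.market_good_price),
            np.full(census.n, baseline.prices.maize_price),
            baseline.solution.shadow,
            np.full(census.n, baseline.prices.wage),
            np.full(census.n, baseline.prices.rent),
        ]
    )
    p1 = np.column_stack(
        [
            np.full(census.n, post.prices.market_good_price),
            np.full(census.n, post.prices.maize_price),
            post.solution.shadow,
            np.full(census.n, post.prices.wage),
            np.full(census.n, post.prices.rent),
        ]
    )
    s0 = e0 / np.maximum(e0.sum(axis=1, keepdims=True), 1e-300)
    s1 = e1 / np.maximum(e1.sum(axis=1, keepdims=True), 1e-300)
    sbar = 0.5 * (s0 + s1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logrel = np.where(sbar > 0, np.log(p1 / p0), 0.0)
    deflator = np.exp((sbar * logrel).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_nom = np.where(included, 100.0 * (y1 / y0 - 1.0), np.nan)
        pct_real = np.where(included, 100.0 * ((y1 / deflator) / y0 - 1.0), np.nan)
    return RealIncomeChange(
        pct_nominal=pct_nom,
        pct_real=pct_real,
        currency_nominal=y1 - y0,
        currency_real=y1 / deflator - y0,
        deflator=deflator,
        included=included,
    )


def _group_pct(change: RealIncomeChange, y0: np.ndarray, mask: np.ndarray) -> float:
    """Income-weighted mean real change for a household group, percent."""
    m = mask & change.included
    if not np.any(m):
        return 0.0  # empty group: no members, no change
    return float(100.0 * change.currency_real[m].sum() / y0[m].sum())


# ---------------------------------------------------------------------------
# cost ledger
# ---------------------------------------------------------------------------


@dataclass
class CostLedger:
    public_cost: float
    pes_payments: float
    compensation_cost: float
    program_wage_bill: float
    net_private_benefit_nominal: float
    net_private_benefit_real: float
    absentee_benefit: float
    net_private_benefit_real_all: float
    social_cost: float  # public cost minus local private benefit
    social_cost_all: float  # public cost minus all private benefit (incl. absentee)
    group_benefits: dict = field(default_factory=dict)


def cost_ledger(
    census: VillageCensus,
    baseline: EquilibriumState,
    post: EquilibriumState,
    *,
    compensation_cost: float = 0.0,
    program_wage_bill: float = 0.0,
) -> CostLedger:
    """Aggregate public/private cost-benefit ledger of a program state."""
    change = real_income_change(census, baseline, post)
    pes = post.prices.pes_rate * post.total_enrolled
    public = pes + compensation_cost + program_wage_bill
    priv_nom = float(change.currency_nominal[change.included].sum())
    priv_real = float(change.currency_real[change.included].sum())
    absentee = post.absentee_income - baseline.absentee_income
    flags = _flag_masks(census)
    sol0 = baseline.solution
    groups = {}
    for name, mask in (
        ("participants", post.enrolled_local > 1e-12),
        ("non_participants", ~(post.enrolled_local > 1e-12)),
        ("subsistence", flags["subsistence"]),
        ("commercial", flags["commercial"]),
        ("local_landlords", flags["landlord"]),
    ):
        m = mask & change.included
        groups[name] = float(change.currency_real[m].sum())
    groups["absentee_landlords"] = float(absentee)
    return CostLedger(
        public_cost=public,
        pes_payments=pes,
        compensation_cost=compensation_cost,
        program_wage_bill=program_wage_bill,
        net_private_benefit_nominal=priv_nom,
        net_private_benefit_real=priv_real,
        absentee_benefit=float(absentee),
        net_private_benefit_real_all=priv_real + float(absentee),
        social_cost=public - priv_real,
        social_cost_all=public - (priv_real + float(absentee)),
        group_benefits=groups,
    )


def _flag_masks(census: VillageCensus) -> dict[str, np.ndarray]:
    return {
        name: np.array([h.flags[name] for h in census.households])
        for name in ("subsistence", "commercial", "landlord", "landholder")
    }


# ---------------------------------------------------------------------------
# Table-style outcome report
# ---------------------------------------------------------------------------


@dataclass
class OutcomeReport:
    """Percentage changes versus baseline plus the currency ledger for one
    program point (the published table convention: one decimal)."""

    carbon_premium_pct: float
    program_area_pct: float
    participating_households_pct: float
    local_enrollment_pct_of_target: float
    wage_pct: float
    rent_pct: float
    economic_rent_pct: float
    total_output_pct: float
    subsistence_output_pct: float
    commercial_output_pct: float
    market_surplus_pct: float
    open_market_purchases_pct: float
    income_all_pct: float
    income_subsistence_pct: float
    income_commercial_pct: float
    income_participants_pct: float
    income_nonparticipants_pct: float
    income_local_landlords_pct: float
    income_absentee_pct: float
    public_cost: float
    compensation_cost: float
    program_wage_bill: float
    net_private_benefit_nominal: float
    net_private_benefit_real: float
    net_private_benefit_real_all: float
    social_cost: float
    social_cost_all: float

    def to_series(self, name: str = "value") -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in dc_fields(self)}, name=name)

    def rounded(self) -> pd.Series:
        s = self.to_series()
        pct = s.index.str.endswith("_pct") | (s.index == "local_enrollment_pct_of_target")
        out = s.copy()
        out[pct] = s[pct].round(1)
        out[~pct] = s[~pct].round(0)
        return out


def _quantity_indices(census: VillageCensus, baseline: EquilibriumState, state: EquilibriumState):
    flags = _flag_masks(census)
    com = flags["commercial"]
    p0 = np.where(com, baseline.prices.maize_price, baseline.solution.shadow)
    total = float((p0 * state.solution.output).sum())
    sub = float((p0 * state.solution.output)[~com].sum())
    comm = float((p0 * state.solution.output)[com].sum())
    surplus = float(state.solution.sales.sum())
    purchases = float(state.solution.m.sum())
    return total, sub, comm, surplus, purchases


def _pct(post: float, base: float) -> float:
    if base == 0:
        return 0.0 if post == 0 else float("inf")
    return 100.0 * (post / base - 1.0)


def build_report(
    census: VillageCensus,
    baseline: EquilibriumState,
    post: EquilibriumState,
    *,
    compensation_cost: float = 0.0,
    program_wage_bill: float = 0.0,
) -> OutcomeReport:
    """Translate a solved post-program state into the outcome ledger."""
    change = real_income_change(census, baseline, post)
    ledger = cost_ledger(
        census, baseline, post,
        compensation_cost=compensation_cost,
        program_wage_bill=program_wage_bill,
    )
    y0 = baseline.solution.income
    flags = _flag_masks(census)
    part = post.enrolled_local > 1e-12
    t0, s0, c0, surp0, pur0 = _quantity_indices(census, baseline, baseline)
    t1, s1, c1, surp1, pur1 = _quantity_indices(census, baseline, post)
    r0, w0 = baseline.prices.rent, baseline.prices.wage
    rent_pct = 100.0 * (post.prices.rent / r0 - 1.0)
    premium_pct = 100.0 * post.premium if post.total_enrolled > 0 else 0.0
    econ_rent = (
        economic_rent_pct(premium_pct, rent_pct) if post.total_enrolled > 0 else 0.0
    )
    absentee0 = baseline.absentee_income
    return OutcomeReport(
        carbon_premium_pct=premium_pct,
        program_area_pct=100.0 * post.total_enrolled / census.arable_land,
        participating_households_pct=100.0 * float(part.sum()) / census.n,
        local_enrollment_pct_of_target=(
            100.0 * float(post.enrolled_local.sum()) / post.enrollment_target
            if post.enrollment_target > 0
            else 0.0
        ),
        wage_pct=100.0 * (post.prices.wage / w0 - 1.0),
        rent_pct=rent_pct,
        economic_rent_pct=econ_rent,
        total_output_pct=_pct(t1, t0),
        subsistence_output_pct=_pct(s1, s0),
        commercial_output_pct=_pct(c1, c0),
        market_surplus_pct=_pct(surp1, surp0),
        open_market_purchases_pct=_pct(pur1, pur0),
        income_all_pct=_group_pct(change, y0, np.ones(census.n, bool)),
        income_subsistence_pct=_group_pct(change, y0, flags["subsistence"]),
        income_commercial_pct=_group_pct(change, y0, flags["commercial"]),
        income_participants_pct=_group_pct(change, y0, part),
        income_nonparticipants_pct=_group_pct(change, y0, ~part),
        income_local_landlords_pct=_group_pct(change, y0, flags["landlord"]),
        income_absentee_pct=(
            100.0 * (post.absentee_income / absentee0 - 1.0) if absentee0 > 0 else 0.0
        ),
        public_cost=ledger.public_cost,
        compensation_cost=compensation_cost,
        program_wage_bill=program_wage_bill,
        net_private_benefit_nominal=ledger.net_private_benefit_nominal,
        net_private_benefit_real=ledger.net_private_benefit_real,
        net_private_benefit_real_all=ledger.net_private_benefit_real_all,
        social_cost=ledger.social_cost,
        social_cost_all=ledger.social_cost_all,
    )


# ---------------------------------------------------------------------------
# worked-example arithmetic checks
# ---------------------------------------------------------------------------


def _load_reference() -> dict:
    path = importlib.resources.files("villagecge.data") / "reference_ledger.json"
    return json.loads(path.read_text(encoding="utf-8"))


def derived_ratio_checks(printed: Optional[dict] = None) -> pd.DataFrame:
    """Recompute every derivable ratio among the reference program-cost
    figures shipped with the package and compare at printed precision.

    Returns a frame with columns (check, computed, expected, status); a check
    whose inputs are missing is marked ``skipped`` rather than passed.
    """
    ref = printed if printed is not None else _load_reference()
    rows: list[dict] = []

    def add(name, compute, expected, digits=0):
        try:
            value = compute()
        except KeyError as exc:
            rows.append(
                {"check": name, "computed": float("nan"), "expected": expected,
                 "status": f"skipped (missing {exc})"}
            )
            return
        ok = round(value, digits) == round(expected, digits)
        rows.append(
            {"check": name, "computed": value, "expected": expected,
             "status": "pass" if ok else "FAIL"}
        )

    for prem, rent, want in ref.get("economic_rent_examples", []):
        add(
            f"economic rent at premium {prem}% with rent change {rent}%",
            lambda prem=prem, rent=rent: economic_rent_pct(prem, rent),
            want,
        )
    s1 = ref.get("scenario1", {})
    s1a = ref.get("scenario1a", {})
    s2 = ref.get("scenario2", {})
    add(
        "loss reduction from higher prices (%)",
        lambda: 100.0 * (s1["net_private_loss"] - s1a["residual_losses"]) / s1["net_private_loss"],
        23.0,
    )
    add(
        "public-cost excess of price reform over direct compensation (%)",
        lambda: 100.0 * (
            s1a["public_cost"] / (s1["public_cost"] * (1.0 + s1["compensation_uplift"])) - 1.0
        ),
        14.0,
    )
    add(
        "fixed-wage public-cost saving (%)",
        lambda: 100.0 * (1.0 - s2["public_cost"] / s1["public_cost"]),
        3.0,
    )
    add(
        "fixed-wage social-cost saving (%)",
        lambda: 100.0 * (
            1.0
            - (s2["public_cost"] - s2["net_private_gain"])
            / (s1["public_cost"] + s1["net_private_loss"])
        ),
        21.0,
    )
    add("identical inputs give a zero difference (%)",
        lambda: 100.0 * (s1["public_cost"] / s1["public_cost"] - 1.0), 0.0)
    return pd.DataFrame(rows)
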