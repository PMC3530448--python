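"""Synthetic village censuses.

The simulator is calibrated to a small Mexican-highland farming village whose
household survey is not publicly deposited.  This module generates seeded
synthetic censuses that reproduce the published *population structure* of that
village -- the agent-type shares (landholders, commercial vs. subsistence
farmers, landlords, tenants, employers, employees), an on-farm maize
consumption share of ~85%, and a land rental market supplied ~80% by absentee
landowners -- without attempting to reconstruct any actual household.

A census is a fully articulated baseline economy: every household carries a
land and labor endowment, a baseline activity allocation, and baseline net
factor positions, and the village's land and labor markets clear exactly at
the baseline prices.  Market consistency is what makes the census calibratable
(see :mod:`villagecge.markets`).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CensusProfile",
    "HouseholdRecord",
    "VillageCensus",
    "generate_census",
    "read_census",
    "write_census",
    "InfeasibleProfileError",
    "CensusSchemaError",
    "FLAG_NAMES",
]

FLAG_NAMES = (
    "landholder",
    "landless",
    "maize_farmer",
    "commercial",
    "subsistence",
    "landlord",
    "tenant",
    "employer",
    "employee",
)

CSV_SCHEMA_VERSION = "villagecge-census-v1"

#: columns of the census CSV, in order
CSV_COLUMNS = (
    ["id", "land_owned", "family_labor"]
    + list(FLAG_NAMES)
    + [
        "baseline_land_cultivated",
        "baseline_land_rented_net",
        "baseline_labor_hired_net",
        "baseline_farm_labor",
        "baseline_hired_labor",
        "baseline_offfarm_labor",
        "baseline_output",
        "baseline_onfarm_consumption",
        "baseline_market_maize",
        "baseline_transfer",
    ]
)


class InfeasibleProfileError(ValueError):
    """A census profile admits no market-consistent baseline."""


class CensusSchemaError(ValueError):
    """A census CSV violates the documented schema."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CensusProfile:
    """Target population structure for a synthetic village census.

    Shares are fractions of households unless stated otherwise.  The default
    values are the published characteristics of the study village: agent-type
    shares, an ~85% on-farm maize consumption share, and a land rental market
    supplied ~80% by absentee landowners.  The absentee land endowment
    defaults to 30% of the total arable area.
    """

    n_households: int = 49
    share_landholders: float = 0.94
    share_maize_farmers: float = 0.98
    share_commercial: float = 0.04
    share_landlords: float = 0.02
    share_tenant_landless: float = 2.0 / 3.0
    share_tenant_landowners: float = 0.35
    share_employers: float = 0.48
    share_employees: float = 0.48
    onfarm_consumption_share: float = 0.85
    absentee_rental_supply_share: float = 0.80
    #: absentee-owned fraction of the total arable area (local + absentee)
    absentee_land_share: float = 0.30
    #: (mean ha, log-scale dispersion) of the log-normal small-holding draw
    landholding_distribution: tuple[float, float] = (1.8, 0.45)
    #: (mean person-days/yr, coefficient of variation) of family labor
    labor_endowment_distribution: tuple[float, float] = (420.0, 0.15)

    # baseline price normalisation (market good is the numeraire)
    maize_price: float = 1.0
    market_good_price: float = 1.0
    baseline_wage: float = 1.0
    baseline_rent: float = 18.0

    # technology/scale anchors used to lay out a consistent baseline
    commercial_land_multiplier: float = 5.0
    subsistence_labor_per_ha: float = 120.0
    commercial_labor_per_ha: float = 30.0
    returns_to_scale_subsistence: float = 0.70
    returns_to_scale_commercial: float = 0.90
    shadow_price_wedge: float = 0.20
    #: hired share of farm labor on employer farms
    employer_hired_share: float = 0.25
    #: target cash floor, as a fraction of the value of family time
    cash_floor_share: float = 0.80
    #: share of cash income spent on open-market maize
    maize_budget_share: float = 0.20
    #: landlord households are extended families with more family labor
    landlord_family_multiplier: float = 2.2
    #: share of the rental market absorbed by large commercial farms
    commercial_rental_absorption: float = 0.20

    def __post_init__(self) -> None:
        shares = {
            "share_landholders": self.share_landholders,
            "share_maize_farmers": self.share_maize_farmers,
            "share_commercial": self.share_commercial,
            "share_landlords": self.share_landlords,
            "share_tenant_landless": self.share_tenant_landless,
            "share_tenant_landowners": self.share_tenant_landowners,
            "share_employers": self.share_employers,
            "share_employees": self.share_employees,
            "onfarm_consumption_share": self.onfarm_consumption_share,
            "absentee_rental_supply_share": self.absentee_rental_supply_share,
            "absentee_land_share": self.absentee_land_share,
        }
        for name, value in shares.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} not in [0, 1]")
        if self.n_households < 2:
            raise ValueError("n_households must be >= 2")
        if self.share_commercial > self.share_maize_farmers:
            raise ValueError("commercial farmers cannot exceed maize farmers")
        for name in ("maize_price", "market_good_price", "baseline_wage", "baseline_rent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CensusProfile":
        d = dict(d)
        for key in ("landholding_distribution", "labor_endowment_distribution"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HouseholdRecord:
    """One household row of a village census.

    Positive ``baseline_land_rented_net`` means land rented *in*; positive
    ``baseline_labor_hired_net`` means labor hired *in*.
    """

    id: int
    land_owned: float
    family_labor: float
    flags: dict[str, bool]
    baseline_land_cultivated: float
    baseline_land_rented_net: float
    baseline_labor_hired_net: float
    baseline_farm_labor: float
    baseline_hired_labor: float
    baseline_offfarm_labor: float
    baseline_output: float
    baseline_onfarm_consumption: float
    baseline_market_maize: float
    baseline_transfer: float

    @property
    def baseline_leisure(self) -> float:
        family_on_farm = self.baseline_farm_labor - self.baseline_hired_labor
        return self.family_labor - family_on_farm - self.baseline_offfarm_labor

    def validate(self) -> None:
        f = self.flags
        if set(f) != set(FLAG_NAMES):
            raise ValueError(f"household {self.id}: incomplete flag set")
        if f["landless"] and self.land_owned != 0.0:
            raise ValueError(f"household {self.id}: landless but owns land")
        if f["landholder"] == f["landless"]:
            raise ValueError(f"household {self.id}: landholder/landless flags inconsistent")
        if f["landlord"] and not self.baseline_land_rented_net < 0:
            raise ValueError(f"household {self.id}: landlord must rent land out")
        if f["tenant"] and not self.baseline_land_rented_net > 0:
            raise ValueError(f"household {self.id}: tenant must rent land in")
        if f["commercial"] and not (
            self.baseline_onfarm_consumption < self.baseline_output
        ):
            raise ValueError(f"household {self.id}: commercial farm must sell a surplus")
        if f["subsistence"] and self.baseline_market_maize < 0:
            raise ValueError(f"household {self.id}: negative maize purchases")
        if f["maize_farmer"] != (self.baseline_land_cultivated > 0):
            raise ValueError(f"household {self.id}: maize_farmer flag vs cultivation")
        lhs = self.baseline_land_cultivated
        rhs = self.land_owned + self.baseline_land_rented_net  # enrollment is 0 at baseline
        if abs(lhs - rhs) > 1e-9 * max(1.0, rhs):
            raise ValueError(f"household {self.id}: land identity violated")
        if self.baseline_leisure <= 0:
            raise ValueError(f"household {self.id}: non-positive leisure")


@dataclass
class VillageCensus:
    """A synthetic village: household records plus village-level baseline data."""

    households: list[HouseholdRecord]
    absentee_land: float
    maize_price: float
    market_good_price: float
    baseline_wage: float
    baseline_rent: float
    profile: Optional[CensusProfile] = None

    @property
    def n(self) -> int:
        return len(self.households)

    @property
    def local_land(self) -> float:
        return float(sum(h.land_owned for h in self.households))

    @property
    def arable_land(self) -> float:
        """Total arable area farmed in the locality (local + absentee holdings)."""
        return self.local_land + self.absentee_land

    def count(self, flag: str) -> int:
        return sum(1 for h in self.households if h.flags[flag])

    def rental_balance(self) -> tuple[float, float]:
        """(supply, demand) of the baseline land rental market, in ha."""
        supply = self.absentee_land + sum(
            -h.baseline_land_rented_net
            for h in self.households
            if h.baseline_land_rented_net < 0
        )
        demand = sum(
            h.baseline_land_rented_net
            for h in self.households
            if h.baseline_land_rented_net > 0
        )
        return float(supply), float(demand)

    def labor_balance(self) -> tuple[float, float]:
        hired = sum(h.baseline_hired_labor for h in self.households)
        supplied = sum(h.baseline_offfarm_labor for h in self.households)
        return float(hired), float(supplied)

    def onfarm_consumption_share(self) -> float:
        output = sum(h.baseline_output for h in self.households)
        onfarm = sum(h.baseline_onfarm_consumption for h in self.households)
        return onfarm / output if output > 0 else float("nan")

    def absentee_rental_share(self) -> float:
        supply, _ = self.rental_balance()
        return self.absentee_land / supply if supply > 0 else 0.0

    def validate(self) -> None:
        for h in self.households:
            h.validate()
        supply, demand = self.rental_balance()
        if abs(supply - demand) > 1e-9 * max(1.0, supply):
            raise InfeasibleProfileError(
                f"baseline land rental market does not clear: supply={supply:.6f} "
                f"demand={demand:.6f}"
            )
        hired, supplied = self.labor_balance()
        if abs(hired - supplied) > 1e-9 * max(1.0, hired):
            raise InfeasibleProfileError(
                f"baseline labor market does not clear: hired={hired:.6f} "
                f"off-farm={supplied:.6f}"
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_census(profile: CensusProfile, seed: int) -> VillageCensus:
    """Generate a market-consistent synthetic census for ``profile``.

    Type counts equal ``round(share * n)`` (half away from zero); the baseline
    land-rental and labor markets clear exactly; the aggregate on-farm maize
    consumption share matches the profile target.  Deterministic in ``seed``.

    Raises
    ------
    InfeasibleProfileError
        If no market-consistent baseline exists for the profile (the message
        names the violated balance).
    """
    rng = np.random.default_rng(seed)
    n = profile.n_households
    p = profile
    w0, r0, pm = p.baseline_wage, p.baseline_rent, p.maize_price

    # --- type counts -------------------------------------------------------
    n_landholders = _round_half_away(p.share_landholders * n)
    n_landless = n - n_landholders
    n_farmers = _round_half_away(p.share_maize_farmers * n)
    n_commercial = min(_round_half_away(p.share_commercial * n), n_landholders)
    n_landlords = min(
        _round_half_away(p.share_landlords * n), n_landholders - n_commercial
    )
    n_tenant_landless = min(
        _round_half_away(p.share_tenant_landless * n_landless), n_landless
    )
    n_tenant_owners = _round_half_away(p.share_tenant_landowners * n_landholders)
    n_employers = _round_half_away(p.share_employers * n)
    n_employees = _round_half_away(p.share_employees * n)
    n_nonfarmers = n - n_farmers
    if n_nonfarmers > n_landless - n_tenant_landless + (n_landholders - n_landholders):
        # non-farmers must be landless non-tenants in this construction
        n_nonfarmers = max(0, n_landless - n_tenant_landless)
    if n_employers + n_employees > n:
        raise InfeasibleProfileError(
            "employer + employee shares exceed the household count"
        )

    # --- endowments --------------------------------------------------------
    mean_ha, sigma = p.landholding_distribution
    mu = math.log(mean_ha) - 0.5 * sigma**2
    land = np.zeros(n)
    land[:n_landholders] = rng.lognormal(mu, sigma, size=n_landholders)
    tbar_mean, tbar_cv = p.labor_endowment_distribution
    family_labor = rng.normal(tbar_mean, tbar_cv * tbar_mean, size=n)
    family_labor = np.clip(family_labor, 0.4 * tbar_mean, None)

    order = np.argsort(land[:n_landholders])[::-1]
    commercial_idx = list(order[:n_commercial])
    land[commercial_idx] *= p.commercial_land_multiplier
    landlord_idx = list(order[n_commercial : n_commercial + n_landlords])

    # owner-tenants: the most land-poor owners (excluding commercial/landlords);
    # commercial farms also rent in, and count toward the owner-tenant share.
    n_small_tenants = max(0, n_tenant_owners - n_commercial)
    poor_order = [
        i
        for i in np.argsort(land[:n_landholders])
        if i not in commercial_idx and i not in landlord_idx
    ]
    small_tenant_idx = poor_order[:n_small_tenants]
    tenant_landless_idx = list(range(n_landholders, n_landholders + n_tenant_landless))
    nonfarmer_idx = list(range(n - n_nonfarmers, n))

    # --- land market layout -----------------------------------------------
    # Absentee land is pinned to its share of total area; local landlord
    # supply is then pinned by the absentee share of the rental market.
    # Repair order: landlords are sized before tenant demand is scaled.
    base_local = float(land.sum())
    s_a, s_r = p.absentee_land_share, p.absentee_rental_supply_share
    if s_r > 0.0 and s_a > 0.0:
        k = (s_a / (1.0 - s_a)) * (1.0 - s_r) / s_r
        landlord_out_total = k * base_local / (1.0 - k) if k < 1.0 else None
        if landlord_out_total is None or not np.isfinite(landlord_out_total):
            raise InfeasibleProfileError(
                "absentee land/rental shares leave no feasible landlord supply"
            )
        absentee_land = (s_a / (1.0 - s_a)) * (base_local + landlord_out_total)
    else:
        absentee_land = 0.0
        n_rental_hh = n_small_tenants + n_tenant_landless + n_commercial
        landlord_out_total = 0.8 * mean_ha * n_rental_hh
    if n_landlords == 0 and landlord_out_total > 0:
        raise InfeasibleProfileError(
            "rental market needs local landlord supply but landlord share rounds to zero"
        )
    for i in landlord_idx:  # landlord keeps farming its drawn plot, rents out the rest
        land[i] += landlord_out_total / max(1, n_landlords)
        family_labor[i] *= p.landlord_family_multiplier

    rental_supply = absentee_land + landlord_out_total
    rented_in = np.zeros(n)
    # commercial farms rent in proportionally to their owned scale, capped so
    # that small tenants retain a positive slice of the market
    commercial_demand = (
        min(p.commercial_rental_absorption * rental_supply, float(land[commercial_idx].sum()))
        if n_commercial
        else 0.0
    )
    for i in commercial_idx:
        rented_in[i] = commercial_demand / n_commercial
    rest = rental_supply - commercial_demand
    small_idx = small_tenant_idx + tenant_landless_idx
    if small_idx:
        # water-fill under a family-labor cap: a tenant household must be able
        # to work its whole farm with <= 60% of its family time
        caps = np.array(
            [
                max(0.0, 0.6 * family_labor[i] / p.subsistence_labor_per_ha - land[i])
                for i in small_idx
            ]
        )
        weights = rng.uniform(0.6, 1.4, size=len(small_idx))
        alloc = np.zeros(len(small_idx))
        remaining = rest
        open_mask = caps > 0
        for _ in range(60):
            if remaining <= 1e-12 or not np.any(open_mask):
                break
            w_open = weights * open_mask
            step = remaining * w_open / w_open.sum()
            new_alloc = np.minimum(alloc + step, caps)
            remaining -= float((new_alloc - alloc).sum())
            alloc = new_alloc
            open_mask = alloc < caps - 1e-12
        if remaining > 1e-9:
            # tenant labor capacity is exhausted: large commercial farms
            # absorb the leftover rental supply
            if n_commercial:
                for i in commercial_idx:
                    rented_in[i] += remaining / n_commercial
                remaining = 0.0
            else:
                raise InfeasibleProfileError(
                    "baseline land rental market cannot clear: tenant labor "
                    "capacity cannot absorb the rental supply"
                )
        # exact closure repair: charge the float residual to the slackest tenant
        alloc[int(np.argmax(caps - alloc))] += remaining
        for j, i in enumerate(small_idx):
            rented_in[i] = alloc[j]
    elif rest > 1e-9:
        raise InfeasibleProfileError(
            "rental supply exceeds tenant demand and no tenants exist to absorb it"
        )
    elif n_commercial:
        rented_in[commercial_idx[0]] += rest

    rented_out = np.zeros(n)
    for i in landlord_idx:
        rented_out[i] = landlord_out_total / max(1, n_landlords)

    cultivated = land + rented_in - rented_out
    for i in nonfarmer_idx:
        cultivated[i] = 0.0
    is_commercial = np.zeros(n, bool)
    is_commercial[commercial_idx] = True

    # --- farm labor --------------------------------------------------------
    intensity = np.where(is_commercial, p.commercial_labor_per_ha, p.subsistence_labor_per_ha)
    farm_labor = intensity * cultivated

    employees: list[int] = []
    for i in tenant_landless_idx + nonfarmer_idx:
        if i not in employees:
            employees.append(i)
    # fill with the smallest farms; owner-tenants join last so that their
    # family time is free to work the land they rent in
    rest_order = [i for i in np.argsort(farm_labor) if i not in employees]
    for pass_tenants in (False, True):
        for i in rest_order:
            if len(employees) >= n_employees:
                break
            if i in commercial_idx or i in landlord_idx or i in employees:
                continue
            if (i in small_tenant_idx) != pass_tenants:
                continue
            employees.append(i)
    employees = employees[:n_employees]
    candidates = [i for i in range(n) if i not in employees]
    candidates.sort(key=lambda i: -farm_labor[i])
    employers = candidates[:n_employers]
    if len(employers) < n_employers:
        raise InfeasibleProfileError(
            "employer share cannot be met: too few non-employee households"
        )

    hired = np.zeros(n)
    for i in employers:
        if is_commercial[i]:
            fam = min(0.5 * family_labor[i], 0.6 * farm_labor[i])
            hired[i] = farm_labor[i] - fam
        else:
            hired[i] = p.employer_hired_share * farm_labor[i]
        if hired[i] <= 0:  # employer flag requires hiring
            hired[i] = max(1.0, 0.05 * farm_labor[i])

    # repair loop: family size correlates with farm size (endowments lifted so
    # no household commits more than 85% of family time to its own fields) and
    # hired labor is scaled down to what employee households can supply
    for _ in range(4):
        family_on_farm = farm_labor - hired
        family_labor = np.maximum(family_labor, family_on_farm / 0.85)
        slack = np.maximum(0.9 * family_labor - family_on_farm, 0.0)
        slack_emp = np.array([slack[i] for i in employees])
        total_hired = float(hired.sum())
        if total_hired <= 0.95 * slack_emp.sum():
            break
        hired *= 0.95 * slack_emp.sum() / total_hired
    family_on_farm = farm_labor - hired
    family_labor = np.maximum(family_labor, family_on_farm / 0.85)
    total_hired = float(hired.sum())
    offfarm = np.zeros(n)
    slack = np.maximum(0.9 * family_labor - family_on_farm, 0.0)
    slack_emp = np.array([slack[i] for i in employees])
    if slack_emp.sum() <= 0 or total_hired <= 0:
        raise InfeasibleProfileError(
            "labor market cannot clear: no off-farm capacity among employees"
        )
    if total_hired > slack_emp.sum():
        raise InfeasibleProfileError(
            "labor market cannot clear: hired demand exceeds employee capacity"
        )
    for j, i in enumerate(employees):
        offfarm[i] = total_hired * slack_emp[j] / slack_emp.sum()
    offfarm[employees[0]] += total_hired - offfarm[list(employees)].sum()  # exact

    # --- output and consumption -------------------------------------------
    shadow0 = (1.0 + p.shadow_price_wedge) * pm
    cost = r0 * cultivated + w0 * farm_labor
    nu = np.where(is_commercial, p.returns_to_scale_commercial, p.returns_to_scale_subsistence)
    pout = np.where(is_commercial, pm, shadow0)
    output = np.where(cultivated > 0, cost / (nu * pout), 0.0)

    q_sub = float(output[~is_commercial].sum())
    q_com = float(output[is_commercial].sum())
    q_tot = q_sub + q_com
    target_onfarm = p.onfarm_consumption_share * q_tot
    if n_commercial and q_com > 0:
        retained_frac = (target_onfarm - q_sub) / q_com
        if not 0.02 <= retained_frac <= 0.98:
            raise InfeasibleProfileError(
                "on-farm consumption target unattainable: commercial output "
                f"share implies retained fraction {retained_frac:.3f} outside (0.02, 0.98)"
            )
    else:
        retained_frac = 0.0
    onfarm_cons = np.where(is_commercial, retained_frac * output, output)
    sales = output - onfarm_cons  # positive only for commercial farms

    # --- cash budgets, maize purchases, transfers --------------------------
    cash_mkt = (
        w0 * (offfarm - hired)
        + r0 * (rented_out - rented_in)
        + pm * np.where(is_commercial, sales, 0.0)
    )
    cash_floor = p.cash_floor_share * w0 * family_labor
    transfer = np.maximum(0.0, cash_floor - cash_mkt)
    cash = cash_mkt + transfer
    market_maize = np.where(is_commercial, 0.0, p.maize_budget_share * cash / pm)

    leisure = family_labor - family_on_farm - offfarm
    if np.any(leisure <= 0):
        raise InfeasibleProfileError(
            "labor allocation infeasible: a household has non-positive leisure"
        )

    # --- assemble records --------------------------------------------------
    households = []
    for i in range(n):
        flags = {
            "landholder": i < n_landholders,
            "landless": i >= n_landholders,
            "maize_farmer": cultivated[i] > 0,
            "commercial": bool(is_commercial[i]),
            "subsistence": bool(cultivated[i] > 0 and not is_commercial[i]),
            "landlord": rented_out[i] > 0,
            "tenant": rented_in[i] > 0,
            "employer": hired[i] > 0,
            "employee": offfarm[i] > 0,
        }
        households.append(
            HouseholdRecord(
                id=i,
                land_owned=float(land[i]),
                family_labor=float(family_labor[i]),
                flags=flags,
                baseline_land_cultivated=float(cultivated[i]),
                baseline_land_rented_net=float(rented_in[i] - rented_out[i]),
                baseline_labor_hired_net=float(hired[i] - offfarm[i]),
                baseline_farm_labor=float(farm_labor[i]),
                baseline_hired_labor=float(hired[i]),
                baseline_offfarm_labor=float(offfarm[i]),
                baseline_output=float(output[i]),
                baseline_onfarm_consumption=float(onfarm_cons[i]),
                baseline_market_maize=float(market_maize[i]),
                baseline_transfer=float(transfer[i]),
            )
        )

    census = VillageCensus(
        households=households,
        absentee_land=float(absentee_land),
        maize_price=pm,
        market_good_price=p.market_good_price,
        baseline_wage=w0,
        baseline_rent=r0,
        profile=profile,
    )
    census.validate()
    share = census.onfarm_consumption_share()
    if n_commercial and abs(share - p.onfarm_consumption_share) > 0.02:
        raise InfeasibleProfileError(
            f"on-farm consumption share {share:.3f} misses target "
            f"{p.onfarm_consumption_share:.3f} by more than 2 points"
        )
    return census


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_census(census: VillageCensus, path: str | Path) -> None:
    """Write a census to the documented CSV schema (UTF-8, flags as 0/1)."""
    path = Path(path)
    meta = {
        "schema": CSV_SCHEMA_VERSION,
        "absentee_land": census.absentee_land,
        "maize_price": census.maize_price,
        "market_good_price": census.market_good_price,
        "baseline_wage": census.baseline_wage,
        "baseline_rent": census.baseline_rent,
    }
    if census.profile is not None:
        meta["profile"] = census.profile.to_dict()
    rows = []
    for h in census.households:
        row: dict = {"id": h.id, "land_owned": h.land_owned, "family_labor": h.family_labor}
        for f in FLAG_NAMES:
            row[f] = int(h.flags[f])
        for col in CSV_COLUMNS[12:]:
            row[col] = getattr(h, col)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    buf = io.StringIO()
    buf.write("# " + json.dumps(meta) + "\n")
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_census(path: str | Path) -> VillageCensus:
    """Read a census CSV written by :func:`write_census`.

    Raises :class:`CensusSchemaError` naming the offending column or row on
    any schema violation.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# "):
        raise CensusSchemaError(f"{path}: missing metadata header line")
    try:
        meta = json.loads(lines[0][2:])
    except json.JSONDecodeError as exc:
        raise CensusSchemaError(f"{path}: unparseable metadata header: {exc}") from exc
    if meta.get("schema") != CSV_SCHEMA_VERSION:
        raise CensusSchemaError(
            f"{path}: unsupported schema {meta.get('schema')!r}, "
            f"expected {CSV_SCHEMA_VERSION!r}"
        )
    frame = pd.read_csv(io.StringIO("\n".join(lines[1:])), float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CensusSchemaError(f"{path}: missing column(s) {missing}")
    households = []
    for idx, row in frame.iterrows():
        try:
            flags = {f: bool(int(row[f])) for f in FLAG_NAMES}
            households.append(
                HouseholdRecord(
                    id=int(row["id"]),
                    land_owned=float(row["land_owned"]),
                    family_labor=float(row["family_labor"]),
                    flags=flags,
                    **{col: float(row[col]) for col in CSV_COLUMNS[12:]},
                )
            )
        except (ValueError, TypeError) as exc:
            raise CensusSchemaError(f"{path}: bad value in row {idx}: {exc}") from exc
    profile = None
    if "profile" in meta:
        profile = CensusProfile.from_dict(meta["profile"])
    census = VillageCensus(
        households=households,
        absentee_land=float(meta["absentee_land"]),
        maize_price=float(meta["maize_price"]),
        market_good_price=float(meta["market_good_price"]),
        baseline_wage=float(meta["baseline_wage"]),
        baseline_rent=float(meta["baseline_rent"]),
        profile=profile,
    )
    census.validate()
    return census
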