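"""Scenario engine: program paths, sweeps and reports.

Five canonical designs are shipped:

``1``   cost-effective program, flexible wages, 10% area target;
``1a``  price reform: premium raised stepwise with the area target fixed and
        enrollment restricted to incumbent participants;
``1b``  area reform: target expanded stepwise at a fixed premium (14%),
        starting from the 1a path point at that premium;
``1c``  market-clearing expansion: cost-effective price search at each target;
``2``   fixed-wage context: cost-effective search under the fixed-wage
        closure, target expanded stepwise.

All randomness lives in census generation; given a census and calibration the
engine is deterministic, so identical configurations produce bit-identical
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .census import VillageCensus
from .household import HouseholdParams
from .markets import ClosureRules, EquilibriumState, solve_equilibrium
from .program import (
    ProgramSpec,
    apply_compensation,
    find_cost_effective_premium,
)
from .accounting import OutcomeReport, build_report

__all__ = ["ScenarioSpec", "ScenarioResult", "SweepCurve", "run_scenario", "sweep",
           "default_scenario", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("1", "1a", "1b", "1c", "2")


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered path of program points under one closure rule."""

    name: str
    closure: ClosureRules
    path: tuple[ProgramSpec, ...]
    carry_incumbents: bool = True

    def __post_init__(self) -> None:
        if not self.path:
            raise ValueError("scenario path must be non-empty")
        premiums = [p.premium for p in self.path if p.premium is not None]
        if len(premiums) > 1 and not _monotone(premiums):
            raise ValueError("premium grid must be monotone")
        targets = [p.area_target for p in self.path]
        if len(set(targets)) > 1 and not _monotone(targets):
            raise ValueError("area grid must be monotone")


def _monotone(xs) -> bool:
    return all(b >= a for a, b in zip(xs, xs[1:])) or all(
        b <= a for a, b in zip(xs, xs[1:])
    )


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    baseline: EquilibriumState
    states: list[EquilibriumState]
    reports: list[OutcomeReport]  # first entry is the all-zero baseline report

    def frame(self) -> pd.DataFrame:
        """Outcome table, indicators in rows and path points in columns."""
        cols = {"baseline": self.reports[0].to_series()}
        for i, rep in enumerate(self.reports[1:]):
            cols[f"point_{i}"] = rep.to_series()
        return pd.DataFrame(cols)


@dataclass
class SweepCurve:
    """Equilibrium outcomes along a monotone program grid."""

    variable: str  # 'premium' | 'area'
    grid: np.ndarray
    table: pd.DataFrame  # one row per grid point, one column per indicator

    def ordinate(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


def run_scenario(
    spec: ScenarioSpec,
    census: VillageCensus,
    params: list[HouseholdParams],
    *,
    baseline: Optional[EquilibriumState] = None,
) -> ScenarioResult:
    """Solve every path point of ``spec`` and report outcomes vs. baseline."""
    if baseline is None:
        baseline = solve_equilibrium(census, params, spec.closure, None)
    reports = [build_report(census, baseline, baseline)]
    states: list[EquilibriumState] = []
    incumbents: Optional[dict] = None
    for point in spec.path:
        if point.area_target <= 0:
            state = baseline
            comp_cost = wage_bill = 0.0
        else:
            if point.price_mode == "cost_effective":
                _, state = find_cost_effective_premium(
                    census, params, spec.closure, point.area_target,
                    incumbents=incumbents,
                )
            else:
                state = solve_equilibrium(
                    census, params, spec.closure, point, incumbents=incumbents
                )
            comp_cost = wage_bill = 0.0
            if point.compensation != "none":
                comp = apply_compensation(
                    census, params, spec.closure, point, baseline, state
                )
                state = comp.state
                comp_cost = comp.added_public_cost - comp.wage_bill
                wage_bill = comp.wage_bill
        states.append(state)
        reports.append(
            build_report(
                census, baseline, state,
                compensation_cost=comp_cost, program_wage_bill=wage_bill,
            )
        )
        # the incumbent participant set is pinned by the scenario's first
        # program point (the pre-reform program), not updated along the path
        if spec.carry_incumbents and incumbents is None and point.area_target > 0:
            incumbents = {"local": state.enrolled_local.copy(),
                          "absentee": state.enrolled_absentee}
    return ScenarioResult(spec=spec, baseline=baseline, states=states, reports=reports)


def sweep(
    spec: ScenarioSpec,
    census: VillageCensus,
    params: list[HouseholdParams],
    variable: str,
    grid,
    *,
    baseline: Optional[EquilibriumState] = None,
) -> SweepCurve:
    """Sweep ``variable`` ('premium' or 'area') over a monotone ``grid``,
    holding the rest of the first path point fixed."""
    grid = np.asarray(list(grid), float)
    if grid.size == 0 or (grid.size > 1 and not _monotone(list(grid))):
        raise ValueError("sweep grid must be non-empty and monotone")
    base_point = spec.path[0]
    points = []
    for v in grid:
        if variable == "premium":
            points.append(
                replace(base_point, premium=float(v), price_mode="fixed_premium")
            )
        elif variable == "area":
            points.append(replace(base_point, area_target=float(v)))
        else:
            raise ValueError("variable must be 'premium' or 'area'")
    swept = ScenarioSpec(
        name=f"{spec.name}-sweep-{variable}",
        closure=spec.closure,
        path=tuple(points),
        carry_incumbents=spec.carry_incumbents,
    )
    result = run_scenario(swept, census, params, baseline=baseline)
    table = pd.DataFrame([r.to_series() for r in result.reports[1:]])
    table.insert(0, variable, grid)
    return SweepCurve(variable=variable, grid=grid, table=table)


def default_scenario(
    name: str,
    census: VillageCensus,
    params: list[HouseholdParams],
    *,
    area_step: float = 0.01,
    premium_step: float = 0.04,
    max_area: float = 0.20,
    max_premium: float = 0.50,
) -> ScenarioSpec:
    """Build the canonical scenario specs (see module docstring).

    Scenarios 1a and 1b start from the solved cost-effective program, so this
    runs the base program when needed.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    flexible = ClosureRules("flexible")
    if name == "1":
        return ScenarioSpec(
            name="1", closure=flexible,
            path=(ProgramSpec(area_target=0.10, price_mode="cost_effective"),),
        )
    if name == "1a":
        pi_star, _ = find_cost_effective_premium(census, params, flexible, 0.10)
        grid = [
            p for p in np.arange(0.10, max_premium + 1e-9, premium_step) if p > pi_star
        ]
        path = [ProgramSpec(area_target=0.10, price_mode="cost_effective")] + [
            ProgramSpec(
                area_target=0.10, price_mode="fixed_premium", premium=float(p),
                participation="incumbents_only",
            )
            for p in grid
        ]
        return ScenarioSpec(name="1a", closure=flexible, path=tuple(path))
    if name == "1b":
        # starts where the 1a price reform stands at a 14% premium, then
        # expands the target at that price with participation re-opened
        path = [
            ProgramSpec(area_target=0.10, price_mode="cost_effective"),
            ProgramSpec(
                area_target=0.10, price_mode="fixed_premium", premium=0.14,
                participation="incumbents_only",
            ),
        ]
        for theta in np.arange(0.10 + area_step, max_area + 1e-9, area_step):
            path.append(
                ProgramSpec(
                    area_target=float(theta), price_mode="fixed_premium", premium=0.14
                )
            )
        return ScenarioSpec(name="1b", closure=flexible, path=tuple(path))
    closure = flexible if name == "1c" else ClosureRules("fixed")
    return ScenarioSpec(
        name=name, closure=closure,
        path=tuple(
            ProgramSpec(area_target=float(t), price_mode="cost_effective")
            for t in np.arange(0.10, max_area + 1e-9, area_step)
        ),
    )
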