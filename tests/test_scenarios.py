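"""Scenario engine and CLI: deterministic reports, path consistency, sweep
monotonicity, and command-line smoke tests."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import villagecge as v
from villagecge.cli import main as cli_main
from villagecge.program import ProgramSpec
from villagecge.scenarios import ScenarioSpec, default_scenario, run_scenario, sweep


@pytest.fixture(scope="module")
def scenario1_result(census, params, baseline):
    spec = default_scenario("1", census, params)
    return run_scenario(spec, census, params, baseline=baseline)


def test_identical_runs_are_bit_identical(census, params, baseline):
    spec = default_scenario("1", census, params)
    a = run_scenario(spec, census, params, baseline=baseline)
    b = run_scenario(spec, census, params, baseline=baseline)
    for ra, rb in zip(a.reports, b.reports):
        assert ra.to_series().equals(rb.to_series())


def test_baseline_report_is_all_zero(scenario1_result):
    base = scenario1_result.reports[0].to_series()
    assert np.allclose(base.to_numpy(dtype=float), 0.0, atol=1e-9)


def test_empty_program_point_gives_zero_report(census, params, baseline):
    spec = ScenarioSpec(
        name="empty", closure=v.ClosureRules("flexible"),
        path=(ProgramSpec(area_target=0.0),),
    )
    res = run_scenario(spec, census, params, baseline=baseline)
    assert np.allclose(res.reports[1].to_series().to_numpy(dtype=float), 0.0, atol=1e-9)


def test_price_reform_leaves_rents_flat_but_builds_economic_rents(census, params, baseline):
    """Restricting enrollment to incumbents decouples the payment from the
    land market: rents stay nearly flat while economic rents grow with the
    premium."""
    spec = default_scenario("1a", census, params, premium_step=0.18)
    res = run_scenario(spec, census, params, baseline=baseline)
    reports = res.reports[2:]  # skip baseline and the cost-effective start
    rents = [r.rent_pct for r in reports]
    econ = [r.economic_rent_pct for r in reports]
    assert max(rents) - min(rents) < 1.0  # percentage points: nearly flat
    assert all(b > a for a, b in zip(econ, econ[1:]))
    assert econ[-1] > 20.0


def test_expansion_start_point_matches_price_reform_point(census, params, baseline):
    """The expansion scenario's starting point (14% premium, 10% target)
    reproduces the price-reform path point at the same premium exactly."""
    spec_a = default_scenario("1a", census, params, premium_step=0.04)
    spec_b = default_scenario("1b", census, params, area_step=0.05)
    res_a = run_scenario(spec_a, census, params, baseline=baseline)
    res_b = run_scenario(spec_b, census, params, baseline=baseline)
    i14 = next(
        j for j, p in enumerate(spec_a.path)
        if p.premium is not None and abs(p.premium - 0.14) < 1e-12
    )
    assert res_a.reports[1 + i14].to_series().equals(res_b.reports[2].to_series())


def test_expansion_dissipates_economic_rents(census, params, baseline):
    """At a fixed premium, expanding the target raises market rents and
    squeezes economic rents monotonically, crossing zero once rents overtake
    the payment."""
    first = ProgramSpec(area_target=0.10, price_mode="fixed_premium", premium=0.08)
    spec = ScenarioSpec(
        name="expansion", closure=v.ClosureRules("flexible"), path=(first,),
    )
    curve = sweep(spec, census, params, "area", [0.10, 0.13, 0.16],
                  baseline=baseline)
    econ = curve.ordinate("economic_rent_pct")
    assert all(b <= a + 1e-9 for a, b in zip(econ, econ[1:]))
    assert econ[0] > 0 and econ[-1] < 0  # sign change as rents cross the payment
    rents = curve.ordinate("rent_pct")
    assert rents[-1] > 8.0


def test_carbon_supply_curve_weakly_increasing(census, params, scenario1, fixed_wage):
    """Cost-effective premiums rise with the area target under both closures,
    and the fixed-wage curve lies weakly below the flexible one."""
    flex = v.ClosureRules("flexible")
    pis = {}
    for closure, name in ((flex, "flex"), (fixed_wage, "fixed")):
        pis[name] = [
            v.find_cost_effective_premium(census, params, closure, t)[0]
            for t in (0.10, 0.15, 0.20)
        ]
        assert all(b >= a for a, b in zip(pis[name], pis[name][1:]))
    assert all(f <= x for f, x in zip(pis["fixed"], pis["flex"]))


def test_single_point_sweep_matches_run(census, params, baseline):
    point = ProgramSpec(area_target=0.10, price_mode="fixed_premium", premium=0.12)
    spec = ScenarioSpec(name="pt", closure=v.ClosureRules("flexible"), path=(point,))
    res = run_scenario(spec, census, params, baseline=baseline)
    curve = sweep(spec, census, params, "premium", [0.12], baseline=baseline)
    assert curve.table.iloc[0]["rent_pct"] == res.reports[1].rent_pct


def test_monotonicity_validation():
    with pytest.raises(ValueError, match="monotone"):
        ScenarioSpec(
            name="bad", closure=v.ClosureRules("flexible"),
            path=(
                ProgramSpec(area_target=0.10, price_mode="fixed_premium", premium=0.2),
                ProgramSpec(area_target=0.30, price_mode="fixed_premium", premium=0.1),
                ProgramSpec(area_target=0.20, price_mode="fixed_premium", premium=0.3),
            ),
        )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_generate_calibrate_run(tmp_path):
    runner = CliRunner()
    census_path = tmp_path / "census.csv"
    params_path = tmp_path / "params.json"
    out_prefix = tmp_path / "report"
    r = runner.invoke(cli_main, ["generate", "--seed", "42", "--out", str(census_path)])
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main, ["calibrate", "--census", str(census_path), "--out", str(params_path)]
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["run", "--census", str(census_path), "--params", str(params_path),
         "--scenario", "1", "--out", str(out_prefix)],
    )
    assert r.exit_code == 0, r.output
    payload = json.loads((tmp_path / "report.json").read_text())
    assert payload["scenario"] == "1"
    assert len(payload["reports"]) == 2  # baseline + one program point
    assert (tmp_path / "report.csv").exists()


def test_cli_check_passes():
    r = CliRunner().invoke(cli_main, ["check"])
    assert r.exit_code == 0, r.output
    assert "pass" in r.output


def test_cli_unknown_scenario_fails(tmp_path):
    runner = CliRunner()
    census_path = tmp_path / "census.csv"
    runner.invoke(cli_main, ["generate", "--seed", "1", "--out", str(census_path)])
    r = runner.invoke(
        cli_main, ["run", "--census", str(census_path), "--scenario", "9"]
    )
    assert r.exit_code != 0
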