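# Methods

`villagecge` simulates a small open village economy — a mixed
subsistence/commercial maize-farming community in the densely populated
Mexican tropical highlands — as a collection of optimizing farm households
linked through local land-rental and labor markets, and uses it to trace the
general-equilibrium consequences of a PES/REDD+ land set-aside program:
payments, enrollment, factor prices, output, and the distribution of real
income gains and losses.

## The household model

Each household maximizes a Stone–Geary log utility over four goods — home
maize `q` (with subsistence floor `γ`), open-market maize `m`, a composite
market good `x` (the numéraire), and leisure `ℓ` — subject to a full-income
budget at the village wage `w`, land rent `r`, and the exogenous maize price
`p_m`:

```
U = a·ln(q − γ) + b·ln(m) + d·ln(x) + e·ln(ℓ)
```

Farming uses a Cobb–Douglas technology `Q = A·L^α·N^β` with decreasing
returns (`ν = α + β < 1`). Two regimes:

* **Separable (commercial) farms.** Maize is fully tradable at `p_m`:
  production is profit maximization with closed-form factor demands, and
  consumption spends full income (profit + endowment income + transfers).
  Production is independent of preferences, so the income effect on
  commercial output is exactly zero.
* **Nonseparable (subsistence) farms.** Home maize is a household-specific
  non-tradable: it cannot be sold, and purchased maize is an imperfect
  substitute. The household therefore "buys" `q` along its own convex cost
  curve `C(q) = κ(w, r)·(q/A)^{1/ν}`, and the marginal cost at the optimum,
  `p* = C′(q*)`, is the endogenous **shadow price** of subsistence output.
  Reduction to one dimension makes the solution robust and fast: given `q`,
  the rest of the budget splits across `(m, x, ℓ)` in fixed proportions, so
  `q*` solves a single monotone equation, found by (vectorized) bisection to
  ~1e-15 relative precision. A corner pass pins leisure at the time endowment
  when demand exceeds it.

Because `λ` (the marginal utility of income) falls with income, lump-sum
transfers raise home-maize demand, subsistence land use, and the shadow
price — the income effect on subsistence production that drives all of the
distributional results. Every demand is homogeneous of degree zero in
`(w, r, p_m, p_x, payment, transfers)`.

The utility weight vector has four entries where a three-good formulation
(maize/market good/leisure) would have sufficed for commercial households:
market maize must be distinct from home maize for the shadow price to be
endogenous, and landless consumers need the market-maize good with no home
production. Commercial households carry weight zero on market maize (home
and market maize are one good for them); landless households carry weight
zero on home maize.

## Synthetic census (the study conditions)

The survey underlying the study village is unpublished, so the package ships
a generator targeting only its printed population structure: 49 households;
94% landholders / 6% landless; 98% maize farmers; 4% commercial farmers who
sell surpluses; 2% landlords; tenants = 2/3 of landless plus 35% of
landowners; 48% employers and 48% employees; ~85% of maize output consumed
on-farm; ~80% of rental-market land supplied by absentee landowners, whose
holdings default to 30% of the total arable area. Type counts are
`round(share × n)` (half away from zero), repaired in a fixed order
(landlords sized before tenant demand is scaled) so that the baseline land
and labor markets clear *exactly*; exact closure is what makes the census
calibratable.

Structural defaults were chosen once to reproduce the qualitative behaviour
of the study economy and then frozen:

| parameter | default | why |
|---|---|---|
| landholdings | log-normal, mean 1.8 ha, σ=0.45 | right-skewed smallholdings, the regional norm |
| family labor | ~420 person-days/yr (CV 0.15) | two adult workers plus partial second shift |
| baseline wage / rent / maize price | 1 / 18 / 1 | levels are free (only percentage changes are reported); rent of 18/ha puts the land cost share of subsistence farming at ~0.13 |
| subsistence technology | ν = 0.70, ~120 person-days/ha | labor-intensive smallholding; the low land share makes subsistence output respond to wages more than to rents |
| commercial technology | ν = 0.90, ~30 person-days/ha | near-constant returns make commercial factor demands highly price-elastic, so commercial farms bear the adjustment |
| shadow-price wedge | 20% over `p_m` | net-buying households value home maize at a premium |
| Stone–Geary floor | γ = 60% of baseline home consumption | keeps subsistence demand income-inelastic but not rigid |
| non-farm transfers | floor at 80% of family-time value | high non-farm income shares (remittances, support programs) are the rural-Mexico norm and cushion the wage-income channel |
| landlord family multiplier | 2.2 | landholding correlates with family size; keeps the landlord's gains on rents roughly offset by imputed wage losses |

Calibration inverts the first-order conditions at the baseline: commercial
returns to scale are identified by the observed profit margin; subsistence
returns are not identified from one cross-section and are pinned at the
profile value, after which the baseline shadow price follows from the factor
bill. The calibrated model reproduces every baseline allocation to machine
precision (tested at 1e-6).

## Markets and closure

Land always clears locally: the arable area (local + absentee) is fixed, and
absentee owners are pure rentiers supplying all of it. The labor market
clears locally under the **flexible-wage** closure; under the **fixed-wage**
closure off-farm labor demand is perfectly elastic at the baseline wage and
the residual is absorbed outside the village. Maize and the market good are
traded with the outside economy at fixed prices, so factor-market excess
demands plus the external account sum identically to zero (Walras' law); the
solver records that residual (≈1e-16) at every iterate.

The equilibrium solver uses a quasi-Newton root on log-prices with a nested
Brent-bracketing fallback (labor market inside the land market), relative
excess-demand tolerance 1e-8. Bracketing 1-D root isolation was preferred
over damped tâtonnement for robustness to the kinks that program enrollment
introduces in household responses.

## Program mechanics

The program pays `(1+π)·r₀` per enrolled hectare. A household's willingness
to accept is the market rent (land is homogeneous and rentable), but it can
enroll only *spare owned land* — land its own optimal cultivation plan does
not use — so subsistence demands bind enrollment from below, and the
program's own payments feed back into land demand. Enrollment and prices are
solved as a joint fixed point. Rules, all deterministic:

* strict gain: no voluntary enrollment at `π ≤ 0` (a payment equal to the
  rent leaves land in the rental market);
* local priority with proportional rationing when local supply exceeds the
  target; absentee land fills the residual whenever the premium is strictly
  positive (the elastic fringe), which also keeps total enrollment — and
  hence land supply — continuous in prices at the rent/payment crossover;
* along a reform path, the incumbent participant set is pinned by the first
  program point, and committed land stays enrolled even if market rents later
  overtake the payment (economic rents then turn negative rather than
  enrollment collapsing mid-reform).

`find_cost_effective_premium` bisects (tolerance 1e-6) for the smallest
premium whose payment covers the post-program equilibrium rent; at the
solution rents have risen to the payment and economic rents are ~0.
Compensation variants: lump-sum transfers to losers are iterated to a fixed
point (transfers shift subsistence demand and prices); the
employer-of-last-resort variant is the fixed-wage equilibrium with the
absorbed labor charged to the program at the baseline wage.

## Accounting

Nominal income is full income at the household's own prices: endowment
values, transfers, program payments, commercial profit, and the
home-production surplus valued at the shadow price. Real changes deflate by
a household-specific Törnqvist index (average expenditure shares, log price
relatives) over the market good, market maize, home maize at the shadow
price, leisure at the wage, and rented-in land services at the rent. Output
aggregates are quantity indices valued at baseline prices (shadow prices for
subsistence farms), so reported output changes are quantity changes. Group
income changes are income-weighted and decompose exactly (participants +
non-participants = all). The "net private benefit" is reported both for
local households only and including absentee owners, since whether absentee
gains belong in the locality's ledger is a reporting choice.

## What the synthetic village does and does not show

Passing tests demonstrate the model's internal economics — market clearing,
the income effect, rent dissipation, supply curves, ledger conservation — on
a village *emulating the printed population structure* of the study site.
They do not validate the published point estimates (wage −2.5%, rents +7.0%
at the 10% target, etc.), which are outputs of a calibration to the
unpublished survey; on the default synthetic village the same experiment
yields, e.g., a 5.9% cost-effective premium, a 1.7% wage drop and a 4.3%
fixed-wage premium — the same causal pattern at calibration-specific
magnitudes. One qualitative claim of the study does not hold under these
forms: with absentee owners holding 30% of the area, a rent increase under
the fixed-wage closure necessarily leaves small real-income losses
(0.1–0.4%) among net land renters, so "no losing households" fails here (the
corresponding acceptance test is deliberately left failing; see the test
docstring).

## Numerical choices and limitations

* Household bisection: 78 iterations on a bracketed interval (machine
  precision); infeasible subsistence floors raise an explicit error.
* Equilibrium tolerance 1e-8 (relative excess demand); premium bisection
  1e-6; compensation fixed point 1e-6 of mean income, damping 0.8.
* Ties: at exact payment/rent equality owners keep land in the rental
  market; rationing is proportional; all tie-breaks are deterministic, and
  all randomness lives in census generation, so identical seeds give
  bit-identical outputs.
* Short-run model: no credit, risk, investment, or intertemporal choice; no
  forest-product extraction; no land heterogeneity; no goods-market
  multiplier (maize and the market good are priced outside the village); no
  administrative or monitoring costs; no biophysical carbon accounting — the
  program is specified in land area, not tonnes.
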