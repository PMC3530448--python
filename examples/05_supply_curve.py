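"""The locality's carbon-supply curve.

Under cost-effective pricing the payment equals the equilibrium land rent,
so the (area target, premium) locus traces the village's supply curve of
carbon services.  Opportunity costs rise with the program itself -- local
subsistence demand bids land back -- so supply is upward sloping even though
land quality is uniform.
"""

import villagecge as v

census = v.generate_census(v.CensusProfile(), seed=42)
params = v.calibrate(census)

print("area target   premium (flexible wage)   premium (fixed wage)")
for theta in (0.10, 0.125, 0.15, 0.175, 0.20):
    pi_flex, _ = v.find_cost_effective_premium(
        census, params, v.ClosureRules("flexible"), theta
    )
    pi_fix, _ = v.find_cost_effective_premium(
        census, params, v.ClosureRules("fixed"), theta
    )
    print(f"   {100 * theta:5.1f}%            {100 * pi_flex:6.2f}%"
          f"                 {100 * pi_fix:6.2f}%")

print()
print("Both curves rise with the target (the marginal cost of carbon grows as")
print("the program unfurls); the fixed-wage curve lies below because constant")
print("wages depress the returns to land and with them the enrollment price.")
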