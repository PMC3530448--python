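{
 "n_households": 49,
 "share_landholders": 0.94,
 "share_maize_farmers": 0.98,
 "share_commercial": 0.04,
 "share_landlords": 0.02,
 "share_tenant_landless": 0.6666666666666666,
 "share_tenant_landowners": 0.35,
 "share_employers": 0.48,
 "share_employees": 0.48,
 "onfarm_consumption_share": 0.85,
 "absentee_rental_supply_share": 0.8,
 "absentee_land_share": 0.3,
 "landholding_distribution": [
  1.8,
  0.45
 ],
 "labor_endowment_distribution": [
  420.0,
  0.15
 ],
 "maize_price": 1.0,
 "market_good_price": 1.0,
 "baseline_wage": 1.0,
 "baseline_rent": 18.0,
 "commercial_land_multiplier": 5.0,
 "subsistence_labor_per_ha": 120.0,
 "commercial_labor_per_ha": 30.0,
 "returns_to_scale_subsistence": 0.7,
 "returns_to_scale_commercial": 0.9,
 "shadow_price_wedge": 0.2,
 "employer_hired_share": 0.25,
 "cash_floor_share": 0.8,
 "maize_budget_share": 0.2,
 "landlord_family_multiplier": 2.2,
 "commercial_rental_absorption": 0.2
}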