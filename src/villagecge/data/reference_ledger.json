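{
  "_comment": "Published worked-example ledger for the study village (currency units); used by derived_ratio_checks as the printed-arithmetic consistency suite.",
  "economic_rent_examples": [
    [50.0, 7.1, 40.0],
    [7.0, 7.0, 0.0],
    [0.0, 0.0, 0.0]
  ],
  "scenario1": {
    "public_cost": 232500,
    "net_private_loss": 48200,
    "absentee_gain": 4000,
    "absentee_gain_from_payments": 590,
    "compensation_uplift": 0.23
  },
  "scenario1a": {
    "public_cost": 325900,
    "residual_losses": 37300,
    "local_landlord_gain": 69800,
    "absentee_gain": 4400,
    "net_private_gain": 43700
  },
  "scenario1b": {
    "net_private_cost": 103300,
    "absentee_gain": 8700,
    "local_landlord_loss": 2500
  },
  "scenario2": {
    "public_cost": 225300,
    "net_private_gain": 2900,
    "expanded_public_cost": 507100,
    "expanded_wage_bill": 40333,
    "expanded_private_nominal": 41500,
    "expanded_private_real": 14400
  }
}
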