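"""Probe interaction trajectories with simple slopes at age 13.

Uses a fitted coefficient table (here the published estimates of the
Domain x Target model, wrapped as a fit object) and reconstructs the
instantaneous age slopes of the two focal condition contrasts.
"""

import parcelgrowth as pg

published = {
    "gamma_400": 0.000, "gamma_401.soc": -0.005,
    "gamma_800": 0.002, "gamma_801.self": 0.026,
    "gamma_1000": 0.003, "gamma_1001.self": -0.006, "gamma_1001.soc": -0.014,
    "gamma_900": -0.002, "gamma_901.self": -0.011,
    "gamma_1100": -0.000, "gamma_1101.self": 0.009,
    "gamma_500": -0.003, "gamma_501.soc": 0.005, "gamma_1101.soc": -0.001,
}
fit = pg.fit_from_estimates(published)

# Self - Other slope for Social items in self parcels at age 13:
# 1*(gamma_800 + gamma_801.self) + 0.5*(gamma_1000 + gamma_1001.self)
cr = pg.simple_slope(fit, "target_diff", conditioning_code=+0.5,
                     parcel_label="self", age=13.0)
print(f"Self-Other age slope, Social items, self parcels:  {cr.estimate:+.4f}")

# Social - Academic slope for Self evaluation in social parcels at age 13
cr2 = pg.simple_slope(fit, "domain_diff", conditioning_code=+0.5,
                      parcel_label="social", age=13.0)
print(f"Social-Academic age slope, Self items, social parcels: {cr2.estimate:+.4f}")

# A positive first number means the Self > Other difference in self parcels
# is still growing at age 13; the second, slightly negative, says the
# Social > Academic difference in social parcels is flat-to-shrinking.
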