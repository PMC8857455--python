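"""Breath-CO2 fuel mixing: how much of the energy budget is biofilm sugar?

Simulates a 69-bird breath cohort like the field study (fasting birds
exhaling stored-lipid CO2, saturated feeders exhaling dietary-carbohydrate
CO2, intermediates in between), then runs the analysis exactly as in the
field: pick the 14 most-positive / 14 most-negative samples as endpoints
and place every remaining bird linearly between them.
"""

from mudflatmix.breath import select_endpoints, summarize_fuel
from mudflatmix.synthetic import BreathSimConfig, SimConfig, gen_breath

config = SimConfig(seed=2016, breath=BreathSimConfig())  # true mean fraction 0.407
samples = gen_breath(config)
print(f"simulated cohort: {len(samples)} birds, "
      f"{sum(s.context == 'morning_return' for s in samples)} morning-return (fasting)")

endpoints = select_endpoints(samples, k=14)
print(
    f"endpoints: carbohydrate {endpoints.carb_mean:.1f} +/- {endpoints.carb_sd:.1f}, "
    f"lipid {endpoints.lip_mean:.1f} +/- {endpoints.lip_sd:.1f} per mil"
)

result = summarize_fuel(samples, endpoints)
print(
    f"intermediate birds (n = {result.n_intermediate}): carbohydrate fuel fraction "
    f"{100 * result.mean_fraction:.1f} +/- {100 * result.sd_fraction:.1f} %"
)
# The recovered mean (~40%) estimates the share of oxidative energy coming
# from dietary (biofilm) carbohydrate rather than stored/dietary lipid —
# close to the generator's true 40.7% despite 0.9 per mil breath noise.
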