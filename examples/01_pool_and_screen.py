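"""Pool food-web survey rows into dietary endpoints and screen consumers.

Builds the surface-sediment "biofilm" endpoint from three survey summaries
and screens a small liver cohort for terrestrial-feeding outliers.
"""

from mudflatmix import datasets
from mudflatmix.foodweb import IsotopeSample, pool_endpoints, screen_terrestrial

# Pool the three surface-sediment survey rows of the packaged food-web table.
sediment = [s for s in datasets.load_foodweb() if s.source_name == "surface_sediment"]
pooled = pool_endpoints(sediment)
print(
    f"biofilm endpoint: d13C {pooled.mean_d13C:.1f} +/- {pooled.sd_d13C:.1f} per mil, "
    f"d15N {pooled.mean_d15N:.1f} +/- {pooled.sd_d15N:.1f} per mil (n = {pooled.n_total})"
)
# -> d13C -19.7 +/- 1.7, d15N 6.4 +/- 1.5, n = 96: the pooled surface-sediment
#    endpoint that enters the BIOF mixing model.

# Screen a liver cohort: anything below -19 per mil signals upland
# (terrestrial) feeding and is excluded from marine diet models.
cohort = [
    IsotopeSample(f"bird_{i}", "western_sandpiper", "liver", d13c, 13.0)
    for i, d13c in enumerate([-16.0, -15.4, -21.4, -16.8, -23.1])
]
result = screen_terrestrial(cohort)
print(
    f"screen at {result.threshold_d13C} per mil: {len(result.retained)} retained, "
    f"{len(result.flagged_terrestrial)} flagged "
    f"({[s.d13C for s in result.flagged_terrestrial]})"
)
# The two strongly depleted birds (-21.4, -23.1) carry a terrestrial carbon
# signal and are kept out of the mixing models.
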