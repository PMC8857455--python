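"""Packaged study constants for the Roberts Bank (Fraser estuary) stopover.

Everything here is summary-level field data or a published physiological
constant: per-study food-web summaries, shorebird tissue cohort statistics,
breath-CO2 oxidation endpoints, diet-tissue trophic discrimination factors
for Calidris shorebirds, and the reference half-lives and body masses used
for allometric turnover scaling.  Raw per-individual field measurements were
never distributed; cohort statistics are the finest grain available, and the
:mod:`mudflatmix.synthetic` module generates pseudo-individuals from them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from mudflatmix.breath import BreathEndpoints
from mudflatmix.foodweb import SourceSummary, read_food_web
from mudflatmix.mixing import SourceSpec, TrophicDiscrimination
from mudflatmix.routing import MacroComposition
from mudflatmix.turnover import TurnoverReference


def foodweb_path() -> Path:
    """Path to the packaged food-web summary table."""
    return Path(resources.files("mudflatmix").joinpath("data/foodweb_roberts_bank.csv"))


def load_foodweb() -> list[SourceSummary]:
    """Load the packaged per-study food-web summaries."""
    return read_food_web(foodweb_path())


#: Macromolecular composition of assimilated MPB carbon:
#: carbohydrate / lipid / protein fractions.
MPB_MACRO_COMPOSITION = MacroComposition(A=0.5, B=0.1, C=0.4)

#: Bulk microphytobenthos delta13C at the study site (per mil).
MPB_BULK_D13C = -16.6
MPB_BULK_D13C_SD = 1.9

#: Assumed biofilm lipid delta13C used in the protein back-calculation
#: (consistent with the fasting breath endpoint, rounded to a round value).
BIOFILM_LIPID_D13C_ASSUMED = -20.0

#: Breath-CO2 oxidation endpoints from the 14 most-positive (carbohydrate
#: metabolism) and 14 most-negative (stored-lipid metabolism) sandpiper
#: breath samples.  Member ids are not recoverable from the summary data.
STUDY_BREATH_ENDPOINTS = BreathEndpoints(
    k=14,
    carb_mean=-13.3,
    carb_sd=0.9,
    lip_mean=-20.4,
    lip_sd=0.9,
    carb_ids=(),
    lip_ids=(),
)

#: Diet-tissue trophic discrimination factors from captive dunlin
#: feeding trials.  Dispersions were not published; 0.5 per mil is a
#: captive-study-scale default (see docs/methods.md).
TDF_LIVER = TrophicDiscrimination(
    tissue="liver", d13C_mean=1.1, d13C_sd=0.5, d15N_mean=4.0, d15N_sd=0.5
)
TDF_MUSCLE = TrophicDiscrimination(
    tissue="muscle", d13C_mean=1.9, d13C_sd=0.5, d15N_mean=3.1, d15N_sd=0.5
)

#: Elemental C:N ratios of the model dietary endpoints (dimensionless).
CN_RATIOS = {
    "MPB": 8.1,
    "biofilm": 9.8,
    "small_invertebrates": 5.1,
    "polychaetes": 5.1,
}

#: The three-source diet endpoint sets used in the mixing models, one per
#: biofilm representation.  ``MPB-protein`` replaces the bulk MPB delta13C
#: with the back-calculated protein-fraction value (-19.9 +/- 1.9 per mil).
#: Polychaete and small-invertebrate endpoints are the study-site values;
#: the polychaete endpoint is the published pooled value (its exact pooling
#: arithmetic over the four survey rows is not recoverable from the
#: summaries, so the published endpoint is used verbatim).
def endpoint_set(variant: str, assumed_conc_n: float = 0.05) -> list[SourceSpec]:
    """Return the three SourceSpec endpoints for a biofilm variant.

    Parameters
    ----------
    variant:
        ``"BIOF"`` (surface-sediment biofilm), ``"MPB"`` (bulk
        microphytobenthos) or ``"MPB-protein"`` (back-calculated MPB
        protein fraction).
    assumed_conc_n:
        Nitrogen mass fraction assumed equal across sources; the carbon
        concentration is derived as ``assumed_conc_n * C:N`` (the source
        C:N ratios enter the model directly as relative carbon
        concentrations; see :func:`mudflatmix.mixing.concentrations_equal_n`).
    """
    from mudflatmix.mixing import concentrations_equal_n

    biofilm_by_variant = {
        "BIOF": ("biofilm", -19.7, 1.7, 6.4, 1.5, CN_RATIOS["biofilm"]),
        "MPB": ("MPB", -16.6, 1.9, 5.8, 0.7, CN_RATIOS["MPB"]),
        "MPB-protein": ("MPB-protein", -19.9, 1.9, 5.8, 0.7, CN_RATIOS["MPB"]),
    }
    if variant not in biofilm_by_variant:
        raise ValueError(f"unknown endpoint variant {variant!r}")
    rows = [
        biofilm_by_variant[variant],
        ("small_invertebrates", -11.7, 1.0, 8.4, 1.1, CN_RATIOS["small_invertebrates"]),
        ("polychaetes", -15.1, 1.9, 11.9, 1.2, CN_RATIOS["polychaetes"]),
    ]
    out = []
    for name, mc, sc, mn, sn, cn in rows:
        conc_c, conc_n = concentrations_equal_n(cn, assumed_conc_n)
        out.append(
            SourceSpec(
                name=name,
                mean_d13C=mc,
                sd_d13C=sc,
                mean_d15N=mn,
                sd_d15N=sn,
                conc_C=conc_c,
                conc_N=conc_n,
            )
        )
    return out


#: Liver cohort statistics of collected birds retained in the mixing models
#: (terrestrially feeding individuals already screened out):
#: (n, mean_d15N, sd_d15N, mean_d13C, sd_d13C) per capture cohort.
LIVER_COHORTS = {
    "western_sandpiper": [
        (8, 13.7, 1.6, -16.0, 0.8),
        (3, 12.9, 0.5, -15.9, 1.1),
    ],
    "dunlin": [
        (11, 12.9, 0.8, -15.6, 1.9),
    ],
}

#: Adipose lipid delta13C cohorts: (n, mean, sd).
ADIPOSE_COHORTS = {
    "western_sandpiper": (8, -19.7, 0.8),
    "dunlin": (11, -18.6, 1.3),
}

#: Breath cohort sizes actually sampled in the field.
BREATH_N = {"western_sandpiper": 69, "dunlin": 12}

#: Allometric turnover references: liver (or liver-equivalent) isotopic
#: half-lives from captive feeding studies.
TURNOVER_REFERENCES = [
    TurnoverReference(
        species_label="japanese_quail", tissue="liver", half_life_days=2.6, body_mass_g=96.0
    ),
    TurnoverReference(
        species_label="yellow_rumped_warbler", tissue="liver", half_life_days=1.0, body_mass_g=12.5
    ),
]

#: Spring-migration body masses (grams), by species and sex.
BODY_MASS_G = {
    "western_sandpiper": {"male": 25.0, "female": 27.5},
    "dunlin": {"male": 59.7, "female": 63.6},
}
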