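# Methods

This note records the models implemented in `mudflatmix`, their assumptions,
the defaults that matter, and the design decisions taken where the problem
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Setting

Small shorebirds (western sandpiper, dunlin) staging on estuarine mudflats
feed on intertidal biofilm and invertebrates. Biofilm is a macromolecular
mixture — roughly half carbohydrate by assimilated carbon, with smaller
lipid and protein fractions — and its components are metabolically routed to
different consumer pools: dietary carbohydrate mostly to oxidative energy
(and lipogenesis), dietary protein to the body-protein pool sampled by liver
tissue. δ¹⁵N traces only the protein pathway; bulk δ¹³C mixes all three.
The package therefore combines four models that together let bulk-tissue,
adipose and breath measurements be interpreted coherently.

## Pooling and screening (`foodweb`)

Dietary endpoints come from several field surveys of the same source, each
reported as (n, mean ± SD). Pooling uses n-weighted means and the exact
two-moment combined SD: total sum of squares = Σ(nᵢ−1)sᵢ² (within) +
Σnᵢ(x̄ᵢ−x̄)² (between), divided by N−1. Survey rows with n ≤ 2 and no
published SD contribute only their mean terms — no dispersion information
exists for them. Pooling is permutation-invariant (inputs are canonically
ordered before summation so floating-point results are bit-stable).

The polychaete endpoint is an exception: the four survey rows pool to
≈ −15.0/12.0‰ by this arithmetic, while the published endpoint is
−15.1 ± 1.9 / 11.9 ± 1.2‰ (n = 35); the exact pooling arithmetic behind the
published value is not recoverable from the summaries, so the published
endpoint is used verbatim in the mixing models (`datasets.endpoint_set`).

Consumers with strongly depleted δ¹³C carry an upland/terrestrial feeding
signal and are screened out before diet modelling. No threshold is
standard; the default −19.0‰ for liver/muscle separates all reported
terrestrial-signal individuals (−19.2‰ and below) from all marine cohort
means (−16.3‰ and above) at this site, and is configurable per tissue.
The comparison is strict (`<`), so a sample exactly at the threshold is
retained.

## Macromolecular routing (`routing`)

Forward model: δ¹³C_tissue = A(δ_c+Δ_c) + B(δ_l+Δ_l) + C(δ_p+Δ_p),
A+B+C = 1, where A/B/C are assimilated-carbon fractions (defaults 0.5 / 0.1
/ 0.4 for MPB from site-specific composition work) and Δ are
substrate→tissue discriminations. With Δ = 0 this is the bulk mass balance,
inverted for the protein fraction: δ_p = [δ_bulk − A·δ_c − B·δ_l]/C. The
inversion requires C > 0 and is the exact inverse of the forward model
(tested to 1e-12).

Inputs for the MPB back-calculation: bulk MPB −16.6‰; carbohydrate from the
carbohydrate-oxidation breath endpoint −13.3‰ (diet→breath discrimination
taken as 0); lipid assumed −20.0‰ (a round value consistent with the
fasting breath endpoint −20.4‰ and measured adipose −19.7/−18.6‰). The two
lipid constants are deliberately distinct config values: −20.0‰ is the
assumption inside the mass balance, −20.4‰ is the measured endpoint that
the sensitivity analysis shifts. Result: δ¹³C_prot = −19.875 → −19.9‰.

Sensitivity: breath = substrate + Δ, so substrate endpoints are measured
endpoints − Δ for Δ ∈ {−1, 0, +1}‰ by default, with the protein value
recomputed through the inversion each time (single code path). Direct
recomputation gives −21.3 / −18.3‰ at Δ = ∓1 rather than the ±1.5‰ shift of
the rounded base value (−21.4 / −18.4‰); the 0.1‰ difference is rounding
provenance, and the package reports the directly computed values.

## Breath-CO₂ fuel mixing (`breath`)

Breath CO₂ δ¹³C reflects the substrate currently oxidised. The cohort
spans fasting birds (stored lipid) to saturated feeders (dietary
carbohydrate), so the k most-negative and k most-positive samples (k = 14
at the study's n = 69) estimate the two endpoints; selection is by value,
deterministic, order-invariant, ties broken by sample id. Capture context
(`morning_return`) is metadata only and never forces membership. Each
remaining bird's carbohydrate fuel fraction is linear interpolation between
the endpoints after subtracting the diet→breath discrimination (default 0);
fractions outside [0,1] are clamped and flagged rather than discarded, so
cohort n is preserved while model violations stay visible. Endpoint members
are excluded from the cohort summary (n_intermediate = n − 2k). Endpoint
provenance is an explicit argument: a small cohort (e.g. 12 dunlin) can be
summarised against endpoints selected from a larger one.

## Concentration-dependent Bayesian mixing model (`mixing`)

Three sources, two isotopes (δ¹³C, δ¹⁵N), all consumers sharing one diet
proportion vector p on the simplex.

* Expected signature: μ_X(p) = Σᵢ pᵢ c_Xᵢ (δ_Xᵢ + Δ_X) / Σᵢ pᵢ c_Xᵢ with
  elemental concentrations c_Xᵢ and tissue TDF Δ_X.
* Observation model: consumer values are independent Gaussians around
  μ_X with variance Σᵢ wᵢ²(σ_Xᵢ² + σ_Δ²) (wᵢ the normalized
  concentration-proportion weights), plus ε² under the default
  `process_residual` error structure. ε captures consumer-level variation
  beyond the propagated process terms.
* Priors: symmetric Dirichlet(1,1,1) on p; half-normal (scale 1‰) on ε.
* Sampling: random-walk Metropolis on the additive log-ratio transform of
  p (the Dirichlet prior and ALR Jacobian combine to Σ αᵢ log pᵢ) and on
  log ε; per-chain proposal scales adapt toward ~30 % acceptance during
  burn-in and are frozen afterwards so the retained draws satisfy detailed
  balance. Defaults: 3 chains × 60 000 iterations, 10 000 burn-in.
  Chains are vectorised and the likelihood uses per-isotope sufficient
  statistics, so a full fit takes seconds. Split-chain R-hat and ESS
  (ArviZ) are always computed; R-hat > 1.1 raises a warning, never a
  silent pass.

**Elemental concentrations.** The study food web supplies only C:N ratios
(MPB 8.1, biofilm 9.8, small invertebrates 5.1, polychaetes 5.1). Two
single-assumption conventions can turn a C:N ratio into (c_C, c_N):
equal carbon fraction across sources (c_N = c_C/C:N,
`concentrations_from_cn`) or equal nitrogen fraction (c_C = c_N·C:N,
`concentrations_equal_n`). The package default for the study endpoints is
**equal nitrogen**: for this food web the C:N differences are driven by
carbohydrate-rich mucilage carbon while protein (hence N) content is
similar across sources, so N is the natural invariant — equivalently, the
published C:N values act directly as relative carbon concentrations. Only
concentration ratios enter the weights; the absolute level (default 5 % N,
putting carbon fractions at 26–49 %) is a display convention. Both
conventions are exposed; with equal concentrations the model reduces
exactly to plain proportional mixing.

**TDFs.** Captive-dunlin values: liver Δ¹³C 1.1‰, Δ¹⁵N 4.0‰; muscle 1.9‰ /
3.1‰. Their dispersions were not published; the default σ_Δ = 0.5‰ per
isotope is captive-study-scale uncertainty and is configurable (the CLI
`mix --tdf-sd` exposes it directly for sensitivity checks).

**Pseudo-consumers.** Individual tissue values were never distributed; only
cohort statistics (n, mean ± SD per capture date) are available. Mixing
fits that reproduce the study therefore draw Gaussian pseudo-individuals
per cohort and, by default, re-centre/re-scale each cohort to its published
mean and SD exactly (`pseudo_consumers(match_moments=True)`). The
likelihood depends on consumers only through per-isotope sufficient
statistics (n, Σx, Σx²), so moment matching makes the reproduced posterior
a function of the published statistics alone instead of one Gaussian draw's
luck — a raw n = 11 draw can land > 2 SE from its nominal mean and move
posterior medians by ~5 points.

**Mixing polygon.** The TDF-corrected mean consumer is tested against the
closed convex hull of the source means with an orientation-robust
half-plane test; collinear sources are reported as degenerate. The check
returns signed per-edge distances rather than a bare flag because the
geometry at this site is marginal: the western sandpiper mean sits ~0.05‰
outside the MPB-protein–polychaete edge, a distance far smaller than the
source SDs, which individual-level spread and source uncertainty absorb.

**Known reproduction behaviour** (computed by the tests and acceptance
script, not asserted beyond their stated tolerances): with the defaults
above, the BIOF and MPB-protein posterior medians for both species land
within ~2 percentage points of the published values; the bulk-MPB variant
differs by ~5–7 points, consistent with the original tool's unreported
sampler settings and error structure mattering most where the source
triangle is widest.

## Turnover allometry (`turnover`)

Isotopic incorporation rate scales with body mass as mass^−0.25, so
half-life scales as mass^0.25: t½(target) = t½(ref)·(m_t/m_r)^0.25.
References: Japanese quail liver (2.6 d, 96 g) and yellow-rumped warbler
(~1 d, 12.5 g); targets are migration masses (western sandpiper 25/27.5 g,
dunlin 59.7/63.6 g by sex). Ranges apply every reference to every target
mass and take min/max — the warbler anchors the lower bound, the quail the
upper (dunlin: 1.5–2.3 d). Residency windows are n × the half-life bounds
(default n = 2, the conventional point at which a fast tissue mostly
reflects local diet). Display rounding is half-up to 1 decimal; internal
values keep full precision.

## Synthetic data (`synthetic`)

The generators emulate the statistical structure the analysis assumes:
Gaussian pseudo-individuals for sources and consumers (consumer
expectations computed through the same concentration-weighted mixing mean +
TDF used in inference — generation and inference intentionally share the
forward model), optional terrestrial outliers injected at a stated rate,
and a breath cohort of n_fasting birds at the lipid endpoint, a saturated
group at the carbohydrate endpoint, and intermediates with Beta-distributed
fuel fractions (Beta parameterised by mean/SD; defaults 0.407/0.144 at the
study's 69-bird scale with 0.9‰ observation noise). All streams derive
from one integer seed via labelled `SeedSequence` substreams (CRC-stable
labels), so a truth record regenerates any dataset bit-identically.

What passing synthetic tests does *not* show about real data: real biofilm
is spatially and temporally patchy, consumer diets vary among individuals
(the model assumes one shared p), real breath cohorts mix fasting states
continuously rather than in three groups, and isotope errors may be
non-Gaussian. The generators encode none of these, by design — they test
the estimators under the model's own assumptions at the study's printed
sample sizes and noise scales.

## Numerical choices and degenerate inputs

* Pooling: single summaries pass through unchanged; mixed source names and
  empty lists are validation errors.
* Routing: C = 0 is a domain error; compositions must sum to 1 within 1e-9.
* Breath: coincident endpoints cannot be constructed (carb must exceed
  lip); 2k ≥ n is rejected so an intermediate pool always exists.
* Mixing: simplex draws are validated to 1e-9; an all-zero-variance
  likelihood degenerates to a point-mass check rather than dividing by
  zero; empty chains are rejected; the polygon test treats |2·area| <
  1e-12 as collinear.
* MCMC seeds: any integer; all derived seeds stay below 2³¹.

## Problem sizes

Default fits (3 × 60k draws) take ~3–5 s each; the full test suite runs in
well under a minute and the acceptance script in ~10 s on one CPU. These
sizes give R-hat ≤ 1.003 and ESS in the thousands for every reported fit;
doubling the draw count moves medians by less than the Monte-Carlo
standard error (tested).

## Limitations

* Two isotopes, exactly three sources; no covariates, hierarchical random
  effects, or informative (e.g. faecal-study) priors.
* TDF dispersions and the original tool's sampler settings are unknown;
  reproduced credible intervals are narrower than the published ones for
  some fits even where medians agree.
* The routing model is bulk-macromolecule only: no amino-acid or
  fatty-acid level routing, no TCA-cycle exchange, no respiratory-quotient
  constraint.
* No sulfur/hydrogen isotopes and no spatial substructure beyond a
  free-text site label.
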