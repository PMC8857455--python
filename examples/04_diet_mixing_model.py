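"""Bayesian diet reconstruction: biofilm vs invertebrates in liver protein.

Fits the three-source, two-isotope, concentration-dependent mixing model
for western sandpiper liver using the MPB-protein endpoint set: the
back-calculated protein fraction of microphytobenthos (-19.9 +/- 1.9 per
mil) against small invertebrates and polychaetes, with captive-shorebird
liver discrimination factors (D13C 1.1, D15N 4.0 per mil).  Consumers are
seeded pseudo-individuals moment-matched to the published liver cohorts.
"""

from mudflatmix import datasets
from mudflatmix.mixing import (
    MixingModelSpec,
    in_mixing_polygon,
    sample_posterior,
    summarize_posterior,
)
from mudflatmix.synthetic import pseudo_consumers

consumers = tuple(pseudo_consumers("western_sandpiper", seed=1))
sources = tuple(datasets.endpoint_set("MPB-protein"))

spec = MixingModelSpec(sources=sources, tdf=datasets.TDF_LIVER, consumers=consumers)
chains = sample_posterior(spec, n_chains=3, n_iter=60_000, n_burn=10_000, seed=1)
summary = summarize_posterior(chains)

print("western sandpiper liver, MPB-protein endpoint set:")
for name, med, lo, hi in zip(
    summary.source_names, summary.median_pct, summary.ci_low_pct, summary.ci_high_pct
):
    print(f"  {name:22s} median {med:5.1f}%   95% CrI {lo:5.1f}-{hi:5.1f}%  "
          f"(R-hat {summary.rhat[name]:.3f})")
# -> MPB-protein contributes a median of about a third of liver protein,
#    polychaetes about half, small invertebrates the remainder — biofilm is
#    a major protein source for a supposedly invertebrate-eating shorebird.

mean_consumer = (
    sum(c for c, _ in consumers) / len(consumers),
    sum(n for _, n in consumers) / len(consumers),
)
check = in_mixing_polygon(mean_consumer, sources, datasets.TDF_LIVER)
print(f"\nmean consumer inside mixing polygon: {check.inside}; "
      f"signed edge distances (per mil): "
      + ", ".join(f"{d:+.2f}" for d in check.signed_edge_distances))
# Positive distances mean the TDF-corrected consumer sits that far inside
# each triangle edge; a small negative value flags a marginal geometry.
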