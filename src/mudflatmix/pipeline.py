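"""End-to-end orchestration of the stopover-diet analysis.

``run_study`` executes the full chain — food-web pooling, terrestrial
screening, macromolecular routing (protein back-calculation + diet-breath
sensitivity), breath fuel mixing, the Bayesian diet mixing model for each
biofilm endpoint variant, and allometric turnover scaling — writing one
CSV/JSON artifact per stage plus a Markdown report.  Identical config and
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

import mudflatmix
from mudflatmix import breath as breath_mod
from mudflatmix import datasets, foodweb, mixing, routing, synthetic, turnover
from mudflatmix.errors import ValidationError

log = logging.getLogger("mudflatmix")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run (and re-run) the full analysis."""

    out_dir: str
    seed: int
    species: tuple[str, ...] = ("western_sandpiper", "dunlin")
    endpoint_variants: tuple[str, ...] = ("BIOF", "MPB", "MPB-protein")
    tissue: str = "liver"
    screening_threshold: float = foodweb.DEFAULT_TERRESTRIAL_THRESHOLD
    # routing
    macro_A: float = 0.5
    macro_B: float = 0.1
    macro_C: float = 0.4
    biofilm_lipid_d13C: float = datasets.BIOFILM_LIPID_D13C_ASSUMED
    mpb_bulk_d13C: float = datasets.MPB_BULK_D13C
    delta_grid: tuple[float, ...] = (-1.0, 0.0, 1.0)
    # breath
    breath_k: int = 14
    breath_path: str | None = None  # None: simulate a study-scale cohort
    # mixing
    assumed_conc_N: float = 0.05
    prior_alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    error_structure: str = "process_residual"
    n_chains: int = 3
    n_iter: int = 60_000
    n_burn: int = 10_000
    # inputs
    foodweb_path: str | None = None  # None: packaged study table
    samples_path: str | None = None  # None: pseudo-consumers from cohorts

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for stochastic stages")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Aggregated stage outputs; every number also lives in a stage file."""

    pooled_endpoints: list[foodweb.PooledEndpoint]
    screening: dict
    protein_backcalc: float
    sensitivity: list[routing.SensitivityRow]
    breath_endpoints: breath_mod.BreathEndpoints
    fuel_summary: breath_mod.FuelMixResult
    posteriors: dict[tuple[str, str], mixing.PosteriorSummary]
    polygon: dict[str, mixing.PolygonCheck]
    turnover: dict[str, turnover.TurnoverEstimate]
    version: str
    config_hash: str


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; lists become tuples."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("species", "endpoint_variants", "delta_grid", "prior_alpha"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_study(config: RunConfig) -> RunReport:
    """Run the complete analysis; see module docstring for the stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- food web -------------------------------------------------------
    with _stage("foodweb"):
        summaries = (
            foodweb.read_food_web(config.foodweb_path)
            if config.foodweb_path
            else datasets.load_foodweb()
        )
        by_source: dict[str, list] = {}
        for s in summaries:
            by_source.setdefault(s.source_name, []).append(s)
        pooled = [foodweb.pool_endpoints(v) for v in by_source.values()]
        foodweb.write_endpoints(pooled, out / "pooled_endpoints.csv")

    # --- screening ------------------------------------------------------
    with _stage("screening"):
        if config.samples_path:
            samples = foodweb.read_samples(config.samples_path)
        else:
            # no individual tissue data shipped: screen a synthetic cohort
            sim = synthetic.SimConfig(seed=config.seed, outlier_rate=0.1, n_consumers=25)
            samples = synthetic.gen_consumers(sim)
        screen = foodweb.screen_terrestrial(samples, config.screening_threshold)
        screening_summary = {
            "threshold_d13C": config.screening_threshold,
            "n_retained": len(screen.retained),
            "n_flagged_terrestrial": len(screen.flagged_terrestrial),
            "flagged_ids": [s.sample_id for s in screen.flagged_terrestrial],
        }
        (out / "screening.json").write_text(json.dumps(screening_summary, indent=2))

    # --- breath ---------------------------------------------------------
    with _stage("breath"):
        if config.breath_path:
            breath_samples = breath_mod.read_breath(config.breath_path)
        else:
            sim = synthetic.SimConfig(seed=config.seed)
            breath_samples = synthetic.gen_breath(sim)
        endpoints = breath_mod.select_endpoints(breath_samples, k=config.breath_k)
        fuel = breath_mod.summarize_fuel(breath_samples, endpoints)
        (out / "breath_endpoints.json").write_text(
            json.dumps(
                {
                    "k": endpoints.k,
                    "carb_mean": endpoints.carb_mean,
                    "carb_sd": endpoints.carb_sd,
                    "lip_mean": endpoints.lip_mean,
                    "lip_sd": endpoints.lip_sd,
                    "carb_ids": list(endpoints.carb_ids),
                    "lip_ids": list(endpoints.lip_ids),
                },
                indent=2,
            )
        )
        breath_mod.write_fuel_result(fuel, out / "fuel_fractions.csv")

    # --- routing --------------------------------------------------------
    with _stage("routing"):
        comp = routing.MacroComposition(config.macro_A, config.macro_B, config.macro_C)
        # carbohydrate endpoint from the measured (study) breath endpoints
        carb = datasets.STUDY_BREATH_ENDPOINTS.carb_mean
        lip_fasting = datasets.STUDY_BREATH_ENDPOINTS.lip_mean
        prot = routing.backcalc_protein_c13(
            config.mpb_bulk_d13C, comp, carb, config.biofilm_lipid_d13C
        )
        grid = routing.sensitivity_grid(
            carb, lip_fasting, config.mpb_bulk_d13C, comp, list(config.delta_grid)
        )
        routing.write_sensitivity(grid, out / "sensitivity.csv")

    # --- mixing ---------------------------------------------------------
    posteriors: dict[tuple[str, str], mixing.PosteriorSummary] = {}
    polygon: dict[str, mixing.PolygonCheck] = {}
    with _stage("mixing"):
        tdf = datasets.TDF_LIVER if config.tissue == "liver" else datasets.TDF_MUSCLE
        rows = []
        for species in config.species:
            consumers = synthetic.pseudo_consumers(species, config.seed)
            mean_pt = (
                sum(c for c, _ in consumers) / len(consumers),
                sum(n for _, n in consumers) / len(consumers),
            )
            for variant in config.endpoint_variants:
                sources = datasets.endpoint_set(variant, config.assumed_conc_N)
                spec = mixing.MixingModelSpec(
                    sources=tuple(sources),
                    tdf=tdf,
                    consumers=tuple(consumers),
                    prior_alpha=config.prior_alpha,
                    error_structure=config.error_structure,  # type: ignore[arg-type]
                )
                chains = mixing.sample_posterior(
                    spec,
                    n_chains=config.n_chains,
                    n_iter=config.n_iter,
                    n_burn=config.n_burn,
                    seed=config.seed,
                )
                summary = mixing.summarize_posterior(chains)
                posteriors[(species, variant)] = summary
                polygon[f"{species}/{variant}"] = mixing.in_mixing_polygon(
                    mean_pt, sources, tdf
                )
                df = mixing.summary_frame(summary)
                df.insert(0, "variant", variant)
                df.insert(0, "species", species)
                rows.append(df)
        pd.concat(rows).to_csv(out / "posterior_summaries.csv", index=False)

    # --- turnover -------------------------------------------------------
    with _stage("turnover"):
        turnover_by_species = {}
        recs = []
        for species, masses in datasets.BODY_MASS_G.items():
            est = turnover.estimate_turnover(
                datasets.TURNOVER_REFERENCES, masses.values()
            )
            turnover_by_species[species] = est
            recs.append(
                {
                    "species": species,
                    "half_life_low_days": est.half_life_days[0],
                    "half_life_high_days": est.half_life_days[1],
                    "residency_low_days": est.residency_window_days[0],
                    "residency_high_days": est.residency_window_days[1],
                }
            )
        pd.DataFrame(recs).to_csv(out / "turnover.csv", index=False)

    report = RunReport(
        pooled_endpoints=pooled,
        screening=screening_summary,
        protein_backcalc=prot,
        sensitivity=grid,
        breath_endpoints=endpoints,
        fuel_summary=fuel,
        posteriors=posteriors,
        polygon=polygon,
        turnover=turnover_by_species,
        version=mudflatmix.__version__,
        config_hash=config.config_hash(),
    )
    _write_report(report, config, out)
    return report


def _write_report(report: RunReport, config: RunConfig, out: Path) -> None:
    lines = [
        "# Stopover diet analysis report",
        "",
        f"- package version: {report.version}",
        f"- config hash: {report.config_hash}",
        f"- seed: {config.seed}",
        "",
        "## Pooled dietary endpoints",
        "",
        "| source | n | d13C | sd | d15N | sd |",
        "|---|---|---|---|---|---|",
    ]
    for e in report.pooled_endpoints:
        fmt = lambda v: "" if v is None else f"{v:.2f}"
        lines.append(
            f"| {e.source_name} | {e.n_total} | {fmt(e.mean_d13C)} | {fmt(e.sd_d13C)} "
            f"| {fmt(e.mean_d15N)} | {fmt(e.sd_d15N)} |"
        )
    lines += [
        "",
        "## Screening",
        "",
        f"threshold {report.screening['threshold_d13C']} per mil: "
        f"{report.screening['n_retained']} retained, "
        f"{report.screening['n_flagged_terrestrial']} flagged terrestrial",
        "",
        "## Macromolecular routing",
        "",
        f"Back-calculated MPB protein d13C: {report.protein_backcalc:.3f} per mil "
        f"({report.protein_backcalc:.1f} at display precision)",
        "",
        "| diet-breath D | d13C_carb | d13C_lip | d13C_prot |",
        "|---|---|---|---|",
    ]
    for r in report.sensitivity:
        lines.append(
            f"| {r.delta_diet_breath:+.1f} | {r.d13C_carb:.1f} | {r.d13C_lip:.1f} "
            f"| {r.d13C_prot:.1f} |"
        )
    ep = report.breath_endpoints
    fu = report.fuel_summary
    lines += [
        "",
        "## Breath fuel mixing",
        "",
        f"endpoints (k={ep.k}): carbohydrate {ep.carb_mean:.1f} +/- {ep.carb_sd:.1f}, "
        f"lipid {ep.lip_mean:.1f} +/- {ep.lip_sd:.1f} per mil",
        f"intermediate cohort (n={fu.n_intermediate}): mean carbohydrate fraction "
        f"{100 * fu.mean_fraction:.1f} +/- {100 * fu.sd_fraction:.1f} %",
        "",
        "## Diet mixing model posteriors",
        "",
        "| species | variant | source | median % | 95% CrI | R-hat |",
        "|---|---|---|---|---|---|",
    ]
    for (species, variant), s in report.posteriors.items():
        for i, name in enumerate(s.source_names):
            lines.append(
                f"| {species} | {variant} | {name} | {s.median_pct[i]:.1f} "
                f"| {s.ci_low_pct[i]:.1f}-{s.ci_high_pct[i]:.1f} | {s.rhat[name]:.3f} |"
            )
    lines += ["", "## Turnover", ""]
    for species, est in report.turnover.items():
        lo, hi = est.half_life_days
        rlo, rhi = est.residency_window_days
        lines.append(
            f"- {species}: liver half-life {lo:.1f}-{hi:.1f} d, "
            f"2-half-life residency window {rlo:.1f}-{rhi:.1f} d"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")

    payload = {
        "version": report.version,
        "config_hash": report.config_hash,
        "protein_backcalc_d13C": report.protein_backcalc,
        "fuel_mean_fraction": report.fuel_summary.mean_fraction,
        "posterior_medians_pct": {
            f"{sp}/{var}": dict(zip(s.source_names, s.median_pct))
            for (sp, var), s in report.posteriors.items()
        },
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
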