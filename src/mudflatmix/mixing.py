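"""Concentration-dependent Bayesian stable-isotope mixing model.

Estimates the diet proportions p = (p1, p2, p3) of three dietary sources
from consumer delta13C/delta15N observations.  Sources differ in elemental
concentration, so a source rich in carbon dominates the carbon balance of
the mixture: for isotope X in {C, N} the expected consumer signature is the
concentration-weighted mean

    mu_X(p) = sum_i p_i c_Xi (delta_Xi + D_X) / sum_i p_i c_Xi,

with c_Xi the source's elemental concentration and D_X the diet-tissue
trophic discrimination factor (TDF).  Observations are modelled as Gaussian
around mu_X with variance propagated from the source and TDF dispersions
through the normalized weights w_i = p_i c_Xi / sum_j p_j c_Xj:

    var_X(p) = sum_i w_i^2 (sigma_Xi^2 + sigma_D^2)  [+ eps^2 residual],

the optional residual scale eps capturing consumer-level variation beyond
the process terms.  Inference is by random-walk Metropolis on an additive
log-ratio transform of the simplex (plus log eps), with a Dirichlet prior
on p and a half-normal prior on eps.  Convergence is monitored with the
split-chain R-hat statistic and effective sample size (via ArviZ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import arviz as az
import numpy as np
import pandas as pd

from mudflatmix.errors import DomainError, ValidationError

_SIMPLEX_TOL = 1e-9

#: Default half-normal prior scale for the residual sd (per mil).
RESIDUAL_PRIOR_SCALE = 1.0

#: R-hat above which sample_posterior emits a non-convergence warning.
RHAT_WARN = 1.1


@dataclass(frozen=True)
class SourceSpec:
    """A dietary source: isotope means/sds and elemental concentrations."""

    name: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    conc_C: float
    conc_N: float

    def __post_init__(self) -> None:
        if self.sd_d13C <= 0 or self.sd_d15N <= 0:
            raise ValidationError(f"{self.name}: source sds must be > 0")
        if self.conc_C <= 0 or self.conc_N <= 0:
            raise ValidationError(f"{self.name}: concentrations must be > 0")


@dataclass(frozen=True)
class TrophicDiscrimination:
    """Diet-to-tissue discrimination factors for one consumer tissue."""

    tissue: str
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float

    def __post_init__(self) -> None:
        if self.tissue not in ("liver", "muscle"):
            raise ValidationError(f"tissue must be liver or muscle, got {self.tissue!r}")
        if self.d13C_sd < 0 or self.d15N_sd < 0:
            raise ValidationError("TDF sds must be >= 0")


@dataclass(frozen=True)
class DietProportions:
    """A point on the 3-simplex: diet proportions of the three sources."""

    p: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(x < 0 or x > 1 for x in self.p):
            raise ValidationError(f"proportions outside [0, 1]: {self.p}")
        if abs(sum(self.p) - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(f"proportions must sum to 1: {self.p}")


@dataclass(frozen=True)
class MixingModelSpec:
    """Full specification of a three-source, two-isotope mixing model."""

    sources: tuple[SourceSpec, SourceSpec, SourceSpec]
    tdf: TrophicDiscrimination
    consumers: tuple[tuple[float, float], ...]  # (d13C, d15N) per individual
    prior_alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    error_structure: Literal["process", "process_residual"] = "process_residual"

    def __post_init__(self) -> None:
        if len(self.sources) != 3:
            raise ValidationError(f"exactly 3 sources required, got {len(self.sources)}")
        if len(self.consumers) < 2:
            raise ValidationError("at least 2 consumers required")
        if any(a <= 0 for a in self.prior_alpha):
            raise ValidationError("prior_alpha must be positive elementwise")
        if self.error_structure not in ("process", "process_residual"):
            raise ValidationError(f"unknown error_structure {self.error_structure!r}")


@dataclass(frozen=True)
class MixingChains:
    """Post-burn-in MCMC draws: proportions, residual scale, diagnostics."""

    p: np.ndarray  # (n_chains, n_kept, 3)
    residual_scale: np.ndarray  # (n_chains, n_kept)
    acceptance_rate: float
    rhat: dict[str, float]
    ess: dict[str, float]
    source_names: tuple[str, str, str]
    seed: int


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-source median and central 95% credible interval, in percent."""

    source_names: tuple[str, ...]
    median_pct: tuple[float, ...]
    ci_low_pct: tuple[float, ...]
    ci_high_pct: tuple[float, ...]
    rhat: dict[str, float]
    ess: dict[str, float]
    acceptance_rate: float


@dataclass(frozen=True)
class PolygonCheck:
    """Mixing-polygon membership of a TDF-corrected consumer point.

    ``signed_edge_distances`` are per-edge distances of the corrected
    consumer from each triangle edge, positive towards the interior, so a
    marginally outside point reports a small negative distance.
    """

    inside: bool
    degenerate: bool
    signed_edge_distances: tuple[float, ...]

    def __bool__(self) -> bool:
        return self.inside


def concentrations_from_cn(
    cn_ratio: float, assumed_conc_C: float = 0.40
) -> tuple[float, float]:
    """Derive (conc_C, conc_N) mass fractions from an elemental C:N ratio.

    The carbon mass fraction is assumed constant across sources (organic
    carbon content varies little); the C:N ratio then fixes the nitrogen
    fraction as ``assumed_conc_C / cn_ratio``.
    """
    if cn_ratio <= 0:
        raise ValidationError(f"cn_ratio must be > 0, got {cn_ratio}")
    if not 0 < assumed_conc_C <= 1:
        raise ValidationError(f"assumed_conc_C must be in (0, 1], got {assumed_conc_C}")
    return assumed_conc_C, assumed_conc_C / cn_ratio


def concentrations_equal_n(
    cn_ratio: float, assumed_conc_N: float = 0.05
) -> tuple[float, float]:
    """Derive (conc_C, conc_N) assuming equal nitrogen fraction per source.

    The complementary convention to :func:`concentrations_from_cn`: the
    nitrogen mass fraction is held constant across sources and the carbon
    fraction scales with C:N, ``conc_C = assumed_conc_N * cn_ratio``.
    For biofilm-type food webs this is the natural reading — nitrogen
    tracks protein content, which varies little among the sources, while
    the large C:N differences come from carbohydrate-rich mucilage carbon.
    Only concentration *ratios* matter to the mixing weights, so the
    absolute ``assumed_conc_N`` is a display convention (default 5% N,
    which puts organic carbon fractions in a realistic 25-50% band).
    """
    if cn_ratio <= 0:
        raise ValidationError(f"cn_ratio must be > 0, got {cn_ratio}")
    if not 0 < assumed_conc_N <= 1:
        raise ValidationError(f"assumed_conc_N must be in (0, 1], got {assumed_conc_N}")
    conc_c = assumed_conc_N * cn_ratio
    if conc_c > 1:
        raise ValidationError(
            f"assumed_conc_N={assumed_conc_N} with C:N={cn_ratio} implies "
            f"carbon fraction {conc_c} > 1"
        )
    return conc_c, assumed_conc_N


def _iso_arrays(
    sources: Sequence[SourceSpec], tdf: TrophicDiscrimination, isotope: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    if isotope == "C":
        mu = np.array([s.mean_d13C for s in sources])
        sd = np.array([s.sd_d13C for s in sources])
        conc = np.array([s.conc_C for s in sources])
        return mu, sd, conc, tdf.d13C_mean, tdf.d13C_sd
    if isotope == "N":
        mu = np.array([s.mean_d15N for s in sources])
        sd = np.array([s.sd_d15N for s in sources])
        conc = np.array([s.conc_N for s in sources])
        return mu, sd, conc, tdf.d15N_mean, tdf.d15N_sd
    raise ValidationError(f"isotope must be 'C' or 'N', got {isotope!r}")


def expected_signature(
    p: DietProportions | Sequence[float],
    sources: Sequence[SourceSpec],
    tdf: TrophicDiscrimination,
    isotope: Literal["C", "N"],
) -> float:
    """Concentration-weighted expected consumer signature for one isotope."""
    pv = np.asarray(p.p if isinstance(p, DietProportions) else p, dtype=float)
    mu, _, conc, tdf_mean, _ = _iso_arrays(sources, tdf, isotope)
    den = float(np.sum(pv * conc))
    if den <= 0:
        raise DomainError("zero total concentration weight")
    return float(np.sum(pv * conc * (mu + tdf_mean)) / den)


def log_likelihood(
    spec: MixingModelSpec,
    p: DietProportions | Sequence[float],
    residual_scale: float = 0.0,
) -> float:
    """Gaussian log-likelihood of the consumers under diet proportions p.

    Sums, over consumers and both isotopes, normal log-densities centred on
    :func:`expected_signature` with variance propagated through the squared
    normalized concentration-proportion weights (plus the residual term
    when the spec's error structure enables it).
    """
    pv = np.asarray(p.p if isinstance(p, DietProportions) else p, dtype=float)
    if not np.all(np.isfinite(pv)) or not np.isfinite(residual_scale):
        raise DomainError("non-finite inputs to log_likelihood")
    if spec.error_structure == "process_residual" and residual_scale <= 0:
        raise ValidationError("residual_scale must be > 0 under process_residual")
    obs = np.asarray(spec.consumers, dtype=float)  # (n, 2): d13C, d15N
    total = 0.0
    for col, isotope in ((0, "C"), (1, "N")):
        mu_s, sd_s, conc, tdf_mean, tdf_sd = _iso_arrays(spec.sources, spec.tdf, isotope)
        den = np.sum(pv * conc)
        if den <= 0:
            raise DomainError("zero total concentration weight")
        w = pv * conc / den
        mu = np.sum(w * (mu_s + tdf_mean))
        var = np.sum(w**2 * (sd_s**2 + tdf_sd**2))
        if spec.error_structure == "process_residual":
            var = var + residual_scale**2
        if var <= 0:
            # degenerate spec (all sds zero, no residual): point mass
            return 0.0 if np.allclose(obs[:, col], mu) else -np.inf
        x = obs[:, col]
        total += float(
            -0.5 * len(x) * np.log(2 * np.pi * var) - np.sum((x - mu) ** 2) / (2 * var)
        )
    return total


# ---------------------------------------------------------------------------
# MCMC


def _softmax3(z: np.ndarray) -> np.ndarray:
    """Map (nc, 2) unconstrained coordinates to (nc, 3) simplex points."""
    full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _log_post_batch(
    z: np.ndarray,
    u: np.ndarray,
    stats: list[tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float, float, int]],
    alpha: np.ndarray,
    with_residual: bool,
    prior_only: bool,
) -> np.ndarray:
    """Unnormalised log posterior in transformed space, vectorised over chains.

    The additive log-ratio Jacobian folds the Dirichlet(alpha) prior into
    sum_i alpha_i log p_i; the log-residual transform contributes u plus a
    half-normal prior on exp(u).
    """
    p = _softmax3(z)
    logp = np.log(np.clip(p, 1e-300, None))
    out = logp @ alpha  # Dirichlet prior + ALR Jacobian
    eps2 = np.zeros_like(u)
    if with_residual:
        eps = np.exp(u)
        out += u - eps**2 / (2 * RESIDUAL_PRIOR_SCALE**2)
        eps2 = eps**2
    if prior_only:
        return out
    for mu_s, sd2_tdf, conc, sx, sxx, _, _, n in stats:
        den = p @ conc
        w = p * conc / den[:, None]
        mu = w @ mu_s
        var = (w**2) @ sd2_tdf
        if with_residual:
            var = var + eps2
        out += -0.5 * n * np.log(2 * np.pi * var) - (sxx - 2 * mu * sx + n * mu**2) / (
            2 * var
        )
    return out


def sample_posterior(
    spec: MixingModelSpec,
    n_chains: int = 3,
    n_iter: int = 60_000,
    n_burn: int = 10_000,
    seed: int = 0,
    prior_only: bool = False,
) -> MixingChains:
    """Random-walk Metropolis sampling of the diet-proportion posterior.

    The simplex is parameterised by an additive log-ratio transform (two
    unconstrained coordinates; the Jacobian is included in the target) and,
    under the ``process_residual`` error structure, the residual scale by
    its logarithm.  Per-chain proposal scales adapt towards ~30% acceptance
    during burn-in and are frozen afterwards, preserving detailed balance
    over the retained draws.  Fully reproducible for a given seed.

    Emits a warning (never fails silently) when the split-chain R-hat of
    any proportion exceeds ``RHAT_WARN``.
    """
    if n_iter <= n_burn:
        raise ValidationError(f"n_iter ({n_iter}) must exceed n_burn ({n_burn})")
    if n_chains < 1:
        raise ValidationError("need at least one chain")
    rng = np.random.default_rng(seed)
    with_residual = spec.error_structure == "process_residual"
    alpha = np.asarray(spec.prior_alpha, dtype=float)

    obs = np.asarray(spec.consumers, dtype=float)
    stats = []
    for col, isotope in ((0, "C"), (1, "N")):
        mu_s, sd_s, conc, tdf_mean, tdf_sd = _iso_arrays(spec.sources, spec.tdf, isotope)
        x = obs[:, col]
        stats.append(
            (
                mu_s + tdf_mean,
                sd_s**2 + tdf_sd**2,
                conc,
                float(x.sum()),
                float((x**2).sum()),
                tdf_mean,
                tdf_sd,
                len(x),
            )
        )

    dim = 3 if with_residual else 2
    # Overdispersed starts: chains begin at distinct corners of the simplex.
    z = rng.normal(0.0, 2.0, size=(n_chains, 2))
    u = np.full(n_chains, np.log(0.5)) + rng.normal(0.0, 0.5, size=n_chains)
    log_step = np.full(n_chains, np.log(0.5))
    lp = _log_post_batch(z, u, stats, alpha, with_residual, prior_only)

    n_kept = n_iter - n_burn
    kept_p = np.empty((n_chains, n_kept, 3))
    kept_eps = np.zeros((n_chains, n_kept))
    accepted_post = 0

    normals = rng.normal(size=(n_iter, n_chains, dim))
    log_unif = np.log(rng.uniform(size=(n_iter, n_chains)))

    for t in range(n_iter):
        step = np.exp(log_step)[:, None]
        dz = normals[t, :, :2] * step
        z_prop = z + dz
        if with_residual:
            u_prop = u + normals[t, :, 2] * step[:, 0]
        else:
            u_prop = u
        lp_prop = _log_post_batch(z_prop, u_prop, stats, alpha, with_residual, prior_only)
        accept = log_unif[t] < (lp_prop - lp)
        z[accept] = z_prop[accept]
        u[accept] = u_prop[accept]
        lp[accept] = lp_prop[accept]
        if t < n_burn:
            log_step += 0.05 * (accept.astype(float) - 0.3)
        else:
            accepted_post += int(accept.sum())
            k = t - n_burn
            kept_p[:, k, :] = _softmax3(z)
            if with_residual:
                kept_eps[:, k] = np.exp(u)

    names = tuple(s.name for s in spec.sources)
    idata = az.from_dict(posterior={f"p_{n}": kept_p[:, :, i] for i, n in enumerate(names)})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {n: float(rhat_ds[f"p_{n}"].values) for n in names}
    ess = {n: float(ess_ds[f"p_{n}"].values) for n in names}
    worst = max(rhat.values())
    if n_chains > 1 and worst > RHAT_WARN:
        warnings.warn(
            f"MCMC may not have converged: max split-chain R-hat = {worst:.3f} "
            f"(threshold {RHAT_WARN}); inspect chains / increase n_iter.",
            RuntimeWarning,
            stacklevel=2,
        )
    return MixingChains(
        p=kept_p,
        residual_scale=kept_eps,
        acceptance_rate=accepted_post / max(n_kept * n_chains, 1),
        rhat=rhat,
        ess=ess,
        source_names=names,
        seed=seed,
    )


def summarize_posterior(chains: MixingChains) -> PosteriorSummary:
    """Pool chains and report per-source medians and 95% credible intervals
    (percent scale), carrying the sampler diagnostics along."""
    if chains.p.size == 0:
        raise ValidationError("empty chains: nothing to summarize")
    flat = chains.p.reshape(-1, 3)
    med = np.median(flat, axis=0) * 100.0
    lo = np.quantile(flat, 0.025, axis=0) * 100.0
    hi = np.quantile(flat, 0.975, axis=0) * 100.0
    return PosteriorSummary(
        source_names=chains.source_names,
        median_pct=tuple(float(v) for v in med),
        ci_low_pct=tuple(float(v) for v in lo),
        ci_high_pct=tuple(float(v) for v in hi),
        rhat=chains.rhat,
        ess=chains.ess,
        acceptance_rate=chains.acceptance_rate,
    )


def in_mixing_polygon(
    consumer: tuple[float, float],
    sources: Sequence[SourceSpec],
    tdf: TrophicDiscrimination,
) -> PolygonCheck:
    """Test whether a TDF-corrected consumer lies in the source triangle.

    The consumer point (d13C, d15N) is corrected by subtracting the TDF
    means and tested against the closed convex hull of the three source
    means with an orientation-robust half-plane test.  A collinear source
    triangle is reported as degenerate (and not inside).
    """
    if len(sources) != 3:
        raise ValidationError("mixing polygon requires exactly 3 sources")
    pt = np.array([consumer[0] - tdf.d13C_mean, consumer[1] - tdf.d15N_mean])
    verts = np.array([[s.mean_d13C, s.mean_d15N] for s in sources])
    v0, v1, v2 = verts

    def _cross(a: np.ndarray, b: np.ndarray) -> float:
        return float(a[0] * b[1] - a[1] * b[0])

    area2 = _cross(v1 - v0, v2 - v0)
    if abs(area2) < 1e-12:
        return PolygonCheck(inside=False, degenerate=True, signed_edge_distances=())
    orient = 1.0 if area2 > 0 else -1.0
    dists = []
    for i in range(3):
        a, b = verts[i], verts[(i + 1) % 3]
        edge = b - a
        # positive towards the triangle interior
        d = orient * _cross(edge, pt - a) / float(np.hypot(*edge))
        dists.append(d)
    inside = all(d >= -1e-12 for d in dists)
    return PolygonCheck(inside=inside, degenerate=False, signed_edge_distances=tuple(dists))


def export_chains(chains: MixingChains, path: str | Path) -> None:
    """Write pooled draws as CSV: draw, chain, p_<source>..., residual_scale."""
    n_chains, n_kept, _ = chains.p.shape
    recs = {
        "draw": np.tile(np.arange(n_kept), n_chains),
        "chain": np.repeat(np.arange(n_chains), n_kept),
    }
    for i, name in enumerate(chains.source_names):
        recs[f"p_{name}"] = chains.p[:, :, i].reshape(-1)
    recs["residual_scale"] = chains.residual_scale.reshape(-1)
    pd.DataFrame(recs).to_csv(path, index=False)


def summary_frame(summary: PosteriorSummary) -> pd.DataFrame:
    """Posterior summary as a tidy DataFrame (one row per source)."""
    return pd.DataFrame(
        {
            "source": summary.source_names,
            "median_pct": summary.median_pct,
            "ci_2.5_pct": summary.ci_low_pct,
            "ci_97.5_pct": summary.ci_high_pct,
            "rhat": [summary.rhat[n] for n in summary.source_names],
            "ess": [summary.ess[n] for n in summary.source_names],
        }
    )
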