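"""Breath-CO2 delta13C fuel mixing.

Breath CO2 carries the delta13C of the substrate currently being oxidised.
Feeding shorebirds burning dietary (biofilm) carbohydrate exhale relatively
13C-enriched CO2; fasting birds burning stored lipid exhale depleted CO2.
Given a cohort sampled across the feeding/fasting spectrum, the k most
positive and k most negative individuals define carbohydrate- and
lipid-oxidation endpoints, and every intermediate bird's carbohydrate fuel
fraction follows from a one-isotope, two-endpoint linear mixing model:

    f_carb = (d13C_breath - D - lip_mean) / (carb_mean - lip_mean),

with D the (near-zero) diet-to-breath discrimination.  Fractions outside
[0, 1] are clamped and flagged rather than discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mudflatmix.errors import DomainError, FormatError, ValidationError

CONTEXTS = frozenset({"morning_return", "daytime", "unknown"})


@dataclass(frozen=True)
class BreathSample:
    """One bird's breath-CO2 delta13C measurement with capture context."""

    sample_id: str
    species: str
    d13C_breath: float
    context: str = "unknown"
    capture_time: str | None = None

    def __post_init__(self) -> None:
        if not -40.0 <= self.d13C_breath <= 0.0:
            raise ValidationError(
                f"sample {self.sample_id}: d13C_breath={self.d13C_breath} outside [-40, 0]"
            )
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"sample {self.sample_id}: context {self.context!r} not in {sorted(CONTEXTS)}"
            )


@dataclass(frozen=True)
class BreathEndpoints:
    """Carbohydrate- and lipid-oxidation breath endpoints (means +/- sd)."""

    k: int
    carb_mean: float
    carb_sd: float
    lip_mean: float
    lip_sd: float
    carb_ids: tuple[str, ...] = ()
    lip_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.carb_mean <= self.lip_mean:
            raise ValidationError(
                f"carbohydrate endpoint ({self.carb_mean}) must exceed "
                f"lipid endpoint ({self.lip_mean})"
            )
        if set(self.carb_ids) & set(self.lip_ids):
            raise ValidationError("endpoint member sets overlap")


@dataclass(frozen=True)
class FuelMixResult:
    """Per-bird carbohydrate fuel fractions and their cohort summary."""

    per_bird: tuple[tuple[str, float, bool], ...]  # (sample_id, fraction, clamped)
    mean_fraction: float
    sd_fraction: float
    n_intermediate: int


def select_endpoints(samples: Sequence[BreathSample], k: int = 14) -> BreathEndpoints:
    """Select the k most-positive / k most-negative samples as endpoints.

    The endpoints are the mean +/- sd of each extreme group; the result is
    deterministic and invariant to input order (ties broken by ascending
    sample_id).  Requires ``2k`` strictly fewer samples than available so
    an intermediate pool remains.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if 2 * k >= len(samples):
        raise ValidationError(
            f"need more than 2k={2 * k} samples to leave an intermediate pool, "
            f"got {len(samples)}"
        )
    ranked = sorted(samples, key=lambda s: (s.d13C_breath, s.sample_id))
    lip_group, carb_group = ranked[:k], ranked[-k:]

    def _stats(group: Sequence[BreathSample]) -> tuple[float, float]:
        vals = np.array([s.d13C_breath for s in group])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    carb_mean, carb_sd = _stats(carb_group)
    lip_mean, lip_sd = _stats(lip_group)
    return BreathEndpoints(
        k=k,
        carb_mean=carb_mean,
        carb_sd=carb_sd,
        lip_mean=lip_mean,
        lip_sd=lip_sd,
        carb_ids=tuple(sorted(s.sample_id for s in carb_group)),
        lip_ids=tuple(sorted(s.sample_id for s in lip_group)),
    )


def fuel_fraction(
    d13C_breath: float,
    endpoints: BreathEndpoints,
    delta_diet_breath: float = 0.0,
) -> tuple[float, bool]:
    """Carbohydrate fraction of oxidised fuel for one breath observation.

    Linearly places the (discrimination-corrected) observation between the
    lipid (f=0) and carbohydrate (f=1) endpoints; values outside [0, 1]
    are clamped and flagged.  Returns ``(fraction, clamped)``.
    """
    span = endpoints.carb_mean - endpoints.lip_mean
    if span == 0:
        raise DomainError("endpoints coincide: fuel fraction undefined")
    f = (d13C_breath - delta_diet_breath - endpoints.lip_mean) / span
    clamped = f < 0.0 or f > 1.0
    return min(max(f, 0.0), 1.0), clamped


def summarize_fuel(
    samples: Sequence[BreathSample],
    endpoints: BreathEndpoints,
    delta_diet_breath: float = 0.0,
) -> FuelMixResult:
    """Cohort-level fuel mixing over the intermediate (non-endpoint) birds.

    Birds whose ids belong to either endpoint group are excluded, so the
    summary describes the remaining ``n - 2k`` intermediate individuals.
    """
    members = set(endpoints.carb_ids) | set(endpoints.lip_ids)
    intermediates = [s for s in samples if s.sample_id not in members]
    if not intermediates:
        raise ValidationError("no intermediate samples left after endpoint exclusion")
    per_bird = []
    for s in intermediates:
        f, clamped = fuel_fraction(s.d13C_breath, endpoints, delta_diet_breath)
        per_bird.append((s.sample_id, f, clamped))
    fracs = np.array([f for _, f, _ in per_bird])
    return FuelMixResult(
        per_bird=tuple(per_bird),
        mean_fraction=float(fracs.mean()),
        sd_fraction=float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0,
        n_intermediate=len(per_bird),
    )


def read_breath(path: str | Path) -> list[BreathSample]:
    """Read breath samples (columns ``sample_id,species,d13C_breath,context,capture_time``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["sample_id", "species", "d13C_breath", "context", "capture_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            d13c = float(rec["d13C_breath"])
        except ValueError:
            raise FormatError(
                f"{path}, row {line}: non-numeric d13C_breath={rec['d13C_breath']!r}"
            ) from None
        if math.isnan(d13c):
            raise FormatError(f"{path}, row {line}: missing d13C_breath")
        try:
            out.append(
                BreathSample(
                    sample_id=rec["sample_id"],
                    species=rec["species"],
                    d13C_breath=d13c,
                    context=rec["context"] or "unknown",
                    capture_time=rec["capture_time"] or None,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}, row {line}: {exc}") from exc
    return out


def write_breath(samples: Iterable[BreathSample], path: str | Path) -> None:
    """Write breath samples in the ``breath.csv`` dialect."""
    rows = [
        {
            "sample_id": s.sample_id,
            "species": s.species,
            "d13C_breath": s.d13C_breath,
            "context": s.context,
            "capture_time": s.capture_time or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fuel_result(result: FuelMixResult, path: str | Path) -> None:
    """Write per-bird fuel fractions as CSV."""
    rows = [
        {"sample_id": sid, "fraction_carbohydrate": f, "clamped": clamped}
        for sid, f, clamped in result.per_bird
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
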