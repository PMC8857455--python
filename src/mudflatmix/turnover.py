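"""Allometric scaling of tissue isotopic half-lives.

Isotopic incorporation rate scales with body mass roughly as mass^-0.25,
so a tissue half-life measured in a reference species can be transferred
to a target species of different mass:

    t_half(target) = t_half(ref) * (m_target / m_ref)^0.25.

Two half-lives of local feeding are conventionally taken as the residency
needed for a fast tissue (liver, plasma) to predominantly reflect the local
diet, which turns scaled half-lives into a stopover residency window.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from mudflatmix.errors import ValidationError

#: Mass exponent of turnover *rate*; half-life scales as mass^(-exponent).
DEFAULT_MASS_EXPONENT = -0.25


@dataclass(frozen=True)
class TurnoverReference:
    """A measured tissue half-life in a reference species of known mass."""

    species_label: str
    tissue: str
    half_life_days: float
    body_mass_g: float

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValidationError(f"{self.species_label}: half_life_days must be > 0")
        if self.body_mass_g <= 0:
            raise ValidationError(f"{self.species_label}: body_mass_g must be > 0")


@dataclass(frozen=True)
class TurnoverEstimate:
    """Scaled half-life bounds and the implied residency window (days)."""

    target_mass_g: float
    half_life_days: tuple[float, float]
    residency_window_days: tuple[float, float]


def scale_half_life(
    ref: TurnoverReference,
    target_mass_g: float,
    exponent: float = DEFAULT_MASS_EXPONENT,
) -> float:
    """Scale a reference half-life to a target body mass.

    ``exponent`` is the allometric exponent of the turnover *rate*
    (default -0.25); the half-life therefore scales as the reciprocal,
    ``(m_target / m_ref) ** (-exponent)``.
    """
    if target_mass_g <= 0:
        raise ValidationError(f"target_mass_g must be > 0, got {target_mass_g}")
    return ref.half_life_days * (target_mass_g / ref.body_mass_g) ** (-exponent)


def residency_window(
    half_life_low: float,
    half_life_high: float,
    n_half_lives: int = 2,
) -> tuple[float, float]:
    """Residency window spanned by ``n_half_lives`` of the half-life bounds."""
    if not 0 < half_life_low <= half_life_high:
        raise ValidationError(
            f"need 0 < low <= high, got ({half_life_low}, {half_life_high})"
        )
    if n_half_lives < 1:
        raise ValidationError(f"n_half_lives must be >= 1, got {n_half_lives}")
    return n_half_lives * half_life_low, n_half_lives * half_life_high


def estimate_turnover(
    references: Sequence[TurnoverReference],
    target_masses_g: Iterable[float],
    exponent: float = DEFAULT_MASS_EXPONENT,
    n_half_lives: int = 2,
) -> TurnoverEstimate:
    """Half-life and residency range over all reference x target-mass pairs.

    Every reference is applied to every target mass (e.g. both sexes) and
    the min/max span the plausible half-life range; the residency window is
    ``n_half_lives`` times those bounds.
    """
    masses = list(target_masses_g)
    if not references or not masses:
        raise ValidationError("need at least one reference and one target mass")
    values = [scale_half_life(r, m, exponent) for r in references for m in masses]
    lo, hi = min(values), max(values)
    return TurnoverEstimate(
        target_mass_g=masses[0] if len(masses) == 1 else float("nan"),
        half_life_days=(lo, hi),
        residency_window_days=residency_window(lo, hi, n_half_lives),
    )


def round_display(value: float, decimals: int = 1) -> float:
    """Half-up rounding for display (internal values keep full precision)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
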