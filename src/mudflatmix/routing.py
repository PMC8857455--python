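"""Macromolecular carbon-routing mass balance.

A consumer tissue built from a macromolecularly mixed diet (biofilm:
carbohydrate-rich mucilage plus algal lipid and protein) carries a delta13C
value that is the assimilation-weighted mean of the component substrates,
each shifted by its substrate-to-tissue discrimination factor:

    d13C_tissue = A (d13C_carb + D_c-t) + B (d13C_lip + D_l-t)
                + C (d13C_prot + D_p-t),     A + B + C = 1,

where A, B, C are the fractions of assimilated carbon contributed by
carbohydrate, lipid and protein.  Setting all discriminations to zero gives
the bulk-substrate mass balance, which can be inverted for the protein
fraction's delta13C when the carbohydrate and lipid values are known from
breath-CO2 and adipose assays:

    d13C_prot = [d13C_bulk - A d13C_carb - B d13C_lip] / C.

The sensitivity grid propagates an uncertain diet-to-breath discrimination
(breath = substrate + D, so substrate = measured breath endpoint - D)
through that back-calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from mudflatmix.errors import DomainError, ValidationError

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MacroComposition:
    """Fractions of assimilated carbon from carbohydrate (A), lipid (B)
    and protein (C); must lie in [0, 1] and sum to 1."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if abs(self.A + self.B + self.C - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"macromolecular fractions must sum to 1, got {self.A + self.B + self.C!r}"
            )


@dataclass(frozen=True)
class MacroIsotopes:
    """delta13C of the carbohydrate, lipid and protein fractions (per mil)."""

    d13C_carb: float
    d13C_lip: float
    d13C_prot: float

    def __post_init__(self) -> None:
        for name in ("d13C_carb", "d13C_lip", "d13C_prot"):
            v = getattr(self, name)
            if not -40.0 <= v <= 0.0:
                raise ValidationError(f"{name}={v} outside [-40, 0] per mil")


@dataclass(frozen=True)
class DiscriminationSet:
    """Substrate-to-tissue (and diet-to-breath) 13C discrimination factors."""

    d_carb_tissue: float = 0.0
    d_lip_tissue: float = 0.0
    d_prot_tissue: float = 0.0
    d_diet_breath: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_carb_tissue", "d_lip_tissue", "d_prot_tissue", "d_diet_breath"):
            v = getattr(self, name)
            if not -5.0 <= v <= 5.0:
                raise ValidationError(f"{name}={v} outside [-5, +5] per mil")


@dataclass(frozen=True)
class SensitivityRow:
    """Substrate endpoints implied by one diet-breath discrimination value."""

    delta_diet_breath: float
    d13C_carb: float
    d13C_lip: float
    d13C_prot: float


ZERO_DISCRIMINATION = DiscriminationSet()


def forward_tissue_c13(
    comp: MacroComposition,
    iso: MacroIsotopes,
    disc: DiscriminationSet = ZERO_DISCRIMINATION,
) -> float:
    """Predict tissue delta13C from macromolecular routing (forward model).

    Returns ``A(dc+Dc) + B(dl+Dl) + C(dp+Dp)``; linear in every argument
    and bounded by the min/max of the discrimination-shifted components.
    """
    return (
        comp.A * (iso.d13C_carb + disc.d_carb_tissue)
        + comp.B * (iso.d13C_lip + disc.d_lip_tissue)
        + comp.C * (iso.d13C_prot + disc.d_prot_tissue)
    )


def backcalc_protein_c13(
    d13C_bulk: float,
    comp: MacroComposition,
    d13C_carb: float,
    d13C_lip: float,
) -> float:
    """Back-calculate the protein fraction's delta13C from the bulk value.

    Inverts the zero-discrimination mass balance for the protein term:
    ``[bulk - A*carb - B*lip] / C``.  Exact inverse of
    :func:`forward_tissue_c13` at zero discrimination.

    Raises
    ------
    DomainError
        If the protein fraction C is zero (the inversion is undefined).
    """
    if comp.C == 0:
        raise DomainError("protein fraction C = 0: back-calculation undefined")
    return (d13C_bulk - comp.A * d13C_carb - comp.B * d13C_lip) / comp.C


def sensitivity_grid(
    base_carb_endpoint: float,
    base_lip_endpoint: float,
    bulk: float,
    comp: MacroComposition,
    deltas: Sequence[float],
) -> list[SensitivityRow]:
    """Propagate diet-breath discrimination through the back-calculation.

    Measured breath endpoints estimate substrate values only up to the
    diet-to-breath discrimination D (breath = substrate + D); for each D
    in ``deltas`` the implied substrate endpoints are ``base - D`` and the
    protein value is recomputed through the mass-balance inversion.  Rows
    preserve the input order of ``deltas``.
    """
    if not deltas:
        raise ValidationError("deltas must be non-empty")
    rows = []
    for d in deltas:
        carb = base_carb_endpoint - d
        lip = base_lip_endpoint - d
        rows.append(
            SensitivityRow(
                delta_diet_breath=d,
                d13C_carb=carb,
                d13C_lip=lip,
                d13C_prot=backcalc_protein_c13(bulk, comp, carb, lip),
            )
        )
    return rows


def write_sensitivity(rows: Iterable[SensitivityRow], path: str | Path) -> None:
    """Write a sensitivity table as CSV, full precision plus 1-decimal display."""
    recs = []
    for r in rows:
        recs.append(
            {
                "delta_diet_breath": r.delta_diet_breath,
                "d13C_carb": r.d13C_carb,
                "d13C_lip": r.d13C_lip,
                "d13C_prot": r.d13C_prot,
                "d13C_carb_1dp": round(r.d13C_carb, 1),
                "d13C_lip_1dp": round(r.d13C_lip, 1),
                "d13C_prot_1dp": round(r.d13C_prot, 1),
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)
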