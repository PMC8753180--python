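"""Solubility–diffusion (series-resistance) membrane permeability model.

For a solute crossing an inhomogeneous membrane, each depth contributes a
resistance ``1/(K(z) D(z))`` where ``K(z)`` is the local water→membrane
partition constant and ``D(z)`` the local diffusion coefficient.  For a
piecewise-constant (slab) profile the permeability coefficient is

    P_m = [ sum_i  w_i / (K_i * D_i) ]^-1        (w_i in cm)

The default H2O2 profile models the bilayer core as three slabs: two
0.7-nm octanol-like flanks (K = 6.6e-2) around a 1.6-nm hexadecane-like
centre (K = 8.2e-6), with the aqueous diffusion coefficient used throughout.
Headgroup and structured-water regions carry no slabs (no experimental
partition estimate exists for them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import constants
from .exceptions import GeometryError

NM_PER_CM = 1e7


@dataclass(frozen=True)
class Slab:
    """One homogeneous membrane layer.

    width_nm : thickness (nm); K : dimensionless local partition constant
    (membrane/water); D : local diffusion coefficient (cm^2 s^-1).
    """

    width_nm: float
    K: float
    D: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise GeometryError("slab width must be > 0")
        if self.K <= 0 or self.D <= 0:
            raise GeometryError("slab K and D must be > 0")

    @property
    def resistance(self) -> float:
        """Diffusional resistance of the slab, s cm^-1."""
        return (self.width_nm / NM_PER_CM) / (self.K * self.D)


@dataclass(frozen=True)
class SlabProfile:
    """Ordered sequence of slabs spanning the membrane."""

    slabs: tuple[Slab, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.slabs:
            raise GeometryError("profile must contain at least one slab")
        object.__setattr__(self, "slabs", tuple(self.slabs))

    @property
    def total_thickness_nm(self) -> float:
        return sum(s.width_nm for s in self.slabs)

    @classmethod
    def from_dicts(cls, specs: Iterable[dict]) -> "SlabProfile":
        return cls(tuple(Slab(s["width_nm"], s["K"], s["D"]) for s in specs))

    @classmethod
    def h2o2_default(
        cls,
        D: float = constants.D_H2O2_WATER,
        K_flank: float = constants.KD_OCTANOL,
        K_core: float = constants.KD_HEXADECANE,
    ) -> "SlabProfile":
        """The three-slab H2O2 profile (0.7 / 1.6 / 0.7 nm, octanol/hexadecane/octanol)."""
        w_flank, w_core, _ = constants.SLAB_WIDTHS_NM
        return cls(
            (
                Slab(w_flank, K_flank, D),
                Slab(w_core, K_core, D),
                Slab(w_flank, K_flank, D),
            )
        )


def permeability_from_profile(profile: SlabProfile) -> float:
    """Membrane permeability coefficient (cm s^-1) of a slab profile.

    Invariant under slab reordering (resistances add), and strictly
    increasing in any K_i or D_i.
    """
    return 1.0 / sum(s.resistance for s in profile.slabs)


def resistance_shares(profile: SlabProfile) -> pd.DataFrame:
    """Per-slab resistances and their fractional share of the total."""
    rows = []
    total = sum(s.resistance for s in profile.slabs)
    for i, s in enumerate(profile.slabs):
        rows.append(
            {
                "slab": i,
                "width_nm": s.width_nm,
                "K": s.K,
                "D_cm2_s": s.D,
                "resistance_s_cm": s.resistance,
                "share": s.resistance / total,
            }
        )
    return pd.DataFrame(rows)


def usl_permeability(D: float, thickness_um: float) -> float:
    """Permeability of an unstirred aqueous layer, cm s^-1.

    A stagnant water film of the given thickness (um) offers a purely
    diffusional resistance: P = D / thickness.
    """
    if D <= 0 or thickness_um <= 0:
        raise ValueError("D and thickness must be > 0")
    return D / (thickness_um * 1e-4)


def barrier_factor(
    P_m: float,
    D_water: float = constants.D_H2O2_WATER,
    thickness_nm: float = constants.MEMBRANE_THICKNESS_NM,
) -> float:
    """Fold by which the membrane slows diffusion relative to an equally thick water layer.

    Returns ``(D_water / thickness) / P_m`` with the thickness in nm.  The
    default thickness (3.0 nm) is the sum of the three slab widths, the only
    thickness the slab model defines.
    """
    if P_m <= 0 or D_water <= 0 or thickness_nm <= 0:
        raise ValueError("all inputs must be > 0")
    return (D_water / (thickness_nm / NM_PER_CM)) / P_m
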