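"""Double-partition estimation of partition constants and partition thermodynamics.

The partition constant of H2O2 between an organic solvent and water is too
small to measure by assaying the organic phase directly (aqueous peroxidase
assays do not work in octanol or hexadecane).  The double-partition protocol
sidesteps this: H2O2 is first equilibrated between water (w1) and the organic
solvent (os1); a water-free aliquot of the organic phase (os2) is then
re-equilibrated against fresh water (w2), and H2O2 is quantified in the two
*aqueous* phases only.  Closed mass balance over the second step gives the
partition constant

    K_D = C_w2 * V_w2 / ((C_w1 - C_w2) * V_os2)

where ``C_w1``/``C_w2`` are the equilibrium aqueous concentrations and
``V_w2``/``V_os2`` the second-step volumes.  K_D is a concentration ratio
(organic/water), hence dimensionless; any consistent volume unit cancels.

Thermodynamics follow from the temperature dependence of K_D:
``dG = -R T ln K_D`` and the van't Hoff line ``ln K_D = -dH/(R T) + dS/R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .constants import R_GAS
from .exceptions import InconsistentMeasurementError, InsufficientDataError


@dataclass(frozen=True)
class PartitionSystem:
    """Volumes and measured aqueous concentrations of a double-partition experiment.

    Parameters
    ----------
    V_os1, V_w1 : float
        Organic and water phase volumes in the first equilibration (mL).
    V_os2, V_w2 : float
        Organic volume carried over, and fresh water volume, in the second
        equilibration (mL). ``V_os2 <= V_os1``.
    C_w1, C_w2 : float
        Measured equilibrium H2O2 concentrations in water phases 1 and 2 (M).
    T : float
        Absolute temperature (K).
    """

    V_os1: float
    V_w1: float
    V_os2: float
    V_w2: float
    C_w1: float
    C_w2: float
    T: float = 298.15

    def __post_init__(self) -> None:
        for name in ("V_os1", "V_w1", "V_os2", "V_w2"):
            if getattr(self, name) <= 0:
                raise InconsistentMeasurementError(f"volume {name} must be > 0")
        if self.V_os2 > self.V_os1 + 1e-12:
            raise InconsistentMeasurementError(
                "V_os2 cannot exceed V_os1 (the carried aliquot comes from os1)"
            )
        if self.C_w2 < 0:
            raise InconsistentMeasurementError("C_w2 must be >= 0")
        if self.C_w1 <= self.C_w2:
            raise InconsistentMeasurementError(
                "C_w1 must exceed C_w2: equal or inverted concentrations are "
                "inconsistent with a finite partition constant"
            )
        if self.T <= 0:
            raise InconsistentMeasurementError("temperature must be > 0 K")


@dataclass(frozen=True)
class ThermoResult:
    """Partition constant with its derived thermodynamic state functions.

    ``dG`` must equal ``-R T_ref ln K_D`` and, when the enthalpy/entropy pair is
    set, ``dG`` must equal ``dH - T_ref dS / 1000`` (both in kJ mol^-1) within
    ``tol`` — these consistency checks run at construction.
    """

    K_D: float
    dG: float
    T_ref: float = 298.15
    dH: float | None = None
    dS: float | None = None
    tol: float = 0.1  # kJ mol^-1, covers report-level rounding

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be > 0")
        expected = delta_g(self.K_D, self.T_ref)
        if abs(expected - self.dG) > self.tol:
            raise ValueError(
                f"dG={self.dG} kJ/mol inconsistent with -RT ln K_D = {expected:.3f}"
            )
        if self.dH is not None and self.dS is not None:
            gibbs_helmholtz = self.dH - self.T_ref * self.dS / 1000.0
            if abs(gibbs_helmholtz - self.dG) > self.tol:
                raise ValueError(
                    f"dG={self.dG} inconsistent with dH - T dS = {gibbs_helmholtz:.3f}"
                )

    def to_dict(self) -> dict:
        return {
            "K_D": self.K_D,
            "dG_kJ_mol": self.dG,
            "dH_kJ_mol": self.dH,
            "dS_J_mol_K": self.dS,
            "T_ref_K": self.T_ref,
        }


def kd_from_double_partition(exp: PartitionSystem) -> float:
    """Partition constant (organic/water) from a double-partition measurement.

    Applies the closed mass balance over the second equilibration:
    ``K_D = C_w2 V_w2 / ((C_w1 - C_w2) V_os2)``.

    Returns 0 when no H2O2 reached the second water phase (C_w2 = 0).
    """
    return exp.C_w2 * exp.V_w2 / ((exp.C_w1 - exp.C_w2) * exp.V_os2)


def delta_g(K_D: float, T: float) -> float:
    """Gibbs energy of transfer from water to the organic phase, kJ mol^-1.

    ``dG = -R T ln(K_D) / 1000``.  Positive when the solute prefers water.
    """
    if K_D <= 0:
        raise ValueError("K_D must be > 0 for a Gibbs energy")
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return -R_GAS * T * math.log(K_D) / 1000.0


@dataclass(frozen=True)
class VantHoffResults:
    """Enthalpy/entropy of partition from the van't Hoff line.

    ``dH`` in kJ mol^-1, ``dS`` in J mol^-1 K^-1, with OLS standard errors
    (NaN for an exact two-point fit).
    """

    dH: float
    dS: float
    dH_stderr: float
    dS_stderr: float
    n_points: int

    def delta_g(self, T: float) -> float:
        """Gibbs energy implied by (dH, dS) at temperature ``T``, kJ mol^-1."""
        return self.dH - T * self.dS / 1000.0

    def summary(self) -> str:
        lines = [
            "van't Hoff analysis of partition constants",
            f"  points: {self.n_points}",
            f"  dH = {self.dH:.2f} kJ/mol (se {self.dH_stderr:.2g})",
            f"  dS = {self.dS:.2f} J/(mol K) (se {self.dS_stderr:.2g})",
        ]
        return "\n".join(lines)


class VantHoffModel:
    """Ordinary least squares of ln(K_D) against 1/T.

    Slope = -dH/R, intercept = dS/R.  With exactly two points the line is
    exact and reproduces the two-point arithmetic used with measurements at
    25 and 37 C.
    """

    def __init__(self, points: Iterable[tuple[float, float]]):
        pts = [(float(T), float(K)) for T, K in points]
        if len(pts) < 2:
            raise InsufficientDataError("van't Hoff fit needs >= 2 points")
        temps = [T for T, _ in pts]
        if len(set(temps)) < 2:
            raise InsufficientDataError("van't Hoff fit needs distinct temperatures")
        if any(K <= 0 for _, K in pts):
            raise ValueError("all K_D must be > 0")
        if any(T <= 0 for T in temps):
            raise ValueError("all temperatures must be > 0 K")
        self.points = pts

    def fit(self) -> VantHoffResults:
        x = np.array([1.0 / T for T, _ in self.points])
        y = np.array([math.log(K) for _, K in self.points])
        res = stats.linregress(x, y)
        dH = -res.slope * R_GAS / 1000.0
        dS = res.intercept * R_GAS
        return VantHoffResults(
            dH=dH,
            dS=dS,
            dH_stderr=res.stderr * R_GAS / 1000.0,
            dS_stderr=res.intercept_stderr * R_GAS,
            n_points=len(self.points),
        )


def vant_hoff(points: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Convenience wrapper: (dH kJ mol^-1, dS J mol^-1 K^-1) from (T, K_D) pairs."""
    res = VantHoffModel(points).fit()
    return res.dH, res.dS


def kd_from_thermo(dH: float, dS: float, T: float) -> float:
    """Forward van't Hoff evaluation: K_D(T) from dH (kJ mol^-1) and dS (J mol^-1 K^-1)."""
    return math.exp(-dH * 1000.0 / (R_GAS * T) + dS / R_GAS)


def thermo_report_table(rows: Sequence[tuple[str, ThermoResult]]) -> str:
    """Plain-text table of partition thermodynamics, one solvent per row.

    Thermodynamic outputs are rounded to one decimal (kJ mol^-1 / J mol^-1 K^-1)
    at this report layer only; the underlying results keep full precision.
    """
    header = f"{'Solvent':<14}{'K_D':>12}{'dG (kJ/mol)':>14}{'dH (kJ/mol)':>14}{'dS (J/mol/K)':>14}"
    lines = [header, "-" * len(header)]
    for label, res in rows:
        dh = f"{res.dH:.1f}" if res.dH is not None else "-"
        ds = f"{res.dS:.1f}" if res.dS is not None else "-"
        lines.append(f"{label:<14}{res.K_D:>12.3g}{res.dG:>14.1f}{dh:>14}{ds:>14}")
    return "\n".join(lines)
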