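"""Seeded generators for every input the analysis pipeline consumes.

Each generator solves the forward problem exactly (mass balance, ODE
integration, or closed-form kinetics), then corrupts the observable with
multiplicative Gaussian noise clipped at zero, and returns the result
together with a machine-readable truth sidecar.  Identical arguments and
seed produce byte-identical outputs.

Designs mirror the experimental layouts of the study this package models:

- ``gen_partition`` — the double-partition protocol (5 mM load for the
  octanol-like case, 2 M for the hexadecane-like case);
- ``gen_timecourse_series`` — latency dose series: liposome volumes
  5–25 uL, or RBC suspensions at 0.9–3.5 uM HbO2 (intact) and a tenfold
  dilution (lysed), read as absorbance at 240 nm;
- ``gen_arrhenius_series`` — permeability coefficients over a temperature
  grid;
- ``gen_stopped_flow`` — single- (osmotic water efflux, 2 s at 1 kHz) and
  double-exponential (glycerol influx, 40 s at 25 Hz) light-scattering
  traces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .kinetics import (
    KineticScenario,
    extracellular_rate_constant,
    simulate,
)
from .latency import Geometry, SignalKind, TimeCourse
from .partition import PartitionSystem

_CSV_FLOAT = "%.10g"


def _write_truth(truth: dict, path: Path) -> None:
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# double partition
# ---------------------------------------------------------------------------

def forward_double_partition(
    K_D: float, V_os1: float, V_w1: float, V_os2: float, V_w2: float, C0: float
) -> tuple[float, float]:
    """Exact equilibrium aqueous concentrations of the two sequential partitions.

    Each step is a closed mass balance: in step 1 an initial amount
    ``C0 * V_w1`` distributes between water and organic phases with ratio
    ``K_D``; a volume ``V_os2`` of the organic phase is then equilibrated
    against fresh water ``V_w2``.
    """
    if min(V_os1, V_w1, V_os2, V_w2) <= 0 or V_os2 > V_os1:
        raise ValueError("infeasible volumes")
    if K_D < 0 or C0 <= 0:
        raise ValueError("K_D must be >= 0 and C0 > 0")
    C_w1 = C0 * V_w1 / (V_w1 + K_D * V_os1)
    n2 = K_D * C_w1 * V_os2
    C_w2 = n2 / (V_w2 + K_D * V_os2)
    return C_w1, C_w2


@dataclass(frozen=True)
class PartitionSample:
    """A simulated double-partition measurement with its ground truth."""

    system: PartitionSystem
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        s = self.system
        df = pd.DataFrame(
            [
                {
                    "V_os1_mL": s.V_os1, "V_w1_mL": s.V_w1,
                    "V_os2_mL": s.V_os2, "V_w2_mL": s.V_w2,
                    "C_w1_M": s.C_w1, "C_w2_M": s.C_w2, "T_K": s.T,
                }
            ]
        )
        df.to_csv(out / "partition.csv", index=False, float_format=_CSV_FLOAT)
        _write_truth(self.truth, out / "partition.truth.json")


def gen_partition(
    K_D: float = constants.KD_OCTANOL,
    V_os1: float = 5.0,
    V_w1: float = 5.0,
    V_os2: float = 2.0,
    V_w2: float = 5.0,
    C0: float = 5e-3,
    T: float = 298.15,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> PartitionSample:
    """Simulate one double-partition measurement.

    Noise is multiplicative Gaussian (relative sd ``noise_sd``) on the two
    measured aqueous concentrations, clipped at zero.  Default volumes and
    the 5 mM load follow the octanol protocol; pass ``C0=2.0`` for the
    hexadecane protocol's 2 M load.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    C_w1, C_w2 = forward_double_partition(K_D, V_os1, V_w1, V_os2, V_w2, C0)
    rng = np.random.default_rng(seed)
    noisy = np.clip(
        np.array([C_w1, C_w2]) * (1.0 + noise_sd * rng.standard_normal(2)), 0.0, None
    )
    system = PartitionSystem(
        V_os1=V_os1, V_w1=V_w1, V_os2=V_os2, V_w2=V_w2,
        C_w1=float(noisy[0]), C_w2=float(noisy[1]), T=T,
    )
    truth = {
        "design": "partition", "K_D": K_D, "C0_M": C0,
        "C_w1_clean": C_w1, "C_w2_clean": C_w2,
        "noise_sd": noise_sd, "seed": seed,
    }
    return PartitionSample(system=system, truth=truth)


# ---------------------------------------------------------------------------
# latency time-course series
# ---------------------------------------------------------------------------

#: default liposome series: volumes of stock added (uL), per the dose design
LIPOSOME_AMOUNTS_UL = (5.0, 10.0, 15.0, 20.0, 25.0)
#: default vesicle volume fraction of the liposome stock
LIPOSOME_STOCK_VOLUME_FRACTION = 0.04
#: default cuvette reaction volume, mL
REACTION_VOLUME_ML = 1.0
#: default intact RBC series: suspension HbO2 concentrations (M), 0.9-3.5 uM
RBC_AMOUNTS_M = (0.9e-6, 1.5e-6, 2.2e-6, 2.9e-6, 3.5e-6)


@dataclass(frozen=True)
class LatencySeriesSample:
    """Synthetic latency experiment: intact and disrupted absorbance series."""

    intact: tuple[TimeCourse, ...]
    disrupted: tuple[TimeCourse, ...]
    geometry: Geometry
    truth: dict

    def manifest(self) -> pd.DataFrame:
        rows = []
        for arm, traces in (("intact", self.intact), ("disrupted", self.disrupted)):
            for i, tc in enumerate(traces):
                rows.append(
                    {
                        "trace_file": f"{arm}_{i:02d}.csv",
                        "arm": arm,
                        "amount": tc.amount,
                        "amount_units": self.truth["amount_units"],
                        "temperature_C": tc.temperature - constants.ZERO_CELSIUS,
                        "signal_kind": tc.signal_kind.value,
                        "pathlength_cm": tc.pathlength,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for arm, traces in (("intact", self.intact), ("disrupted", self.disrupted)):
            for i, tc in enumerate(traces):
                pd.DataFrame({"t_s": tc.t, "signal": tc.y}).to_csv(
                    out / f"{arm}_{i:02d}.csv", index=False, float_format=_CSV_FLOAT
                )
        self.manifest().to_csv(out / "manifest.csv", index=False, float_format=_CSV_FLOAT)
        _write_truth(self.truth, out / "series.truth.json")


def _sample_grid(k_obs: float, max_time: float = 60.0,
                 consumed_fraction: float = 0.15, n_points: int = 61) -> np.ndarray:
    """Observation grid: 61 points over min(60 s, time to the target consumption).

    Slow traces get the standard 1 Hz / 60 s cuvette read; fast traces are
    shortened so the initial-rate window keeps enough points.
    """
    if k_obs <= 0:
        return np.linspace(0.0, max_time, n_points)
    t_frac = -math.log(1.0 - consumed_fraction) / k_obs
    return np.linspace(0.0, min(max_time, t_frac), n_points)


def gen_timecourse_series(
    design: str = "liposome",
    P_m: float = 3.7e-5,
    k_catalase: float = 80.0,
    radius_nm: float = 100.0,
    amounts: Sequence[float] | None = None,
    disrupted_amounts: Sequence[float] | None = None,
    C0: float = 10e-3,
    temperature: float = 298.15,
    noise_sd: float = 0.01,
    seed: int = 0,
    stock_volume_fraction: float = LIPOSOME_STOCK_VOLUME_FRACTION,
    reaction_volume_ml: float = REACTION_VOLUME_ML,
    hbo2_cell: float = constants.HBO2_CELL_M,
) -> LatencySeriesSample:
    """Simulate a full latency dose series read as 240-nm absorbance.

    design = "liposome": ``amounts`` are stock volumes (uL) added to the
    cuvette; the encapsulated volume fraction is
    ``amount * stock_volume_fraction / (1000 * reaction_volume_ml)`` and the
    vesicles are spheres of ``radius_nm``.  The disrupted arm uses the same
    amounts with the enzyme redistributed over the whole volume.

    design = "rbc": ``amounts`` are suspension HbO2 concentrations (M); cell
    volume fraction is ``amount / hbo2_cell`` and the geometry is the RBC.
    The lysed arm defaults to a tenfold dilution of the intact amounts.

    The intact arm runs the two-compartment permeation/consumption ODE; the
    disrupted arm is exact first-order decay.  Both are converted to
    absorbance (Beer–Lambert, 240 nm, 1 cm path) before noise is applied.
    """
    if design not in ("liposome", "rbc"):
        raise ValueError(f"unknown design {design!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    if design == "liposome":
        amounts = tuple(amounts) if amounts is not None else LIPOSOME_AMOUNTS_UL
        disrupted_amounts = tuple(disrupted_amounts) if disrupted_amounts is not None else amounts
        geometry = Geometry.sphere(radius_nm)
        amount_units = "uL"

        def fraction(amount: float) -> float:
            return amount * stock_volume_fraction / (1000.0 * reaction_volume_ml)

        A_cell = 4.0 * math.pi * (radius_nm * 1e-7) ** 2
        V_cell = (4.0 / 3.0) * math.pi * (radius_nm * 1e-7) ** 3
    else:
        amounts = tuple(amounts) if amounts is not None else RBC_AMOUNTS_M
        disrupted_amounts = (
            tuple(disrupted_amounts)
            if disrupted_amounts is not None
            else tuple(a / 10.0 for a in amounts)
        )
        geometry = Geometry.rbc()
        amount_units = "M_HbO2"

        def fraction(amount: float) -> float:
            return amount / hbo2_cell

        A_cell = constants.RBC_AREA_CM2
        V_cell = constants.RBC_VOLUME_CM3

    eps = constants.EPSILON_H2O2_240NM

    def absorbance_trace(t: np.ndarray, conc: np.ndarray, amount: float) -> TimeCourse:
        A = conc * eps  # 1 cm path
        noisy = np.clip(A * (1.0 + noise_sd * rng.standard_normal(len(A))), 0.0, None)
        return TimeCourse(
            t=t, y=noisy, signal_kind=SignalKind.absorbance240,
            amount=amount, temperature=temperature, pathlength=1.0,
        )

    intact = []
    for amount in amounts:
        sc = KineticScenario(
            P_m=P_m, hematocrit=fraction(amount), C0_out=C0,
            A_cell=A_cell, V_cell=V_cell, k_cat=k_catalase, T=temperature,
        )
        k_est = extracellular_rate_constant(sc)
        t = _sample_grid(k_est)
        res = simulate(sc, t[-1], n_points=len(t))
        intact.append(absorbance_trace(res.t, res.C_out, amount))

    disrupted = []
    for amount in disrupted_amounts:
        k_obs = k_catalase * fraction(amount)
        t = _sample_grid(k_obs)
        conc = C0 * np.exp(-k_obs * t)
        disrupted.append(absorbance_trace(t, conc, amount))

    truth = {
        "design": design,
        "P_m": P_m,
        "k_catalase": k_catalase,
        "radius_nm": radius_nm if design == "liposome" else None,
        "area_to_volume": geometry.area_to_volume(),
        "amounts": list(amounts),
        "disrupted_amounts": list(disrupted_amounts),
        "amount_units": amount_units,
        "C0_M": C0,
        "temperature_K": temperature,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return LatencySeriesSample(
        intact=tuple(intact), disrupted=tuple(disrupted), geometry=geometry, truth=truth
    )


# ---------------------------------------------------------------------------
# Arrhenius temperature series
# ---------------------------------------------------------------------------

#: default temperature grid, K (20-40 C in 5 C steps)
ARRHENIUS_TEMPERATURES_K = tuple(constants.celsius_to_kelvin(c) for c in (20, 25, 30, 35, 40))


@dataclass(frozen=True)
class ArrheniusSample:
    data: pd.DataFrame  # columns T_K, P_m
    truth: dict

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.data["T_K"], self.data["P_m"]))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(out / "arrhenius.csv", index=False, float_format=_CSV_FLOAT)
        _write_truth(self.truth, out / "arrhenius.truth.json")


def gen_arrhenius_series(
    E_a: float = 57.0,
    P_ref: float = 1.3e-3,
    T_ref: float = 298.15,
    temperatures: Sequence[float] = ARRHENIUS_TEMPERATURES_K,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ArrheniusSample:
    """Permeability coefficients over a temperature grid from the Arrhenius law.

    The truth is parameterised by the activation energy ``E_a`` (kJ mol^-1)
    and the permeability ``P_ref`` at ``T_ref``; noise is multiplicative
    Gaussian on P_m.
    """
    temperatures = tuple(float(T) for T in temperatures)
    lnA = math.log(P_ref) + E_a * 1000.0 / (constants.R_GAS * T_ref)
    rng = np.random.default_rng(seed)
    clean = np.array(
        [math.exp(lnA - E_a * 1000.0 / (constants.R_GAS * T)) for T in temperatures]
    )
    noisy = np.clip(clean * (1.0 + noise_sd * rng.standard_normal(len(clean))), 0.0, None)
    data = pd.DataFrame({"T_K": temperatures, "P_m": noisy})
    truth = {
        "design": "arrhenius", "E_a_kJ_mol": E_a, "lnA": lnA,
        "P_ref": P_ref, "T_ref_K": T_ref, "noise_sd": noise_sd, "seed": seed,
    }
    return ArrheniusSample(data=data, truth=truth)


# ---------------------------------------------------------------------------
# stopped-flow traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoppedFlowSample:
    trace: TimeCourse
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_s": self.trace.t, "signal": self.trace.y}).to_csv(
            out / "stopped_flow.csv", index=False, float_format=_CSV_FLOAT
        )
        _write_truth(self.truth, out / "stopped_flow.truth.json")


def gen_stopped_flow(
    model: str = "single_exp",
    k_water: float = 5.0,
    k_rise: float = 8.0,
    k_glycerol: float = 0.2,
    amplitude: float = 0.5,
    baseline: float = 1.0,
    duration: float | None = None,
    rate_hz: float | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> StoppedFlowSample:
    """Light-scattering stopped-flow trace with known rate constants.

    single_exp: ``baseline + amplitude * exp(-k_water t)``, 2 s at 1 kHz
    (osmotic shrinkage).  double_exp: ``baseline + amplitude *
    (exp(-k_glycerol t) - exp(-k_rise t))``, 40 s at 25 Hz (shrink-then-
    reswell on glycerol influx).
    """
    if model == "single_exp":
        duration = 2.0 if duration is None else duration
        rate_hz = 1000.0 if rate_hz is None else rate_hz
        t = np.arange(0.0, duration, 1.0 / rate_hz)
        clean = baseline + amplitude * np.exp(-k_water * t)
        truth = {"design": "stopped_flow", "model": model, "k_water": k_water}
    elif model == "double_exp":
        duration = 40.0 if duration is None else duration
        rate_hz = 25.0 if rate_hz is None else rate_hz
        t = np.arange(0.0, duration, 1.0 / rate_hz)
        clean = baseline + amplitude * (np.exp(-k_glycerol * t) - np.exp(-k_rise * t))
        truth = {"design": "stopped_flow", "model": model,
                 "k_rise": k_rise, "k_glycerol": k_glycerol}
    else:
        raise ValueError(f"unknown stopped-flow model {model!r}")
    truth.update({"amplitude": amplitude, "baseline": baseline,
                  "noise_sd": noise_sd, "seed": seed})
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean * (1.0 + noise_sd * rng.standard_normal(len(clean))), 0.0, None)
    flat = bool(np.ptp(clean) < 1e-12)
    truth["flat"] = flat
    trace = TimeCourse(t=t, y=noisy, signal_kind=SignalKind.scattering)
    return StoppedFlowSample(trace=trace, truth=truth)
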