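"""Physical constants and frozen experimental parameters.

Every quantity carries its unit in the name or the trailing comment.
``CONSTANTS_VERSION`` is echoed into every structured result file so that a
record can always be traced back to the constants table it was computed with.
"""

CONSTANTS_VERSION = "1.0"

#: universal gas constant, J mol^-1 K^-1
R_GAS = 8.314

ZERO_CELSIUS = 273.15  # K

# ---------------------------------------------------------------------------
# spectrophotometry
# ---------------------------------------------------------------------------
#: molar extinction coefficient of H2O2 at 240 nm, M^-1 cm^-1
EPSILON_H2O2_240NM = 39.4
#: molar extinction coefficient of H2O2 at 270 nm, M^-1 cm^-1
EPSILON_H2O2_270NM = 7.4
#: molar extinction coefficient of oxyhemoglobin at 577 nm, M^-1 cm^-1 (15 mM^-1 cm^-1)
EPSILON_HBO2_577NM = 15_000.0

# ---------------------------------------------------------------------------
# diffusion and partition
# ---------------------------------------------------------------------------
#: aqueous diffusion coefficient of H2O2 used in the slab model, cm^2 s^-1
D_H2O2_WATER = 1.4e-5
#: aqueous diffusion coefficient of H2O2 at 25 C used for the unstirred-layer
#: reference permeability, cm^2 s^-1
D_H2O2_WATER_25C = 1.43e-5

#: partition constant of H2O2 between n-octanol and water at 25 C (organic/water)
KD_OCTANOL = 6.6e-2
#: partition constant of H2O2 between hexadecane and water at 25 C (organic/water)
KD_HEXADECANE = 8.2e-6

#: three-slab decomposition of the bilayer core: octanol-like flank, hexadecane-like
#: centre, octanol-like flank (nm)
SLAB_WIDTHS_NM = (0.7, 1.6, 0.7)
#: total thickness of the modelled bilayer core, nm (sum of the slab widths; also
#: the thickness convention used for the water-layer barrier comparison)
MEMBRANE_THICKNESS_NM = 3.0

# ---------------------------------------------------------------------------
# red blood cell
# ---------------------------------------------------------------------------
#: RBC membrane surface area, cm^2
RBC_AREA_CM2 = 1.4e-6
#: RBC volume, cm^3
RBC_VOLUME_CM3 = 9e-11
#: intracellular oxyhemoglobin reference concentration, M. Cell density in a
#: suspension is expressed through its total HbO2 concentration; dividing by
#: this value gives the cell volume fraction.
HBO2_CELL_M = 20e-3
#: Prx2 + H2O2 rate constant, M^-1 s^-1
K_PRX2 = 1e8
#: cytosolic Prx2 pool, M (400 uM)
PRX2_TOTAL_M = 400e-6
#: physiological hematocrit (volume fraction)
HEMATOCRIT_PHYSIOLOGICAL = 0.45

#: Intracellular catalase pseudo-first-order constant, s^-1.  Frozen by
#: inverting the latency relation P_m = k R / [(A/V)(1-R)] at the measured
#: P_m = 1.6e-3 cm s^-1 and R = 1/4.3 with the RBC geometry above:
#: k = P_m (A/V) (1-R)/R = 82.1 s^-1.
K_CATALASE_RBC = 82.1

#: measured RBC membrane permeability coefficients to H2O2, cm s^-1
PM_RBC_37C = 1.6e-3
PM_RBC_25C = 1.0e-3


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature in degrees Celsius to kelvin."""
    return t_celsius + ZERO_CELSIUS


def as_kelvin(value: float, unit: str = "K") -> float:
    """Normalise a temperature given in kelvin (``"K"``) or Celsius (``"C"``)."""
    if unit == "K":
        t = float(value)
    elif unit in ("C", "degC", "celsius"):
        t = celsius_to_kelvin(float(value))
    else:
        raise ValueError(f"unknown temperature unit {unit!r}")
    if t <= 0:
        raise ValueError(f"non-physical absolute temperature {t} K")
    return t
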