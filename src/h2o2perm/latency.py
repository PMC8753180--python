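"""Enzyme-latency estimation of membrane permeability coefficients.

An enzyme enclosed by a semi-permeable membrane appears less active than the
same enzyme free in solution because its substrate must first cross the
membrane.  At steady state the ratio R of encapsulated to free activity equals
the inverse of the transmembrane substrate gradient, and the permeability
coefficient follows from

    P_m = k_catalase * R / [ (A/V) * (1 - R) ]

where ``k_catalase`` is the intravesicular pseudo-first-order rate constant of
the enzyme and ``A/V`` the surface-to-volume ratio of the vesicle or cell
(``A/V ~ 3/r`` for a sphere of radius r).

The experimental pipeline implemented here is

1. primary time courses (absorbance vs time) -> Beer–Lambert conversion
   (:func:`to_concentration`) -> initial rates by early-window linear
   regression (:func:`initial_rate`);
2. secondary plot of initial rate vs enzyme amount -> OLS slope = apparent
   pseudo-first-order constant per unit amount (:func:`secondary_slope`);
3. slope ratio of intact vs disrupted preparations -> latency ratio R
   (:func:`latency_ratio`) -> P_m (:func:`pm_from_latency`).

:class:`LatencyExperiment` packages steps 1–3 as a model object whose
``fit()`` returns a :class:`LatencyResults` with estimates, propagated
standard errors and a ``summary()`` table.  Temperature series are handled by
:class:`ArrheniusModel` and stopped-flow transport assays (osmotic water
efflux, glycerol influx) by :func:`fit_transport_trace`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from . import constants
from .exceptions import (
    FitError,
    GeometryError,
    InsufficientDataError,
    NoLatencyError,
    NoLatencyWarning,
)


class SignalKind(str, Enum):
    absorbance240 = "absorbance240"
    absorbance270 = "absorbance270"
    absorbance577 = "absorbance577"
    scattering = "scattering"
    concentration = "concentration"


#: default molar extinction coefficient per absorbance signal kind, M^-1 cm^-1
EXTINCTION = {
    SignalKind.absorbance240: constants.EPSILON_H2O2_240NM,
    SignalKind.absorbance270: constants.EPSILON_H2O2_270NM,
    SignalKind.absorbance577: constants.EPSILON_HBO2_577NM,
}


@dataclass(frozen=True)
class TimeCourse:
    """A primary kinetic trace.

    ``amount`` is the series variable of the experiment the trace belongs to
    (liposome volume in uL, or HbO2 concentration in M); NaN when the trace is
    not part of a series.
    """

    t: np.ndarray
    y: np.ndarray
    signal_kind: SignalKind = SignalKind.concentration
    amount: float = math.nan
    temperature: float = math.nan  # K
    pathlength: float = 1.0  # cm
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "signal_kind", SignalKind(self.signal_kind))
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(t) < 4:
            raise InsufficientDataError("a time course needs >= 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not math.isnan(self.amount) and self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")

    def __len__(self) -> int:
        return len(self.t)


def to_concentration(tc: TimeCourse, epsilon: float | None = None) -> TimeCourse:
    """Beer–Lambert conversion of an absorbance trace to concentration (M).

    ``epsilon`` overrides the per-wavelength default (M^-1 cm^-1).  Scattering
    traces carry no extinction coefficient and are rejected.
    """
    if tc.signal_kind == SignalKind.concentration:
        return tc
    if tc.signal_kind == SignalKind.scattering:
        raise ValueError("scattering signals have no Beer-Lambert conversion")
    eps = EXTINCTION[tc.signal_kind] if epsilon is None else epsilon
    return replace(tc, y=tc.y / (eps * tc.pathlength), signal_kind=SignalKind.concentration)


@dataclass(frozen=True)
class InitialRate:
    """Initial rate from an early-window linear regression.

    ``rate`` is the negative of the fitted slope (positive for a decaying
    substrate), in signal units per second (M s^-1 for concentration traces).
    """

    rate: float
    stderr: float
    intercept: float
    n_points: int
    t_end: float


def initial_rate(
    tc: TimeCourse,
    max_fraction: float = 0.10,
    max_time: float = 60.0,
    min_points: int = 4,
) -> InitialRate:
    """Initial decomposition rate of a decaying trace.

    The window is the earliest of {first ``max_fraction`` of the initial
    signal consumed, first ``max_time`` seconds}, extended forward if needed
    so that it contains at least ``min_points`` points.
    """
    t = tc.t - tc.t[0]
    y = tc.y
    n = len(t)
    idx = n
    within_time = np.nonzero(t <= max_time)[0]
    if len(within_time):
        idx = within_time[-1] + 1
    y0 = y[0]
    if y0 > 0:
        consumed = (y0 - y) / y0
        crossed = np.nonzero(consumed > max_fraction)[0]
        if len(crossed):
            idx = min(idx, int(crossed[0]))
    idx = max(idx, min_points)
    if idx > n:
        raise InsufficientDataError(
            f"initial-rate window selects {n} points, fewer than {min_points}"
        )
    res = stats.linregress(t[:idx], y[:idx])
    return InitialRate(
        rate=-res.slope,
        stderr=res.stderr,
        intercept=res.intercept,
        n_points=idx,
        t_end=float(t[idx - 1]),
    )


@dataclass(frozen=True)
class RateSeries:
    """Secondary plot: initial rate as a function of enzyme amount.

    ``slope`` is the apparent pseudo-first-order constant per unit amount,
    from OLS with a free intercept.
    """

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    slope_stderr: float

    @property
    def n_points(self) -> int:
        return len(self.points)


def secondary_slope(points: Iterable[tuple[float, float]]) -> RateSeries:
    """OLS slope of the (amount, initial rate) secondary plot.

    Uses a free intercept; the slope is the estimand.  All-identical amounts
    make the fit singular and are rejected.
    """
    pts = tuple((float(a), float(r)) for a, r in points)
    if len(pts) < 2:
        raise InsufficientDataError("secondary plot needs >= 2 points")
    amounts = np.array([a for a, _ in pts])
    rates = np.array([r for _, r in pts])
    if np.allclose(amounts, amounts[0]):
        raise InsufficientDataError("all amounts identical: singular secondary fit")
    res = stats.linregress(amounts, rates)
    return RateSeries(points=pts, slope=res.slope, intercept=res.intercept,
                      slope_stderr=res.stderr if len(pts) > 2 else math.nan)


def latency_ratio(k_enc: float, k_free: float) -> float:
    """Latency ratio R = k_encapsulated / k_free.

    R in (0, 1) encodes the transmembrane substrate gradient (gradient = 1/R).
    R >= 1 means intact and disrupted preparations show the same activity —
    no permeability barrier; this is flagged with :class:`NoLatencyWarning`
    rather than raised, so batch pipelines can record the trace and move on.
    """
    if k_enc <= 0 or k_free <= 0:
        raise NoLatencyError("rate constants must be > 0")
    R = k_enc / k_free
    if R >= 1:
        warnings.warn(
            f"latency ratio R = {R:.3g} >= 1: no permeability barrier detected",
            NoLatencyWarning,
            stacklevel=2,
        )
    return R


class GeometryKind(str, Enum):
    sphere = "sphere"
    explicit = "explicit"


@dataclass(frozen=True)
class Geometry:
    """Vesicle or cell geometry providing the surface-to-volume ratio."""

    kind: GeometryKind
    r_nm: float = math.nan
    A_cm2: float = math.nan
    V_cm3: float = math.nan

    @classmethod
    def sphere(cls, r_nm: float) -> "Geometry":
        if r_nm <= 0:
            raise GeometryError("sphere radius must be > 0")
        return cls(kind=GeometryKind.sphere, r_nm=r_nm)

    @classmethod
    def explicit(cls, A_cm2: float, V_cm3: float) -> "Geometry":
        if A_cm2 <= 0 or V_cm3 <= 0:
            raise GeometryError("area and volume must be > 0")
        return cls(kind=GeometryKind.explicit, A_cm2=A_cm2, V_cm3=V_cm3)

    @classmethod
    def rbc(cls) -> "Geometry":
        """Human red blood cell (A = 1.4e-6 cm^2, V = 9e-11 cm^3)."""
        return cls.explicit(constants.RBC_AREA_CM2, constants.RBC_VOLUME_CM3)

    def area_to_volume(self) -> float:
        """A/V in cm^-1 (3/r for a sphere)."""
        if self.kind == GeometryKind.sphere:
            return 3.0 / (self.r_nm * 1e-7)
        return self.A_cm2 / self.V_cm3


def pm_from_latency(R: float, k_catalase: float, geom: Geometry) -> float:
    """Permeability coefficient (cm s^-1) from the latency ratio.

    ``P_m = k_catalase R / [(A/V)(1 - R)]``; requires 0 < R < 1.
    """
    if not 0 < R < 1:
        raise NoLatencyError(
            f"R = {R:.3g} outside (0, 1): "
            + ("no latency (barrier absent)" if R >= 1 else "non-positive activity ratio")
        )
    if k_catalase <= 0:
        raise ValueError("k_catalase must be > 0")
    return k_catalase * R / (geom.area_to_volume() * (1.0 - R))


def r_from_pm(P_m: float, k_catalase: float, geom: Geometry) -> float:
    """Exact inverse of :func:`pm_from_latency`: the latency ratio at a given P_m."""
    if P_m <= 0 or k_catalase <= 0:
        raise ValueError("P_m and k_catalase must be > 0")
    pa = P_m * geom.area_to_volume()
    return pa / (k_catalase + pa)


# ---------------------------------------------------------------------------
# latency experiment as a model object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyResults:
    """Estimates from a fitted latency experiment.

    Standard errors are propagated from the two secondary-plot slope errors
    (delta method); they are NaN when the slopes were fitted from two points.
    """

    intact: RateSeries
    disrupted: RateSeries
    R: float
    R_stderr: float
    P_m: float
    P_m_stderr: float
    k_catalase: float
    geometry: Geometry
    temperature: float = math.nan

    @property
    def gradient(self) -> float:
        """Transmembrane substrate gradient implied by the latency ratio (1/R)."""
        return 1.0 / self.R

    def summary(self) -> str:
        g = self.geometry
        lines = [
            "Enzyme-latency permeability estimate",
            "=" * 40,
            f"  k_intact    = {self.intact.slope:.4g} +- {self.intact.slope_stderr:.2g} s^-1/amount",
            f"  k_disrupted = {self.disrupted.slope:.4g} +- {self.disrupted.slope_stderr:.2g} s^-1/amount",
            f"  R           = {self.R:.4g} +- {self.R_stderr:.2g}",
            f"  gradient    = {self.gradient:.4g}-fold",
            f"  k_catalase  = {self.k_catalase:.4g} s^-1",
            f"  A/V         = {g.area_to_volume():.4g} cm^-1 ({g.kind.value})",
            f"  P_m         = {self.P_m:.4g} +- {self.P_m_stderr:.2g} cm s^-1",
        ]
        if not math.isnan(self.temperature):
            lines.append(f"  T           = {self.temperature:.2f} K")
        return "\n".join(lines)


class LatencyExperiment:
    """Latency experiment: intact and disrupted dose series -> P_m.

    Parameters
    ----------
    intact, disrupted : sequences of :class:`TimeCourse`
        Primary traces with their ``amount`` set.  Absorbance traces are
        converted to concentration internally.
    geometry : Geometry
    k_catalase : float
        Intravesicular pseudo-first-order constant of the enzyme (s^-1),
        from the work-solution calibration (liposomes) or from the lysed-arm
        extrapolation (cells; see :meth:`k_catalase_from_lysed_slope`).
    """

    def __init__(
        self,
        intact: Sequence[TimeCourse],
        disrupted: Sequence[TimeCourse],
        geometry: Geometry,
        k_catalase: float,
        temperature: float = math.nan,
        rate_kwargs: dict | None = None,
    ):
        if len(intact) < 2 or len(disrupted) < 2:
            raise InsufficientDataError("each arm needs >= 2 traces")
        self.intact = [to_concentration(tc) for tc in intact]
        self.disrupted = [to_concentration(tc) for tc in disrupted]
        self.geometry = geometry
        self.k_catalase = float(k_catalase)
        self.temperature = temperature
        self.rate_kwargs = dict(rate_kwargs or {})

    @staticmethod
    def k_catalase_from_lysed_slope(
        lysed_slope_per_M: float, hbo2_cell: float = constants.HBO2_CELL_M
    ) -> float:
        """Intracellular catalase constant from the lysed-arm secondary slope.

        The lysed slope is a rate constant per molar HbO2 in the suspension;
        extrapolating to the intracellular HbO2 concentration (20 mM) gives
        the pseudo-first-order constant inside the cell.
        """
        return lysed_slope_per_M * hbo2_cell

    def _series(self, traces: Sequence[TimeCourse]) -> RateSeries:
        points = []
        for tc in traces:
            ir = initial_rate(tc, **self.rate_kwargs)
            points.append((tc.amount, ir.rate))
        return secondary_slope(points)

    def fit(self) -> LatencyResults:
        intact = self._series(self.intact)
        disrupted = self._series(self.disrupted)
        R = latency_ratio(intact.slope, disrupted.slope)
        rel = 0.0
        if intact.n_points > 2 and disrupted.n_points > 2:
            rel = math.sqrt(
                (intact.slope_stderr / intact.slope) ** 2
                + (disrupted.slope_stderr / disrupted.slope) ** 2
            )
            R_se = abs(R) * rel
        else:
            R_se = math.nan
        P_m = pm_from_latency(R, self.k_catalase, self.geometry)
        # dP/dR = k / [(A/V) (1-R)^2]
        if math.isnan(R_se):
            P_se = math.nan
        else:
            P_se = self.k_catalase / (self.geometry.area_to_volume() * (1 - R) ** 2) * R_se
        return LatencyResults(
            intact=intact,
            disrupted=disrupted,
            R=R,
            R_stderr=R_se,
            P_m=P_m,
            P_m_stderr=P_se,
            k_catalase=self.k_catalase,
            geometry=self.geometry,
            temperature=self.temperature,
        )


# ---------------------------------------------------------------------------
# Arrhenius analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrheniusResults:
    """Activation energy of permeation from ln(P_m) vs 1/T."""

    E_a: float  # kJ mol^-1
    lnA: float
    E_a_stderr: float
    points: tuple[tuple[float, float], ...]

    def predict(self, T: float) -> float:
        return math.exp(self.lnA - self.E_a * 1000.0 / (constants.R_GAS * T))

    def summary(self) -> str:
        return (
            "Arrhenius fit of permeability coefficients\n"
            f"  points: {len(self.points)}\n"
            f"  E_a = {self.E_a:.1f} +- {self.E_a_stderr:.1f} kJ/mol\n"
            f"  ln A = {self.lnA:.2f}"
        )


class ArrheniusModel:
    """OLS of ln(P_m) against 1/T; E_a = -slope * R."""

    def __init__(self, points: Iterable[tuple[float, float]]):
        pts = [(float(T), float(P)) for T, P in points]
        if len(pts) < 2 or len({T for T, _ in pts}) < 2:
            raise InsufficientDataError("Arrhenius fit needs >= 2 distinct temperatures")
        if any(P <= 0 for _, P in pts) or any(T <= 0 for T, _ in pts):
            raise ValueError("temperatures and permeabilities must be > 0")
        self.points = pts

    def fit(self) -> ArrheniusResults:
        x = np.array([1.0 / T for T, _ in self.points])
        y = np.array([math.log(P) for _, P in self.points])
        res = stats.linregress(x, y)
        return ArrheniusResults(
            E_a=-res.slope * constants.R_GAS / 1000.0,
            lnA=res.intercept,
            E_a_stderr=(res.stderr or math.nan) * constants.R_GAS / 1000.0,
            points=tuple(self.points),
        )


def arrhenius_fit(points: Iterable[tuple[float, float]]) -> ArrheniusResults:
    """Convenience wrapper around :class:`ArrheniusModel`."""
    return ArrheniusModel(points).fit()


# ---------------------------------------------------------------------------
# stopped-flow transport assays
# ---------------------------------------------------------------------------

class TransportModel(str, Enum):
    single_exp = "single_exp"
    double_exp = "double_exp"


@dataclass(frozen=True)
class TransportFit:
    """Fitted stopped-flow light-scattering trace.

    single_exp : ``y = a exp(-k t) + c``; ``k_water`` is the observed constant.
    double_exp : ``y = a1 exp(-k1 t) - a2 exp(-k2 t) + c`` with k2 > k1;
    the fast (rising-phase) constant is ``k_rise`` and the slow decaying-phase
    constant is ``k_glycerol``.
    """

    model: TransportModel
    rate_constants: dict
    amplitudes: dict
    baseline: float
    stderr: dict
    ssr: float

    @property
    def k_water(self) -> float:
        return self.rate_constants["k_water"]

    @property
    def k_glycerol(self) -> float:
        return self.rate_constants["k_glycerol"]

    @property
    def k_rise(self) -> float:
        return self.rate_constants["k_rise"]


def _single_exp(t, a, k, c):
    return a * np.exp(-k * t) + c


def _double_exp(t, a1, k1, a2, k2, c):
    return a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t) + c


def fit_transport_trace(
    trace: TimeCourse, model: TransportModel | str = TransportModel.single_exp,
    n_restarts: int = 5,
) -> TransportFit:
    """Nonlinear least-squares fit of a stopped-flow trace.

    Rate-constant starting guesses come from the trace's extremum time; the
    double-exponential fit runs a bounded multi-start (``n_restarts``
    perturbed initialisations) to avoid the k1<->k2 label swap, and reports
    the constants sorted (slow constant = decaying phase).
    """
    model = TransportModel(model)
    t = trace.t - trace.t[0]
    y = trace.y
    span = t[-1] - t[0]

    if model == TransportModel.single_exp:
        c0 = float(y[-1])
        a0 = float(y[0] - c0)
        if abs(a0) < 1e-12 * max(1.0, abs(c0)):
            # flat trace: decay constant is unidentifiable
            raise FitError("flat trace: single-exponential amplitude is zero")
        # half-decay heuristic for the rate guess
        half = c0 + a0 / 2.0
        crossing = np.nonzero((y - half) * np.sign(a0) < 0)[0]
        k0 = math.log(2.0) / t[crossing[0]] if len(crossing) and t[crossing[0]] > 0 else 2.0 / span
        best = None
        for factor in (1.0, 0.3, 3.0, 0.1, 10.0)[: max(1, n_restarts)]:
            try:
                popt, pcov = optimize.curve_fit(
                    _single_exp, t, y, p0=[a0, k0 * factor, c0],
                    bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((_single_exp(t, *popt) - y) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            raise FitError("single-exponential fit did not converge after restarts")
        popt, pcov, ssr = best
        se = np.sqrt(np.diag(pcov))
        return TransportFit(
            model=model,
            rate_constants={"k_water": float(popt[1])},
            amplitudes={"a": float(popt[0])},
            baseline=float(popt[2]),
            stderr={"k_water": float(se[1])},
            ssr=ssr,
        )

    # double exponential: rise then fall
    c0 = float(y[-1])
    i_ext = int(np.argmax(y))  # peak of the rise-then-fall shape
    t_ext = t[i_ext] if t[i_ext] > 0 else span / 10.0
    k_fast0 = 3.0 / t_ext
    # tail log-slope for the slow constant
    tail = slice(int(0.6 * len(t)), len(t))
    dy = y[tail] - c0
    k_slow0 = 1.0 / span
    pos = dy > 0
    if pos.sum() >= 4:
        slope = stats.linregress(t[tail][pos], np.log(dy[pos])).slope
        if slope < 0:
            k_slow0 = -slope
    amp0 = float(np.max(y) - y[0])
    best = None
    for factor in (1.0, 0.3, 3.0, 0.1, 10.0)[: max(1, n_restarts)]:
        p0 = [amp0, k_slow0 * factor, amp0, k_fast0 * factor, c0]
        try:
            popt, pcov = optimize.curve_fit(
                _double_exp, t, y, p0=p0,
                bounds=([0, 1e-12, 0, 1e-12, -np.inf], [np.inf] * 5),
                maxfev=40000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((_double_exp(t, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError("double-exponential fit did not converge after restarts")
    popt, pcov, ssr = best
    a1, k1, a2, k2, c = popt
    se = np.sqrt(np.diag(pcov))
    se1, se2 = float(se[1]), float(se[3])
    if k1 > k2:  # sort: k_glycerol is the slow, decaying-phase constant
        k1, k2, a1, a2, se1, se2 = k2, k1, a2, a1, se2, se1
    if not k2 > k1:
        raise FitError("degenerate double-exponential fit: equal rate constants")
    return TransportFit(
        model=model,
        rate_constants={"k_glycerol": float(k1), "k_rise": float(k2)},
        amplitudes={"a_slow": float(a1), "a_fast": float(a2)},
        baseline=float(c),
        stderr={"k_glycerol": se1, "k_rise": se2},
        ssr=ssr,
    )
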