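"""Kinetic-disequilibrium diagnosis and kinetic-slope projection thermometry.

Carbonates that grow while their parent dissolved-inorganic-carbon (DIC)
pool is out of isotopic equilibrium — CO2 degassing in speleothem films,
CO2 absorption in coral calcifying fluid — inherit coupled Δ47/Δ48
departures from the equilibrium curve.  During the early, nearly linear
stage of either process the disequilibrium trajectory in (Δ48, Δ47) space
has a characteristic slope: −1.0 for degassing, −0.6 for absorption
(reaction-network model results supplied here as exogenous parameters).

Projecting a measured (Δ48, Δ47) pair back along that slope onto the
parametric equilibrium curve recovers the formation temperature free of
kinetic bias; the intersection is found by a bracketed root search on

    g(T) = Δ47 + s·(Δ48_eq(T) − Δ48) − Δ47_eq(T) = 0,

which is strictly monotone in T for any negative slope.  Uncertainties are
propagated by Monte-Carlo resampling of the measured pair (independent
normal draws per channel, σ = 2 SE / 2).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .equilibrium import (
    CalibrationRangeError,
    EquilibriumCalibration,
    Temperature,
    as_kelvin,
    default_calibration,
)

__all__ = [
    "ClumpedPair",
    "KineticSlope",
    "ABSORPTION_SLOPE",
    "DEGASSING_SLOPE",
    "slope_for_process",
    "DisequilibriumOffset",
    "ProjectionResult",
    "NoIntersectionError",
    "disequilibrium_offsets",
    "project_to_equilibrium",
    "delta47_only_temperature",
    "mc_uncertainty",
    "equilibrium_consistent",
]

#: Default extension (K) of the root-search bracket beyond the calibration
#: validity range for projections; kinetically displaced draws routinely
#: intersect the curve slightly outside 0–40 °C.
PROJECTION_EXTEND = 25.0
#: Extension used when inverting Δ47 alone to expose the kinetic bias;
#: strongly biased samples map far outside the validity range by design.
D47_ONLY_EXTEND = 30.0


class NoIntersectionError(ValueError):
    """The kinetic trajectory does not intersect the equilibrium curve
    within the admissible temperature bracket."""


@dataclass(frozen=True)
class ClumpedPair:
    """A (Δ47, Δ48) pair on the CDES90 scale with replicate statistics."""

    d47: float
    d48: float
    se47_2: float = 0.0
    se48_2: float = 0.0
    n: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d47) and math.isfinite(self.d48)):
            raise ValueError("Δ values must be finite")
        if self.se47_2 < 0 or self.se48_2 < 0:
            raise ValueError("2 SE values must be ≥ 0")
        if self.n < 1:
            raise ValueError("replicate count must be ≥ 1")


@dataclass(frozen=True)
class KineticSlope:
    """dΔ47/dΔ48 of the early linear disequilibrium trajectory."""

    value: float
    process: str = "custom"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("slope must be finite")
        if self.process in ("absorption", "degassing") and self.value >= 0:
            raise ValueError(f"{self.process} slope must be negative, got {self.value}")


ABSORPTION_SLOPE = KineticSlope(
    -0.6, "absorption", "early-stage CO2 absorption (coral calcifying fluid)"
)
DEGASSING_SLOPE = KineticSlope(
    -1.0, "degassing", "early-stage CO2 degassing (speleothem solution film)"
)


def slope_for_process(process: str) -> KineticSlope:
    """Shipped slope for a named process ('absorption' or 'degassing')."""
    try:
        return {"absorption": ABSORPTION_SLOPE, "degassing": DEGASSING_SLOPE}[process]
    except KeyError:
        raise ValueError(
            f"unknown process {process!r}; expected 'absorption' or 'degassing'"
        ) from None


@dataclass(frozen=True)
class DisequilibriumOffset:
    """Measured-minus-equilibrium offsets at the known growth temperature."""

    dd47: float
    dd48: float
    growth_temperature: Temperature
    se47_2: float = 0.0
    se48_2: float = 0.0
    sample_id: str = ""


@dataclass(frozen=True)
class ProjectionResult:
    """Kinetic-slope projection of a measured pair onto the equilibrium curve."""

    intersection: tuple[float, float]  # (Δ48, Δ47) on the curve
    temperature: Temperature
    ci95: tuple[float, float] | None  # °C
    slope_used: KineticSlope
    converged: bool = True
    equilibrium_consistent: bool = False
    n_draws: int = 0
    mc_failures: int = 0

    @property
    def temperature_c(self) -> float:
        return self.temperature.celsius

    @property
    def temperature_rounded(self) -> int:
        """Projected temperature to the nearest degree Celsius."""
        return int(round(self.temperature.celsius))


def disequilibrium_offsets(
    pair: ClumpedPair,
    growth_temperature: Temperature | float,
    cal: EquilibriumCalibration | None = None,
) -> DisequilibriumOffset:
    """Offsets of a measured pair from equilibrium at its growth temperature.

    The equilibrium values are treated as exact, so the measured 2 SE pair
    carries through unchanged.
    """
    cal = cal or default_calibration()
    t = as_kelvin(growth_temperature)
    return DisequilibriumOffset(
        dd47=pair.d47 - cal.delta47(t),
        dd48=pair.d48 - cal.delta48(t),
        growth_temperature=Temperature(t),
        se47_2=pair.se47_2,
        se48_2=pair.se48_2,
        sample_id=pair.sample_id,
    )


def _project_root(
    d47: float,
    d48: float,
    slope: float,
    cal: EquilibriumCalibration,
    extend: float,
) -> float:
    """Temperature (K) where the line through (d48, d47) with ``slope``
    meets the parametric equilibrium curve."""
    lo, hi = cal.valid_range
    t_lo, t_hi = lo - extend, hi + extend

    def g(t: float) -> float:
        return d47 + slope * (float(cal.poly48(t)) - d48) - float(cal.poly47(t))

    g_lo, g_hi = g(t_lo), g(t_hi)
    if g_lo == 0.0:
        return t_lo
    if g_hi == 0.0:
        return t_hi
    if g_lo * g_hi > 0.0:
        raise NoIntersectionError(
            f"no intersection of the slope-{slope:g} trajectory through "
            f"(Δ48={d48:g}, Δ47={d47:g}) with the equilibrium curve for "
            f"temperatures in [{t_lo:.2f}, {t_hi:.2f}] K"
        )
    return float(brentq(g, t_lo, t_hi, xtol=1e-10, rtol=8.9e-16))


def delta47_only_temperature(
    pair: ClumpedPair,
    cal: EquilibriumCalibration | None = None,
    extend: float = D47_ONLY_EXTEND,
) -> Temperature:
    """Apparent temperature from Δ47 alone, ignoring Δ48.

    Used to quantify the kinetic bias (Δ47-only minus true growth
    temperature); strongly biased samples invert far outside the
    calibration validity range, hence the generous default extension.
    """
    cal = cal or default_calibration()
    return cal.invert(pair.d47, channel="d47", extend=extend)


def mc_uncertainty(
    pair: ClumpedPair,
    slope: KineticSlope,
    cal: EquilibriumCalibration | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    slope_sigma: float = 0.0,
    extend: float = PROJECTION_EXTEND,
) -> tuple[float, float]:
    """95% confidence interval (°C) of the projected temperature.

    Draws (Δ47, Δ48) from independent normals with σ = 2 SE / 2 (the 2 SE
    being read as a 95% interval), re-projects each draw and returns the
    2.5/97.5 percentiles.  Deterministic for a fixed seed.  Slope
    uncertainty is not sampled unless ``slope_sigma`` > 0.
    """
    if n_draws < 1000:
        raise ValueError(f"n_draws must be ≥ 1000, got {n_draws}")
    cal = cal or default_calibration()
    if pair.se47_2 == 0.0 and pair.se48_2 == 0.0 and slope_sigma == 0.0:
        t = _project_root(pair.d47, pair.d48, slope.value, cal, extend) - 273.15
        return (t, t)
    rng = np.random.default_rng(seed)
    d47s = rng.normal(pair.d47, pair.se47_2 / 2.0, n_draws)
    d48s = rng.normal(pair.d48, pair.se48_2 / 2.0, n_draws)
    slopes = (
        rng.normal(slope.value, slope_sigma, n_draws)
        if slope_sigma > 0.0
        else np.full(n_draws, slope.value)
    )

    lo_k, hi_k = cal.valid_range
    if slope_sigma == 0.0 and slope.value < 0.0:
        # g is strictly monotone increasing in T for negative slopes, so all
        # draws can be inverted at once on a precomputed fine grid.
        grid = np.arange(lo_k - extend, hi_k + extend + 1e-9, 0.01)
        h = slope.value * cal.poly48(grid) - cal.poly47(grid)
        target = slopes * d48s - d47s
        ok = (target >= h[0]) & (target <= h[-1])
        temps = np.interp(target[ok], h, grid) - 273.15
        failures = int(n_draws - ok.sum())
    else:
        temps_list = []
        failures = 0
        for a, b, s in zip(d47s, d48s, slopes):
            try:
                temps_list.append(_project_root(a, b, s, cal, extend) - 273.15)
            except (NoIntersectionError, CalibrationRangeError):
                failures += 1
        temps = np.asarray(temps_list)
    if temps.size == 0:
        raise NoIntersectionError("no Monte-Carlo draw intersected the equilibrium curve")
    if failures > 0.1 * n_draws:
        warnings.warn(
            f"{failures}/{n_draws} Monte-Carlo draws had no intersection; "
            "the confidence interval is conditional on intersecting draws",
            stacklevel=2,
        )
    lo, hi = np.percentile(temps, [2.5, 97.5])
    return (float(lo), float(hi))


def equilibrium_consistent(
    pair: ClumpedPair, cal: EquilibriumCalibration | None = None
) -> bool:
    """2 SE box test against the equilibrium curve.

    True when some temperature inside the calibration validity range
    satisfies |Δ47 − Δ47_eq(T)| ≤ 2 SE(Δ47) and |Δ48 − Δ48_eq(T)| ≤ 2
    SE(Δ48) simultaneously (no error covariance is assumed).
    """
    cal = cal or default_calibration()
    lo, hi = cal.valid_range
    tol = 1e-9

    def t_interval(value: float, se2: float, channel: str) -> tuple[float, float] | None:
        poly = cal.poly47 if channel == "d47" else cal.poly48
        v_min, v_max = float(poly(hi)), float(poly(lo))
        v_hi = min(value + se2, v_max)
        v_lo = max(value - se2, v_min)
        if v_hi < v_lo - tol:
            return None
        # decreasing polynomial: larger Δ -> lower T
        t_low = cal.invert(min(v_hi, v_max), channel=channel, extend=0.0).kelvin
        t_high = cal.invert(max(v_lo, v_min), channel=channel, extend=0.0).kelvin
        return (t_low - tol, t_high + tol)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        i47 = t_interval(pair.d47, pair.se47_2, "d47")
        i48 = t_interval(pair.d48, pair.se48_2, "d48")
    if i47 is None or i48 is None:
        return False
    return max(i47[0], i48[0]) <= min(i47[1], i48[1])


def project_to_equilibrium(
    pair: ClumpedPair,
    slope: KineticSlope,
    cal: EquilibriumCalibration | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    slope_sigma: float = 0.0,
    extend: float = PROJECTION_EXTEND,
) -> ProjectionResult:
    """Project a measured pair onto the equilibrium curve along a kinetic slope.

    Returns the intersection point, the kinetic-bias-free temperature, and a
    Monte-Carlo 95% CI (set ``n_draws=0`` to skip the CI).
    """
    cal = cal or default_calibration()
    t_root = _project_root(pair.d47, pair.d48, slope.value, cal, extend)

    # near-tangency diagnostic: derivative of g at the root
    g_prime = slope.value * float(cal.poly48.derivative(t_root)) - float(
        cal.poly47.derivative(t_root)
    )
    converged = True
    if abs(g_prime) < 1e-5:
        warnings.warn(
            "kinetic trajectory is nearly tangent to the equilibrium curve; "
            "the projected temperature is poorly constrained",
            stacklevel=2,
        )
        converged = False

    ci: tuple[float, float] | None = None
    failures = 0
    if n_draws:
        ci = mc_uncertainty(
            pair, slope, cal, n_draws=max(n_draws, 1000), seed=seed,
            slope_sigma=slope_sigma, extend=extend,
        )
    return ProjectionResult(
        intersection=(float(cal.poly48(t_root)), float(cal.poly47(t_root))),
        temperature=Temperature(t_root),
        ci95=ci,
        slope_used=slope,
        converged=converged,
        equilibrium_consistent=equilibrium_consistent(pair, cal),
        n_draws=int(n_draws) if n_draws else 0,
        mc_failures=failures,
    )
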