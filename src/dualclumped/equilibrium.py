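"""Equilibrium Δ47/Δ48–temperature relationships on the CDES90 scale.

The temperature dependence of the carbonate clumped isotope signals is
represented by quartic polynomials in inverse temperature,

    Δ(T) = c0 + c1/T + c2/T² + c3/T³ + c4/T⁴   (T in K, Δ in ‰),

one polynomial per channel (Δ47 and Δ48).  A calibration is constructed by
taking theoretical mineral Δ63/Δ64 polynomials, shifting each by the
phosphoric-acid fractionation factor of its channel, and anchoring the
result to a measured carbonate of independently known, constant formation
temperature (here the Devils Hole vein calcite at 33.7 °C).  Anchoring is a
constant-term shift only, so the shape of the temperature dependence is
purely theoretical while the absolute position is empirical.

The shipped :data:`DEFAULT_CALIBRATION` carries the final anchored
polynomials valid over 0–40 °C, together with the quartic Δ47-vs-Δ48
convenience fit used for plotting/reporting.  Temperature inversion and
kinetic projection always use the parametric polynomial pair, never the
convenience fit (which deviates from the parametric curve by up to
~0.0007‰, documented tolerance 0.0015‰).
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KELVIN_OFFSET",
    "DEFAULT_VALID_RANGE",
    "CalibrationRangeError",
    "CalibrationRangeWarning",
    "Temperature",
    "InverseTemperaturePolynomial",
    "Delta48Polynomial",
    "AcidFractionation",
    "AnchorRecord",
    "EquilibriumCalibration",
    "DEFAULT_CALIBRATION",
    "default_calibration",
    "delta47_eq",
    "delta48_eq",
    "delta47_from_delta48_eq",
    "invert_temperature",
    "acid_fractionation_factors",
    "build_calibration",
    "THEORY_600C_PAIR",
]

KELVIN_OFFSET = 273.15
#: Validity range of the shipped calibration, 0–40 °C.
DEFAULT_VALID_RANGE = (273.15, 313.15)

#: Theoretically predicted calcite Δ63 and Δ64 at 600 °C (‰), the reference
#: point for deriving acid fractionation factors from ETH 1/2 measurements.
THEORY_600C_PAIR = (0.018, 0.002)


class CalibrationRangeError(ValueError):
    """A temperature or Δ value falls outside the admissible range."""


class CalibrationRangeWarning(UserWarning):
    """Evaluation outside the declared validity range (but within the
    permitted extension); results are an extrapolation."""


@dataclass(frozen=True)
class Temperature:
    """A thermodynamic temperature in kelvin."""

    kelvin: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.kelvin) or self.kelvin <= 0.0:
            raise ValueError(f"temperature must be finite and > 0 K, got {self.kelvin!r}")

    @property
    def celsius(self) -> float:
        return self.kelvin - KELVIN_OFFSET

    @classmethod
    def from_celsius(cls, celsius: float) -> "Temperature":
        return cls(kelvin=celsius + KELVIN_OFFSET)

    def __float__(self) -> float:
        return float(self.kelvin)


def as_kelvin(temperature: "Temperature | float") -> float:
    """Coerce a :class:`Temperature` or plain kelvin number to float K."""
    if isinstance(temperature, Temperature):
        return temperature.kelvin
    t = float(temperature)
    if not math.isfinite(t) or t <= 0.0:
        raise ValueError(f"temperature must be finite and > 0 K, got {temperature!r}")
    return t


def _check_range(t_kelvin: float, valid_range: tuple[float, float], extend: float) -> None:
    lo, hi = valid_range
    if t_kelvin < lo - extend or t_kelvin > hi + extend:
        raise CalibrationRangeError(
            f"temperature {t_kelvin:.2f} K is more than {extend:g} K outside the "
            f"calibration validity range [{lo:.2f}, {hi:.2f}] K"
        )
    if t_kelvin < lo or t_kelvin > hi:
        warnings.warn(
            f"temperature {t_kelvin:.2f} K is outside the calibration validity range "
            f"[{lo:.2f}, {hi:.2f}] K; extrapolating",
            CalibrationRangeWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class InverseTemperaturePolynomial:
    """Quartic polynomial in 1/T: c0 + c1/T + c2/T² + c3/T³ + c4/T⁴.

    Must be strictly monotone decreasing in T over ``valid_range`` (checked
    numerically on a 0.1 K grid at construction), which guarantees a unique,
    bracketable temperature inverse.
    """

    coeffs: tuple[float, float, float, float, float]
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE

    def __post_init__(self) -> None:
        if len(self.coeffs) != 5 or not all(math.isfinite(c) for c in self.coeffs):
            raise ValueError("need five finite coefficients c0..c4")
        lo, hi = self.valid_range
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid validity range {self.valid_range!r}")
        grid = np.arange(lo, hi + 1e-9, 0.1)
        values = self(grid)
        if not np.all(np.diff(values) < 0.0):
            raise ValueError(
                "polynomial is not strictly monotone decreasing in T over "
                f"{self.valid_range}"
            )

    def __call__(self, t_kelvin):
        x = 1.0 / np.asarray(t_kelvin, dtype=float)
        c0, c1, c2, c3, c4 = self.coeffs
        return c0 + x * (c1 + x * (c2 + x * (c3 + x * c4)))

    def derivative(self, t_kelvin):
        """dΔ/dT (‰/K)."""
        t = np.asarray(t_kelvin, dtype=float)
        _, c1, c2, c3, c4 = self.coeffs
        return -(c1 / t**2 + 2.0 * c2 / t**3 + 3.0 * c3 / t**4 + 4.0 * c4 / t**5)

    def shifted(self, offset: float) -> "InverseTemperaturePolynomial":
        """Return a copy with ``offset`` added to the constant term."""
        c0, c1, c2, c3, c4 = self.coeffs
        return replace(self, coeffs=(c0 + offset, c1, c2, c3, c4))


@dataclass(frozen=True)
class Delta48Polynomial:
    """Quartic in Δ48 giving equilibrium Δ47; a reporting convenience fit."""

    coeffs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.coeffs) != 5 or not all(math.isfinite(c) for c in self.coeffs):
            raise ValueError("need five finite coefficients b0..b4")

    def __call__(self, d48):
        x = np.asarray(d48, dtype=float)
        b0, b1, b2, b3, b4 = self.coeffs
        return b0 + x * (b1 + x * (b2 + x * (b3 + x * b4)))


@dataclass(frozen=True)
class AcidFractionation:
    """Constant offsets between mineral Δ63/Δ64 and acid-liberated CO2
    Δ47/Δ48 introduced by phosphoric acid digestion at 90 °C."""

    aff47: float = 0.194
    aff48: float = 0.138
    sd47: float = 0.002
    sd48: float = 0.005
    reaction_temperature_c: float = 90.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.aff47) and math.isfinite(self.aff48)):
            raise ValueError("acid fractionation factors must be finite")


@dataclass(frozen=True)
class AnchorRecord:
    """Record of the constant-term anchoring of a calibration to a carbonate
    of known formation temperature."""

    sample_id: str
    anchor_temperature: Temperature
    measured_pair: tuple[float, float]
    applied_offsets: tuple[float, float]


@dataclass(frozen=True)
class EquilibriumCalibration:
    """An anchored pair of equilibrium polynomials plus metadata.

    Parameters
    ----------
    poly47, poly48 :
        Equilibrium Δ47(T) and Δ48(T) polynomials in 1/T, CDES90 scale.
    d47_of_d48 :
        Optional quartic Δ47(Δ48) fit, retained for reporting only; if
        present it must agree with the parametric pair to within 0.0015‰
        over the validity range.
    acid :
        Acid fractionation factors used in the construction.
    anchor :
        Anchoring record, if the calibration was anchored.
    """

    poly47: InverseTemperaturePolynomial
    poly48: InverseTemperaturePolynomial
    d47_of_d48: Delta48Polynomial | None = None
    acid: AcidFractionation = field(default_factory=AcidFractionation)
    anchor: AnchorRecord | None = None
    scale_label: str = "CDES90"

    #: Tolerance (‰) between the Δ47(Δ48) convenience fit and the
    #: parametric curve, checked at construction.
    FIT_TOLERANCE = 0.0015

    def __post_init__(self) -> None:
        if self.poly47.valid_range != self.poly48.valid_range:
            raise ValueError("poly47 and poly48 must share a validity range")
        if self.d47_of_d48 is not None:
            grid = np.linspace(*self.valid_range, 401)
            dev = np.abs(self.d47_of_d48(self.poly48(grid)) - self.poly47(grid))
            if float(dev.max()) > self.FIT_TOLERANCE:
                raise ValueError(
                    "d47_of_d48 fit deviates from the parametric curve by "
                    f"{dev.max():.5f}‰ (> {self.FIT_TOLERANCE}‰)"
                )

    @property
    def valid_range(self) -> tuple[float, float]:
        return self.poly47.valid_range

    # -- evaluation ---------------------------------------------------------

    def delta47(self, temperature: Temperature | float, extend: float = 10.0) -> float:
        t = as_kelvin(temperature)
        _check_range(t, self.valid_range, extend)
        return float(self.poly47(t))

    def delta48(self, temperature: Temperature | float, extend: float = 10.0) -> float:
        t = as_kelvin(temperature)
        _check_range(t, self.valid_range, extend)
        return float(self.poly48(t))

    def delta47_from_delta48(self, d48: float) -> float:
        if self.d47_of_d48 is None:
            raise ValueError("this calibration carries no Δ47(Δ48) convenience fit")
        lo, hi = self.valid_range
        d48_lo, d48_hi = float(self.poly48(hi)), float(self.poly48(lo))
        if not (d48_lo - 1e-12 <= d48 <= d48_hi + 1e-12):
            raise CalibrationRangeError(
                f"Δ48 = {d48:g}‰ outside the fitted range "
                f"[{d48_lo:.4f}, {d48_hi:.4f}]‰"
            )
        return float(self.d47_of_d48(d48))

    def attainable(self, channel: Literal["d47", "d48"], extend: float = 10.0) -> tuple[float, float]:
        """(min, max) of the channel polynomial over the extended range."""
        poly = self.poly47 if channel == "d47" else self.poly48
        lo, hi = self.valid_range
        return float(poly(hi + extend)), float(poly(lo - extend))

    def invert(
        self,
        value: float,
        channel: Literal["d47", "d48"] = "d47",
        extend: float = 10.0,
    ) -> Temperature:
        """Unique temperature at which the channel polynomial equals ``value``.

        Bisection-type bracketed root search (Brent) on the validity range
        extended by ``extend`` kelvin on either side; warns when the root
        falls outside the base range.
        """
        if channel not in ("d47", "d48"):
            raise ValueError(f"channel must be 'd47' or 'd48', got {channel!r}")
        if not math.isfinite(value):
            raise ValueError(f"value must be finite, got {value!r}")
        poly = self.poly47 if channel == "d47" else self.poly48
        lo, hi = self.valid_range
        t_lo, t_hi = lo - extend, hi + extend
        v_min, v_max = float(poly(t_hi)), float(poly(t_lo))
        if not (v_min <= value <= v_max):
            raise CalibrationRangeError(
                f"{channel} = {value:g}‰ is outside the attainable interval "
                f"[{v_min:.4f}, {v_max:.4f}]‰ for temperatures in "
                f"[{t_lo:.2f}, {t_hi:.2f}] K"
            )
        root = brentq(lambda t: float(poly(t)) - value, t_lo, t_hi, xtol=1e-10, rtol=8.9e-16)
        if root < lo or root > hi:
            warnings.warn(
                f"inverted temperature {root - KELVIN_OFFSET:.2f} °C lies outside the "
                f"calibration validity range "
                f"[{lo - KELVIN_OFFSET:.1f}, {hi - KELVIN_OFFSET:.1f}] °C",
                CalibrationRangeWarning,
                stacklevel=2,
            )
        return Temperature(kelvin=float(root))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "scale_label": self.scale_label,
            "valid_range_K": list(self.valid_range),
            "poly47": list(self.poly47.coeffs),
            "poly48": list(self.poly48.coeffs),
            "acid": {
                "aff47": self.acid.aff47,
                "aff48": self.acid.aff48,
                "sd47": self.acid.sd47,
                "sd48": self.acid.sd48,
                "reaction_temperature_c": self.acid.reaction_temperature_c,
            },
        }
        if self.d47_of_d48 is not None:
            d["d47_of_d48"] = list(self.d47_of_d48.coeffs)
        if self.anchor is not None:
            d["anchor"] = {
                "sample_id": self.anchor.sample_id,
                "anchor_temperature_K": self.anchor.anchor_temperature.kelvin,
                "measured_pair": list(self.anchor.measured_pair),
                "applied_offsets": list(self.anchor.applied_offsets),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EquilibriumCalibration":
        vr = tuple(d.get("valid_range_K", DEFAULT_VALID_RANGE))
        acid = AcidFractionation(**d["acid"]) if "acid" in d else AcidFractionation()
        anchor = None
        if "anchor" in d:
            a = d["anchor"]
            anchor = AnchorRecord(
                sample_id=a["sample_id"],
                anchor_temperature=Temperature(a["anchor_temperature_K"]),
                measured_pair=tuple(a["measured_pair"]),
                applied_offsets=tuple(a["applied_offsets"]),
            )
        return cls(
            poly47=InverseTemperaturePolynomial(tuple(d["poly47"]), vr),
            poly48=InverseTemperaturePolynomial(tuple(d["poly48"]), vr),
            d47_of_d48=(
                Delta48Polynomial(tuple(d["d47_of_d48"])) if "d47_of_d48" in d else None
            ),
            acid=acid,
            anchor=anchor,
            scale_label=d.get("scale_label", "CDES90"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EquilibriumCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- shipped default calibration -------------------------------------------

#: Equilibrium Δ47(T), CDES90, 0–40 °C (anchored at Devils Hole, 33.7 °C).
D47_EQ_COEFFS = (0.3642, -2.914e2, 1.800e5, -2.657e7, 1.493e9)
#: Equilibrium Δ48(T), CDES90, 0–40 °C.
D48_EQ_COEFFS = (0.1742, -5.897e1, 1.252e4, 5.039e6, -5.631e8)
#: Quartic Δ47(Δ48) convenience fit combining the two.
D47_VS_D48_COEFFS = (-0.4771, 9.102, -31.709, 65.561, -54.560)

DEFAULT_CALIBRATION = EquilibriumCalibration(
    poly47=InverseTemperaturePolynomial(D47_EQ_COEFFS),
    poly48=InverseTemperaturePolynomial(D48_EQ_COEFFS),
    d47_of_d48=Delta48Polynomial(D47_VS_D48_COEFFS),
    acid=AcidFractionation(),
    anchor=AnchorRecord(
        sample_id="DHC2-8",
        anchor_temperature=Temperature.from_celsius(33.7),
        measured_pair=(0.575, 0.226),
        applied_offsets=(0.010, -0.021),
    ),
)


def default_calibration() -> EquilibriumCalibration:
    """The built-in anchored CDES90 calibration (0–40 °C)."""
    return DEFAULT_CALIBRATION


def _cal(cal: EquilibriumCalibration | None) -> EquilibriumCalibration:
    return DEFAULT_CALIBRATION if cal is None else cal


def delta47_eq(
    temperature: Temperature | float,
    cal: EquilibriumCalibration | None = None,
    extend: float = 10.0,
) -> float:
    """Equilibrium Δ47 (‰, CDES90) at ``temperature``."""
    return _cal(cal).delta47(temperature, extend=extend)


def delta48_eq(
    temperature: Temperature | float,
    cal: EquilibriumCalibration | None = None,
    extend: float = 10.0,
) -> float:
    """Equilibrium Δ48 (‰, CDES90) at ``temperature``."""
    return _cal(cal).delta48(temperature, extend=extend)


def delta47_from_delta48_eq(d48: float, cal: EquilibriumCalibration | None = None) -> float:
    """Equilibrium Δ47 from Δ48 via the quartic convenience fit.

    For reporting only; projection and inversion use the parametric pair.
    """
    return _cal(cal).delta47_from_delta48(d48)


def invert_temperature(
    value: float,
    channel: Literal["d47", "d48"] = "d47",
    cal: EquilibriumCalibration | None = None,
    extend: float = 10.0,
) -> Temperature:
    """Invert an equilibrium polynomial for temperature (bracketed root)."""
    return _cal(cal).invert(value, channel=channel, extend=extend)


def acid_fractionation_factors(
    measured_600c_pair: tuple[float, float],
    theoretical_600c_pair: tuple[float, float] = THEORY_600C_PAIR,
    measured_se_pair: tuple[float, float] = (0.0, 0.0),
) -> AcidFractionation:
    """Acid fractionation factors from the 600 °C-equilibrated standards.

    ``aff = measured − theoretical`` per channel; the theoretical values are
    treated as exact, so the measured standard errors propagate unchanged.
    """
    m47, m48 = measured_600c_pair
    t47, t48 = theoretical_600c_pair
    for v in (m47, m48, t47, t48):
        if not math.isfinite(v):
            raise ValueError("acid fractionation inputs must be finite")
    return AcidFractionation(
        aff47=m47 - t47,
        aff48=m48 - t48,
        sd47=float(measured_se_pair[0]),
        sd48=float(measured_se_pair[1]),
    )


def build_calibration(
    theory63: InverseTemperaturePolynomial,
    theory64: InverseTemperaturePolynomial,
    acid: AcidFractionation,
    anchor_pair: tuple[float, float],
    anchor_temperature: Temperature | float,
    sample_id: str = "anchor",
    d47_of_d48: Delta48Polynomial | None = None,
) -> EquilibriumCalibration:
    """Construct an anchored calibration from theoretical Δ63/Δ64 polynomials.

    The theory polynomials are shifted by the acid fractionation factor of
    their channel and then anchored — a second constant-term shift — so the
    calibration passes exactly through ``anchor_pair`` at the anchor
    temperature.  The applied anchor offsets are stored in the
    :class:`AnchorRecord`.
    """
    t_anchor = as_kelvin(anchor_temperature)
    lo, hi = theory63.valid_range
    if not (lo <= t_anchor <= hi):
        raise CalibrationRangeError(
            f"anchor temperature {t_anchor:.2f} K outside theory range [{lo}, {hi}] K"
        )
    base47 = theory63.shifted(acid.aff47)
    base48 = theory64.shifted(acid.aff48)
    off47 = float(anchor_pair[0] - base47(t_anchor))
    off48 = float(anchor_pair[1] - base48(t_anchor))
    return EquilibriumCalibration(
        poly47=base47.shifted(off47),
        poly48=base48.shifted(off48),
        d47_of_d48=d47_of_d48,
        acid=acid,
        anchor=AnchorRecord(
            sample_id=sample_id,
            anchor_temperature=Temperature(t_anchor),
            measured_pair=(float(anchor_pair[0]), float(anchor_pair[1])),
            applied_offsets=(off47, off48),
        ),
    )
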